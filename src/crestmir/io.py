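"""Light wrappers around the text formats the pipeline touches.

FASTA/FASTQ go through Biopython; GFF3 is written/read as its 9-column
TSV body (1-based inclusive coordinates on disk, 0-based half-open in
memory everywhere else).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_dna(seq: str) -> str:
    """Uppercase and map RNA U to DNA T (matures are printed as RNA)."""
    return seq.upper().replace("U", "T")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def write_gff3(path, rows: Iterable[dict]) -> None:
    """Rows carry 0-based half-open ``start``/``end``; written 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in rows:
            attrs = r.get("attributes", ".")
            fh.write(
                "\t".join([
                    str(r["seqid"]), str(r.get("source", "crestmir")),
                    str(r.get("type", "region")), str(r["start"] + 1),
                    str(r["end"]), str(r.get("score", ".")),
                    str(r.get("strand", ".")), str(r.get("phase", ".")), attrs,
                ]) + "\n"
            )


def read_gff3(path) -> pd.DataFrame:
    """Returns a DataFrame with 0-based half-open ``start``/``end``."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GFF3_COLUMNS,
        dtype={"seqid": str, "attributes": str},
    )
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return df


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
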