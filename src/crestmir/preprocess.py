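"""HD-adapter read cleaning: trim, length-filter, collapse.

The 3' adapter is located by a perfect match to its first 8 nt
(TGGAATTC); the read is cut there and the two 4-nt HD signatures (the
degenerate ligation bases flanking the insert) are removed. Inserts of
16-35 nt are kept. Every discard carries a reason code so that raw =
kept + discarded holds exactly per library.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import normalize_dna

DISCARD_REASONS = ("no_adapter", "insert_too_short", "n_in_insert", "length")


@dataclass
class TrimConfig:
    adapter_prefix: str = "TGGAATTC"
    hd_len: int = 4
    min_len: int = 16
    max_len: int = 35

    def __post_init__(self):
        if len(self.adapter_prefix) != 8:
            raise ValueError("adapter_prefix must be 8 nt")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.hd_len < 0:
            raise ValueError("hd_len must be >= 0")


def trim_read(read: str, config: TrimConfig = TrimConfig()) -> tuple[str | None, str]:
    """Trim one read; returns ``(insert, "ok")`` or ``(None, reason)``.

    The leftmost exact adapter-prefix occurrence wins. A remainder
    shorter than 2*hd_len+1 cannot contain both HD signatures plus a
    non-empty insert and is discarded.
    """
    read = normalize_dna(read)
    pos = read.find(config.adapter_prefix)
    if pos < 0:
        return None, "no_adapter"
    if pos < 2 * config.hd_len + 1:
        return None, "insert_too_short"
    insert = read[config.hd_len:pos - config.hd_len]
    if "N" in insert:
        return None, "n_in_insert"
    return insert, "ok"


def length_filter(insert: str, config: TrimConfig = TrimConfig()) -> bool:
    return config.min_len <= len(insert) <= config.max_len


def trim_library(reads, config: TrimConfig = TrimConfig()):
    """Trim a stream of read sequences.

    Returns ``(kept, tallies)`` where ``kept`` is a Counter of insert
    sequences and ``tallies`` counts raw reads and each discard reason.
    """
    kept: Counter[str] = Counter()
    tallies = {"raw": 0, "kept": 0, **{r: 0 for r in DISCARD_REASONS}}
    hd = config.hd_len
    prefix = config.adapter_prefix
    lo, hi = config.min_len, config.max_len
    min_pos = 2 * hd + 1
    for read in reads:
        tallies["raw"] += 1
        read = normalize_dna(read)
        pos = read.find(prefix)
        if pos < 0:
            tallies["no_adapter"] += 1
            continue
        if pos < min_pos:
            tallies["insert_too_short"] += 1
            continue
        insert = read[hd:pos - hd]
        if "N" in insert:
            tallies["n_in_insert"] += 1
            continue
        if not lo <= len(insert) <= hi:
            tallies["length"] += 1
            continue
        kept[insert] += 1
        tallies["kept"] += 1
    return kept, tallies


@dataclass
class CollapsedReadSet:
    """Distinct insert sequences with per-library counts."""

    sequences: list[str]
    counts: np.ndarray                     # shape (n_sequences, n_libraries)
    libraries: list[str]
    totals: pd.DataFrame = field(default=None)   # per-library tallies

    def __post_init__(self):
        if len(set(self.libraries)) != len(self.libraries):
            raise ValueError("duplicate library ids")
        if self.counts.shape != (len(self.sequences), len(self.libraries)):
            raise ValueError("counts shape does not match sequences x libraries")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def library_index(self, library: str) -> int:
        return self.libraries.index(library)

    def total_counts(self) -> np.ndarray:
        """Per-sequence counts summed over libraries (redundant reads)."""
        return self.counts.sum(axis=1)

    def per_library_kept(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=0), index=self.libraries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sequences,
                            columns=self.libraries)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "sequence"
        df.to_csv(path, sep="\t")

    def write_collapsed_fasta(self, path) -> None:
        totals = self.total_counts()
        order = np.argsort(-totals, kind="stable")
        with open(path, "w") as fh:
            for rank, i in enumerate(order, 1):
                fh.write(f">seq_{rank}_x{int(totals[i])}\n"
                         f"{self.sequences[i]}\n")

    @classmethod
    def from_tsv(cls, path) -> "CollapsedReadSet":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(sequences=list(df.index), counts=df.to_numpy(dtype=np.int64),
                   libraries=list(df.columns))


def collapse(libraries: dict[str, Counter],
             tallies: dict[str, dict] | None = None) -> CollapsedReadSet:
    """Merge per-library insert Counters into one count matrix."""
    lib_ids = list(libraries)
    if len(set(lib_ids)) != len(lib_ids):
        raise ValueError("duplicate library ids")
    seqs = sorted(set().union(*[set(c) for c in libraries.values()]) or set())
    counts = np.zeros((len(seqs), len(lib_ids)), dtype=np.int64)
    index = {s: i for i, s in enumerate(seqs)}
    for j, lib in enumerate(lib_ids):
        for s, c in libraries[lib].items():
            counts[index[s], j] = c
    totals = None
    if tallies is not None:
        totals = pd.DataFrame(tallies).T.reindex(lib_ids)
    return CollapsedReadSet(sequences=seqs, counts=counts, libraries=lib_ids,
                            totals=totals)
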