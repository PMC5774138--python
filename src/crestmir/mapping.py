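"""Exact, full-length, both-strand genome mapping of collapsed inserts.

Reads are 16-35 nt and must match the genome with no gaps or
mismatches, so the index is a hash of 16-nt genome words with
verification extension: look up the first 16 nt of the read (and of its
reverse complement), then confirm the full-length match. All loci are
retained — the miR-427-like repeat cluster is massively multi-mapping
by design.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import revcomp

INDEX_K = 16


@dataclass(frozen=True)
class MatchLocus:
    chrom: str
    start: int   # 0-based half-open on the forward strand
    end: int
    strand: str


class GenomeIndex:
    """Hash index of fixed-width genome words for exact lookup."""

    def __init__(self, genome: dict[str, str], k: int = INDEX_K):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self._index[seq[i:i + k]].append((chrom, i))
        self._index = dict(self._index)

    def map_sequence(self, seq: str) -> list[MatchLocus]:
        """All full-length exact loci of ``seq`` on both strands."""
        n = len(seq)
        if n < self.k:
            raise ValueError(f"read shorter than index word ({n} < {self.k})")
        out: list[MatchLocus] = []
        for strand, probe in (("+", seq), ("-", revcomp(seq))):
            for chrom, i in self._index.get(probe[:self.k], ()):
                if self.genome[chrom][i:i + n] == probe:
                    out.append(MatchLocus(chrom, i, i + n, strand))
        out.sort(key=lambda m: (m.chrom, m.start, m.strand))
        return out


#: genomes above this size use the query-driven sparse word scan
DENSE_INDEX_MAX = 1_000_000

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def _rolling_words(seq: str, k: int) -> np.ndarray:
    """2-bit packed k-mer value at every genome position (k <= 32)."""
    arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    arr = arr.astype(np.uint64)
    n = arr.shape[0]
    if n < k:
        return np.empty(0, dtype=np.uint64)
    v = np.zeros(n - k + 1, dtype=np.uint64)
    for j in range(k):
        v = (v << np.uint64(2)) | arr[j:n - k + 1 + j]
    return v


def _word_value(word: str) -> int:
    v = 0
    for c in word:
        v = (v << 2) | int(_BASE_CODE[ord(c)])
    return v


def _sparse_map(seqs: list[str], genome: dict[str, str], k: int = INDEX_K
                ) -> dict[str, list[MatchLocus]]:
    """Query-driven exact mapping for genomes too large to index densely.

    One vectorised pass per chromosome locates every occurrence of the
    k-nt prefixes of the reads (and of their reverse complements); the
    full-length match is then verified as in the dense path.
    """
    probes: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for s in seqs:
        if len(s) < k:
            raise ValueError(f"read shorter than index word ({len(s)} < {k})")
        probes[s[:k]].append((s, "+"))
        rc = revcomp(s)
        probes[rc[:k]].append((s, "-"))
    probe_vals = np.array(sorted({_word_value(p) for p in probes}),
                          dtype=np.uint64)
    positions: dict[int, list[tuple[str, int]]] = defaultdict(list)
    for chrom, seq in genome.items():
        words = _rolling_words(seq, k)
        hit = np.isin(words, probe_vals)
        for pos in np.flatnonzero(hit):
            positions[int(words[pos])].append((chrom, int(pos)))
    out: dict[str, list[MatchLocus]] = {s: [] for s in seqs}
    for prefix, owners in probes.items():
        for chrom, pos in positions.get(_word_value(prefix), ()):
            gseq = genome[chrom]
            for s, strand in owners:
                probe = s if strand == "+" else revcomp(s)
                if gseq[pos:pos + len(s)] == probe:
                    out[s].append(MatchLocus(chrom, pos, pos + len(s), strand))
    for s in out:
        out[s].sort(key=lambda m: (m.chrom, m.start, m.strand))
        # a palindromic read can register the same interval twice
        dedup = []
        for m in out[s]:
            if not dedup or dedup[-1] != m:
                dedup.append(m)
        out[s] = dedup
    return out


def map_exact(sequences, genome: dict[str, str] | GenomeIndex
              ) -> dict[str, list[MatchLocus]]:
    """Map sequences (iterable or CollapsedReadSet) to all exact loci.

    Sequences with zero loci map to an empty list (flagged unmapped and
    excluded from downstream normalisation). Large genomes are scanned
    with a query-driven word pass instead of a dense index; the
    full-length exact-match contract is identical.
    """
    seqs = list(getattr(sequences, "sequences", sequences))
    if isinstance(genome, GenomeIndex):
        return {s: genome.map_sequence(s) for s in seqs}
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    if sum(len(s) for s in genome.values()) > DENSE_INDEX_MAX:
        return _sparse_map(seqs, genome)
    index = GenomeIndex(genome)
    return {s: index.map_sequence(s) for s in seqs}


def mapping_to_frame(mapping: dict[str, list[MatchLocus]]) -> pd.DataFrame:
    rows = [
        (s, m.chrom, m.start, m.end, m.strand)
        for s in mapping for m in mapping[s]
    ]
    return pd.DataFrame(rows, columns=["sequence", "chrom", "start", "end",
                                       "strand"])


def write_bed6(path, mapping: dict[str, list[MatchLocus]]) -> None:
    with open(path, "w") as fh:
        for s in mapping:
            for m in mapping[s]:
                fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{s}\t0\t{m.strand}\n")


@dataclass
class SizeClassProfile:
    """Per-library redundant-read RPM by insert length (16-35 nt)."""

    rpm: pd.DataFrame                 # index: length, columns: libraries
    matched_totals: pd.Series         # genome-matched reads per library
    mirna_fraction: pd.DataFrame | None = None


def size_class_profile(collapsed, mapping: dict[str, list[MatchLocus]],
                       min_len: int = 16, max_len: int = 35,
                       mirna_intervals=None) -> SizeClassProfile:
    """Length histogram of genome-matched reads, RPM-normalised.

    The RPM denominator is the number of genome-matched reads per
    library. If ``mirna_intervals`` (iterable of (chrom, start, end,
    strand)) is given, the fraction of each length class whose reads
    fall inside an annotated miRNA hairpin is reported as well.
    """
    lengths = np.array([len(s) for s in collapsed.sequences])
    matched = np.array([bool(mapping.get(s)) for s in collapsed.sequences])
    counts = collapsed.counts
    matched_totals = counts[matched].sum(axis=0)
    if (matched_totals == 0).any():
        bad = [collapsed.libraries[j] for j in np.flatnonzero(matched_totals == 0)]
        raise ValueError(f"no genome-matched reads in libraries: {bad}")

    idx = np.arange(min_len, max_len + 1)
    rpm = pd.DataFrame(0.0, index=idx, columns=collapsed.libraries)
    mir = None
    in_mirna = None
    if mirna_intervals is not None:
        ivals = defaultdict(list)
        for chrom, start, end, strand in mirna_intervals:
            ivals[(chrom, strand)].append((start, end))
        def hits_mirna(seq):
            for m in mapping.get(seq, ()):
                for s_, e_ in ivals.get((m.chrom, m.strand), ()):
                    if m.start >= s_ and m.end <= e_:
                        return True
            return False
        in_mirna = np.array([hits_mirna(s) for s in collapsed.sequences])
        mir = pd.DataFrame(np.nan, index=idx, columns=collapsed.libraries)

    for L in idx:
        sel = matched & (lengths == L)
        rpm.loc[L] = counts[sel].sum(axis=0) / matched_totals * 1e6
        if in_mirna is not None:
            class_tot = counts[sel].sum(axis=0).astype(float)
            mirna_tot = counts[sel & in_mirna].sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                mir.loc[L] = np.where(class_tot > 0, mirna_tot / class_tot, np.nan)

    return SizeClassProfile(
        rpm=rpm,
        matched_totals=pd.Series(matched_totals, index=collapsed.libraries),
        mirna_fraction=mir,
    )
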