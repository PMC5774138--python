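"""Characterisation of the 29-nt small-RNA class.

Three questions about the non-miRNA peak at 29 nt: (1) does it sit in
genomic clusters, as piRNAs do? — answered by deterministic density
merging (reads of 25-33 nt, gaps <= 500 nt, >= 50 reads) with the
descriptive piRNA signatures (strand bias, 1U fraction, mean length);
(2) what count-weighted fraction of the focal length lies inside those
clusters?; (3) are focal-length reads enriched in exons (degradation
fragments) or introns (siteRNA-like), tested with a two-proportion z
test of the focal fraction against all other lengths.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .mapping import MatchLocus


@dataclass
class SRNACluster:
    chrom: str
    start: int
    end: int
    count: float
    strand_bias: float      # fraction of counts on the majority strand
    u1_fraction: float      # fraction of member reads starting with U/T
    mean_length: float


@dataclass
class EnrichmentResult:
    feature: str
    focal_fraction: float
    background_fraction: float
    z: float
    p: float
    n_focal: int
    n_background: int


def detect_clusters(mapping: dict[str, list[MatchLocus]],
                    total_counts: dict[str, float],
                    min_len: int = 25, max_len: int = 33,
                    min_reads: float = 50, max_gap: int = 500,
                    ) -> list[SRNACluster]:
    """Density-merge 25-33 nt read loci into clusters.

    Loci separated by <= ``max_gap`` merge; merged intervals keep
    >= ``min_reads`` total count. Multi-locus reads contribute at every
    locus. Returned intervals are disjoint and sorted.
    """
    per_chrom: dict[str, list[tuple[int, int, str, str]]] = defaultdict(list)
    for seq, loci in mapping.items():
        if not (min_len <= len(seq) <= max_len):
            continue
        if total_counts.get(seq, 0) <= 0:
            continue
        for m in loci:
            per_chrom[m.chrom].append((m.start, m.end, m.strand, seq))
    clusters: list[SRNACluster] = []
    for chrom in sorted(per_chrom):
        rows = sorted(per_chrom[chrom])
        cur: list[tuple[int, int, str, str]] = []
        cur_end = -1
        for row in rows + [(1 << 60, 1 << 60, "", "")]:
            s, e, strand, seq = row
            if cur and s - cur_end > max_gap:
                cl = _finish_cluster(chrom, cur, total_counts, min_reads)
                if cl is not None:
                    clusters.append(cl)
                cur = []
                cur_end = -1
            if seq:
                cur.append(row)
                cur_end = max(cur_end, e)
    return clusters


def _finish_cluster(chrom, rows, total_counts, min_reads):
    count = 0.0
    plus = 0.0
    u1 = 0.0
    length_sum = 0.0
    for s, e, strand, seq in rows:
        c = total_counts[seq]
        count += c
        if strand == "+":
            plus += c
        if seq.startswith("T"):
            u1 += c
        length_sum += c * len(seq)
    if count < min_reads:
        return None
    return SRNACluster(
        chrom=chrom, start=min(r[0] for r in rows), end=max(r[1] for r in rows),
        count=count, strand_bias=max(plus, count - plus) / count,
        u1_fraction=u1 / count, mean_length=length_sum / count,
    )


def fraction_in_clusters(mapping: dict[str, list[MatchLocus]],
                         total_counts: dict[str, float],
                         clusters: list[SRNACluster],
                         length: int = 29) -> float | None:
    """Count-weighted fraction of focal-length reads inside any cluster.

    A multi-locus read counts as in-cluster if any of its loci falls
    inside a cluster. Returns None (flagged undefined) with no focal
    reads.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for c in clusters:
        by_chrom[c.chrom].append((c.start, c.end))
    total = 0.0
    inside = 0.0
    for seq, loci in mapping.items():
        if len(seq) != length:
            continue
        cnt = total_counts.get(seq, 0)
        if cnt <= 0 or not loci:
            continue
        total += cnt
        if any(s_ <= m.start and m.end <= e_
               for m in loci for s_, e_ in by_chrom.get(m.chrom, ())):
            inside += cnt
    if total == 0:
        return None
    return inside / total


def feature_intervals(gene_models, feature: str) -> dict[str, list[tuple[int, int]]]:
    """Exon or intron intervals per chromosome from gene models."""
    if feature not in ("exon", "intron"):
        raise ValueError("feature must be 'exon' or 'intron'")
    out: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for g in gene_models:
        ivals = g.exons if feature == "exon" else g.introns
        for s, e in ivals:
            out[g.chrom].append((s, e))
    return dict(out)


def intervals_from_gff(gff: pd.DataFrame, feature: str
                       ) -> dict[str, list[tuple[int, int]]]:
    """Exon (or derived intron) intervals from a gene-model GFF3 table."""
    if feature not in ("exon", "intron"):
        raise ValueError("feature must be 'exon' or 'intron'")
    out: dict[str, list[tuple[int, int]]] = defaultdict(list)
    exons = gff[gff["type"] == "exon"]
    if feature == "exon":
        for _, r in exons.iterrows():
            out[r["seqid"]].append((int(r["start"]), int(r["end"])))
        return dict(out)
    # introns: gaps between consecutive exons of the same gene
    def parent_of(attrs: str) -> str:
        for part in str(attrs).split(";"):
            if part.startswith("Parent="):
                return part[7:]
        return str(attrs)
    for (_seqid, _parent), grp in exons.groupby(
            [exons["seqid"], exons["attributes"].map(parent_of)]):
        iv = sorted(zip(grp["start"].astype(int), grp["end"].astype(int)))
        for (s1, e1), (s2, e2) in zip(iv, iv[1:]):
            if s2 > e1:
                out[_seqid].append((e1, s2))
    return dict(out)


def feature_enrichment(mapping: dict[str, list[MatchLocus]],
                       total_counts: dict[str, float],
                       intervals: dict[str, list[tuple[int, int]]],
                       feature: str = "exon",
                       focal_length: int = 29) -> EnrichmentResult | None:
    """Two-proportion z test of focal-length reads overlapping a feature.

    Focal fraction: count-weighted fraction of genome-matched reads of
    ``focal_length`` with any-overlap (>= 1 nt) of any feature
    interval; background: the same over all other lengths. One-sided
    test of focal > background. Returns None (flagged) with zero focal
    reads; raises on an empty annotation.
    """
    if not intervals or all(len(v) == 0 for v in intervals.values()):
        raise ValueError("empty feature annotation")
    sorted_iv = {c: sorted(v) for c, v in intervals.items()}

    def overlaps(loci) -> bool:
        for m in loci:
            for s_, e_ in sorted_iv.get(m.chrom, ()):
                if m.start < e_ and m.end > s_:
                    return True
        return False

    k = {"focal": 0.0, "bg": 0.0}
    n = {"focal": 0.0, "bg": 0.0}
    for seq, loci in mapping.items():
        if not loci:
            continue
        cnt = total_counts.get(seq, 0)
        if cnt <= 0:
            continue
        cls = "focal" if len(seq) == focal_length else "bg"
        n[cls] += cnt
        if overlaps(loci):
            k[cls] += cnt
    if n["focal"] == 0:
        return None
    if n["bg"] == 0:
        raise ValueError("no background reads to compare against")
    z, p = proportions_ztest(
        count=np.array([k["focal"], k["bg"]]),
        nobs=np.array([n["focal"], n["bg"]]),
        alternative="larger",
    )
    return EnrichmentResult(
        feature=feature,
        focal_fraction=k["focal"] / n["focal"],
        background_fraction=k["bg"] / n["bg"],
        z=float(z), p=float(p),
        n_focal=int(n["focal"]), n_background=int(n["bg"]),
    )


def clusters_table(clusters: list[SRNACluster]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": c.chrom, "start": c.start, "end": c.end,
        "count": c.count, "strand_bias": round(c.strand_bias, 4),
        "u1_fraction": round(c.u1_fraction, 4),
        "mean_length": round(c.mean_length, 3),
    } for c in clusters], columns=["chrom", "start", "end", "count",
                                   "strand_bias", "u1_fraction", "mean_length"])
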