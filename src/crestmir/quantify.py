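"""Hairpin- and arm-level counting, isomiR classification, arm switching.

A read contributes its full count to every annotated hairpin whose
interval fully contains one of its loci on the same strand (the
multi-mapper policy the repeat-cluster isoforms require; a fractional
alternative is available). RPM uses the per-library genome-matched
totals as denominator. Arm-level counts split each hairpin at the
terminal-loop midpoint of its fold; the 5p ratio r = 5p/(5p+3p) drives
tissue arm-switch detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

import numpy as np
import pandas as pd

from .annotate import HairpinLocus
from .mapping import MatchLocus


@dataclass
class CountMatrix:
    raw: pd.DataFrame                # rows: hairpin (or arm) ids, cols: libraries
    rpm: pd.DataFrame
    tissue_map: dict[str, str]       # library -> tissue
    matched_totals: pd.Series        # genome-matched reads per library

    def tissues(self) -> list[str]:
        seen = {}
        for lib in self.raw.columns:
            seen.setdefault(self.tissue_map[lib], None)
        return list(seen)

    def replicate_mean_rpm(self) -> pd.DataFrame:
        """RPM averaged over the biological replicates of each tissue."""
        groups = defaultdict(list)
        for lib in self.rpm.columns:
            groups[self.tissue_map[lib]].append(lib)
        return pd.DataFrame({t: self.rpm[libs].mean(axis=1)
                             for t, libs in groups.items()})


def _locus_table(mapping: dict[str, list[MatchLocus]], seq_index: dict[str, int]):
    """Per (chrom, strand): arrays of (start, end, seq_row) sorted by start."""
    buckets: dict[tuple[str, str], list[tuple[int, int, int]]] = defaultdict(list)
    for seq, loci in mapping.items():
        row = seq_index.get(seq)
        if row is None:
            continue
        for m in loci:
            buckets[(m.chrom, m.strand)].append((m.start, m.end, row))
    out = {}
    for key, rows in buckets.items():
        rows.sort()
        arr = np.array(rows, dtype=np.int64)
        out[key] = (arr[:, 0], arr[:, 1], arr[:, 2])
    return out


def count_to_hairpins(mapping: dict[str, list[MatchLocus]],
                      hairpins: list[HairpinLocus],
                      collapsed, matched_totals: pd.Series,
                      tissue_map: dict[str, str],
                      multimap: str = "full") -> CountMatrix:
    """Per-hairpin per-library read counts (full-containment, same strand).

    ``multimap='full'`` gives every containing hairpin the read's full
    count; ``'fractional'`` splits the count evenly over the hairpins
    that contain the read.
    """
    if multimap not in ("full", "fractional"):
        raise ValueError("multimap must be 'full' or 'fractional'")
    seq_index = {s: i for i, s in enumerate(collapsed.sequences)}
    table = _locus_table(mapping, seq_index)
    rows_per_seq: dict[int, list[int]] = defaultdict(list)
    for hi, h in enumerate(hairpins):
        key = (h.chrom, h.strand)
        if key not in table:
            continue
        starts, ends, seq_rows = table[key]
        lo = np.searchsorted(starts, h.start, side="left")
        hi_i = np.searchsorted(starts, h.end, side="right")
        sel = np.flatnonzero(ends[lo:hi_i] <= h.end) + lo
        for r in set(seq_rows[sel].tolist()):
            rows_per_seq[r].append(hi)
    raw = np.zeros((len(hairpins), len(collapsed.libraries)))
    for r, his in rows_per_seq.items():
        weight = 1.0 if multimap == "full" else 1.0 / len(his)
        for hi in his:
            raw[hi] += collapsed.counts[r] * weight
    ids = [h.id for h in hairpins]
    raw_df = pd.DataFrame(raw, index=ids, columns=collapsed.libraries)
    if multimap == "full":
        raw_df = raw_df.astype(np.int64)
    rpm = raw_df / matched_totals.reindex(raw_df.columns) * 1e6
    return CountMatrix(raw=raw_df, rpm=rpm, tissue_map=dict(tissue_map),
                       matched_totals=matched_totals)


def count_arms(mapping: dict[str, list[MatchLocus]],
               hairpins: list[HairpinLocus],
               collapsed, matched_totals: pd.Series,
               tissue_map: dict[str, str]) -> CountMatrix:
    """Arm-level counts: rows ``<hairpin>|5p`` / ``<hairpin>|3p``.

    A read belongs to the arm on its side of the terminal-loop
    midpoint; reads crossing the midpoint span the loop and are
    excluded.
    """
    seq_index = {s: i for i, s in enumerate(collapsed.sequences)}
    table = _locus_table(mapping, seq_index)
    ids = []
    raw = []
    for h in hairpins:
        mid_hp = h.fold.loop_midpoint
        c5 = np.zeros(len(collapsed.libraries))
        c3 = np.zeros(len(collapsed.libraries))
        key = (h.chrom, h.strand)
        if key in table:
            starts, ends, seq_rows = table[key]
            lo = np.searchsorted(starts, h.start, side="left")
            hi_i = np.searchsorted(starts, h.end, side="right")
            for s, e, r in zip(starts[lo:hi_i], ends[lo:hi_i], seq_rows[lo:hi_i]):
                if e > h.end:
                    continue
                hs, he = h.hairpin_pos(MatchLocus(h.chrom, int(s), int(e), h.strand))
                if he <= mid_hp:
                    c5 += collapsed.counts[r]
                elif hs >= mid_hp:
                    c3 += collapsed.counts[r]
        ids.extend([f"{h.id}|5p", f"{h.id}|3p"])
        raw.append(c5)
        raw.append(c3)
    raw_df = pd.DataFrame(np.array(raw) if raw else np.zeros((0, len(collapsed.libraries))),
                          index=ids, columns=collapsed.libraries).astype(np.int64)
    rpm = raw_df / matched_totals.reindex(raw_df.columns) * 1e6
    return CountMatrix(raw=raw_df, rpm=rpm, tissue_map=dict(tissue_map),
                       matched_totals=matched_totals)


def reads_by_hairpin(hairpins: list[HairpinLocus],
                     mapping: dict[str, list[MatchLocus]],
                     collapsed) -> dict[str, list[tuple[str, int, int, float]]]:
    """One-pass lookup of reads fully inside each hairpin.

    Returns, per hairpin id, ``(sequence, hp_start, hp_end, total_count)``
    with coordinates on the oriented hairpin.
    """
    seq_index = {s: i for i, s in enumerate(collapsed.sequences)}
    totals = collapsed.total_counts()
    table = _locus_table(mapping, seq_index)
    out: dict[str, list[tuple[str, int, int, float]]] = {h.id: [] for h in hairpins}
    for h in hairpins:
        key = (h.chrom, h.strand)
        if key not in table:
            continue
        starts, ends, seq_rows = table[key]
        lo = np.searchsorted(starts, h.start, side="left")
        hi_i = np.searchsorted(starts, h.end, side="right")
        seen: set[int] = set()
        for s, e, r in zip(starts[lo:hi_i], ends[lo:hi_i], seq_rows[lo:hi_i]):
            if e > h.end or r in seen:
                continue
            seen.add(int(r))
            hs, he = h.hairpin_pos(MatchLocus(h.chrom, int(s), int(e), h.strand))
            out[h.id].append((collapsed.sequences[r], hs, he, float(totals[r])))
    return out


# ---------------------------------------------------------------------------
# isomiRs
# ---------------------------------------------------------------------------

@dataclass
class IsomiRRecord:
    hairpin: str
    arm: str                 # 5p | 3p
    seq: str
    offset5: int             # signed nt vs the reference mature 5' end
    offset3: int             # signed nt vs the reference mature 3' end
    counts: pd.Series        # per-library counts


def isomir_offsets(variant_start: int, variant_end: int,
                   ref_start: int, ref_end: int) -> tuple[int, int]:
    """Signed 5'/3' end offsets of a variant vs its reference mature.

    Both intervals are in hairpin coordinates (5'->3'), so the offsets
    are plain end differences. Raises if the two do not overlap.
    """
    if min(variant_end, ref_end) <= max(variant_start, ref_start):
        raise ValueError("variant does not overlap the reference mature")
    return variant_start - ref_start, variant_end - ref_end


def classify_isomirs(hairpin: HairpinLocus,
                     mapping: dict[str, list[MatchLocus]] | None = None,
                     collapsed=None, max_offset: int = 5,
                     reads: list[tuple[str, int, int, float]] | None = None,
                     frame: pd.DataFrame | None = None) -> list[IsomiRRecord]:
    """All isomiR variants of both reference matures of one hairpin.

    ``reads`` (from :func:`reads_by_hairpin`) and ``frame`` (the
    collapsed count frame) can be precomputed to classify many hairpins
    without rescanning the mapping.
    """
    refs = {}
    if hairpin.mature_5p:
        seq, s = hairpin.mature_5p
        refs["5p"] = (s, s + len(seq))
    if hairpin.mature_3p:
        seq, s = hairpin.mature_3p
        refs["3p"] = (s, s + len(seq))
    if frame is None:
        frame = collapsed.to_frame()
    if reads is None:
        reads = reads_by_hairpin([hairpin], mapping, collapsed)[hairpin.id]
    out: list[IsomiRRecord] = []
    for seq, hs, he, _cnt in reads:
        for arm, (rs, re_) in refs.items():
            if min(he, re_) <= max(hs, rs):
                continue
            d5, d3 = isomir_offsets(hs, he, rs, re_)
            if abs(d5) > max_offset or abs(d3) > max_offset:
                continue
            out.append(IsomiRRecord(hairpin=hairpin.id, arm=arm, seq=seq,
                                    offset5=d5, offset3=d3,
                                    counts=frame.loc[seq]))
    out.sort(key=lambda r: (r.arm, r.offset5, r.offset3, r.seq))
    return out


def isomir_table(records: list[IsomiRRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"hairpin": r.hairpin, "arm": r.arm, "sequence": r.seq,
               "offset5": r.offset5, "offset3": r.offset3}
        row.update({lib: int(c) for lib, c in r.counts.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# arm switching
# ---------------------------------------------------------------------------

def arm_profiles(arm_counts: CountMatrix) -> pd.DataFrame:
    """Long table: hairpin x library with c5, c3 and r = 5p/(5p+3p).

    r is NaN (flagged) where 5p + 3p = 0.
    """
    raw = arm_counts.raw
    hairpins = sorted({i.rsplit("|", 1)[0] for i in raw.index})
    rows = []
    for hp in hairpins:
        c5 = raw.loc[f"{hp}|5p"] if f"{hp}|5p" in raw.index else 0
        c3 = raw.loc[f"{hp}|3p"] if f"{hp}|3p" in raw.index else 0
        for lib in raw.columns:
            n5 = int(c5[lib]) if hasattr(c5, "__getitem__") else 0
            n3 = int(c3[lib]) if hasattr(c3, "__getitem__") else 0
            tot = n5 + n3
            rows.append({
                "hairpin": hp, "library": lib,
                "tissue": arm_counts.tissue_map[lib],
                "c5": n5, "c3": n3, "total": tot,
                "r": n5 / tot if tot > 0 else np.nan,
            })
    return pd.DataFrame(rows)


def detect_arm_switch(profiles: pd.DataFrame, tissue_a: str, tissue_b: str,
                      hi: float = 0.7, lo: float = 0.3,
                      min_total: int = 50) -> pd.DataFrame:
    """Hairpins whose replicate-mean 5p ratio flips between two tissues.

    Libraries with arm total < ``min_total`` are excluded; a hairpin
    with no qualifying library in a tissue is reported as
    insufficient-data. Flagged iff mean r >= hi in one tissue and
    <= lo in the other.
    """
    for t in (tissue_a, tissue_b):
        if t not in set(profiles["tissue"]):
            raise ValueError(f"tissue label {t!r} absent from profiles")
    rows = []
    for hp, grp in profiles.groupby("hairpin", sort=True):
        means = {}
        enough = True
        for t in (tissue_a, tissue_b):
            sub = grp[(grp["tissue"] == t) & (grp["total"] >= min_total)]
            if len(sub) == 0:
                enough = False
                means[t] = np.nan
            else:
                means[t] = float(sub["r"].mean())
        ra, rb = means[tissue_a], means[tissue_b]
        switched = bool(enough and ((ra >= hi and rb <= lo)
                                    or (rb >= hi and ra <= lo)))
        rows.append({"hairpin": hp, f"r_{tissue_a}": ra, f"r_{tissue_b}": rb,
                     "status": "ok" if enough else "insufficient_data",
                     "switched": switched})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tissue profiling views
# ---------------------------------------------------------------------------

def profile_views(matrix: CountMatrix, families: dict[str, str],
                  exclude: list[str] = ("mir-427",), n: int = 10) -> dict:
    """Top-n tables, family read fractions, and the heatmap matrix.

    ``families`` maps hairpin id -> family. The top-n per tissue ranks
    replicate-mean RPM after excluding the listed families (the views
    exclude the dominant miR-427 family); family fractions are computed
    over all miRNA-row reads per tissue; the heatmap is the
    replicate-mean RPM matrix.

    Family fractions are a read-level share: pass a matrix built with
    ``multimap='fractional'`` so that a repeat-cluster read is counted
    once, not once per copy.
    """
    mean_rpm = matrix.replicate_mean_rpm()
    fam = pd.Series({i: families.get(i, i) for i in matrix.raw.index})

    tissue_raw = defaultdict(lambda: 0.0)
    groups = defaultdict(list)
    for lib in matrix.raw.columns:
        groups[matrix.tissue_map[lib]].append(lib)
    fam_frac = {}
    for t, libs in groups.items():
        per_fam = matrix.raw[libs].sum(axis=1).groupby(fam).sum()
        total = per_fam.sum()
        fam_frac[t] = per_fam / total if total > 0 else per_fam * np.nan
    family_fraction = pd.DataFrame(fam_frac)

    keep = ~fam.isin(list(exclude))
    top = {}
    for t in mean_rpm.columns:
        ranked = mean_rpm.loc[keep.values, t].sort_values(ascending=False)
        top[t] = ranked.head(min(n, len(ranked)))
    return {"top": top, "family_fraction": family_fraction, "heatmap": mean_rpm}
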