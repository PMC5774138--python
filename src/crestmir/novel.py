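"""Rule-based prediction of novel miRNA hairpins from read stacks.

The predictor distils the consensus core of the standard miRNA
discovery tools into explicit, testable rules: (1) tight same-strand
read stacks (gap <= 3 nt, span <= 40 nt, total count >= 10) outside
annotated hairpins; (2) precise 5' processing (>= 80% of stack counts
share the modal 5' end); (3) a window around the stack that folds into
a validated single stem-loop with the dominant read fully inside one
stem arm — among passing windows of 60-200 nt the LONGEST wins (ties:
highest paired fraction, then leftmost); (4) star-strand support is
flagged when opposite-arm reads form a duplex with the mature showing
the Dicer-typical 2-nt 3' overhang (+-1 nt).

Predictions are grouped single-linkage: two matures share a group iff
they are identical or differ only by end offsets of <= 2 nt.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import HairpinLocus
from .fold import fold_hairpin, validate_hairpin
from .io import revcomp
from .mapping import MatchLocus

WINDOW_MIN, WINDOW_MAX, WINDOW_STEP = 60, 200, 10
WINDOW_FLANK = 5


@dataclass
class CandidateStack:
    chrom: str
    strand: str
    start: int
    end: int
    members: dict[str, tuple[int, int, float]]  # seq -> (start, end, count)
    total: float
    dominant: str
    homogeneity5: float
    star_candidates: list[tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class NovelPrediction:
    hairpin: HairpinLocus
    mature: str
    mature_hp: tuple[int, int]   # interval on the hairpin
    star_support: bool
    group: int | None = None


def _masked(start: int, end: int, mask: list[tuple[int, int]]) -> bool:
    return any(start < e and end > s for s, e in mask)


def find_stacks(mapping: dict[str, list[MatchLocus]], total_counts: dict[str, float],
                masked_hairpins: list[HairpinLocus] = (),
                min_count: float = 10, max_gap: int = 3,
                max_span: int = 40) -> list[CandidateStack]:
    """Cluster same-strand read loci into candidate mature stacks."""
    mask: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for h in masked_hairpins:
        mask[h.chrom].append((h.start, h.end))
    loci: dict[tuple[str, str], list[tuple[int, int, str]]] = defaultdict(list)
    for seq, ms in mapping.items():
        cnt = total_counts.get(seq, 0)
        if cnt <= 0:
            continue
        for m in ms:
            if _masked(m.start, m.end, mask.get(m.chrom, ())):
                continue
            loci[(m.chrom, m.strand)].append((m.start, m.end, seq))
    stacks: list[CandidateStack] = []
    for (chrom, strand), rows in sorted(loci.items()):
        rows.sort()
        cluster: list[tuple[int, int, str]] = []
        cur_end = -1
        for s, e, seq in rows + [(1 << 60, 1 << 60, "")]:
            if cluster and s - cur_end > max_gap:
                stacks.extend(
                    _finish_stack(chrom, strand, cluster, total_counts,
                                  min_count, max_span))
                cluster = []
                cur_end = -1
            if seq:
                cluster.append((s, e, seq))
                cur_end = max(cur_end, e)
    stacks.sort(key=lambda st: (st.chrom, st.start, st.strand))
    return stacks


def _finish_stack(chrom, strand, cluster, total_counts, min_count, max_span):
    start = min(s for s, _, _ in cluster)
    end = max(e for _, e, _ in cluster)
    members = {}
    total = 0.0
    for s, e, seq in cluster:
        c = total_counts[seq]
        members[seq] = (s, e, c)
        total += c
    if total < min_count or end - start > max_span:
        return []
    # 5' end: genomic start on '+', genomic end on '-'
    five_prime = defaultdict(float)
    for s, e, c in members.values():
        five_prime[s if strand == "+" else e] += c
    homogeneity = max(five_prime.values()) / total
    dominant = max(members, key=lambda q: (members[q][2], _inv(q)))
    return [CandidateStack(chrom=chrom, strand=strand, start=start, end=end,
                           members=members, total=total, dominant=dominant,
                           homogeneity5=homogeneity)]


class _inv(str):
    def __lt__(self, other):
        return str.__gt__(self, other)
    def __gt__(self, other):
        return str.__lt__(self, other)


def _window_coords(stack: CandidateStack, chrom_len: int):
    """Candidate (start, end) windows of 60-200 nt containing the stack."""
    out = []
    for L in range(WINDOW_MIN, WINDOW_MAX + 1, WINDOW_STEP):
        if L < stack.span + 2 * WINDOW_FLANK:
            continue
        anchors = {
            stack.start - WINDOW_FLANK,                      # stack at 5' edge
            stack.end + WINDOW_FLANK - L,                    # stack at 3' edge
            (stack.start + stack.end) // 2 - L // 2,         # centred
        }
        for ws in sorted(anchors):
            ws = max(0, min(ws, chrom_len - L))
            if ws <= stack.start - 1 and ws + L >= stack.end + 1:
                out.append((ws, ws + L))
    return sorted(set(out), key=lambda w: (w[1] - w[0], w[0]))


def call_novel(stack: CandidateStack, genome: dict[str, str],
               min_homogeneity: float = 0.8, stem_min: int = 15,
               paired_fraction_min: float = 0.4,
               ) -> tuple[NovelPrediction | None, str]:
    """Call one stack; returns (prediction, reason)."""
    if stack.homogeneity5 < min_homogeneity:
        return None, "imprecise_processing"
    chrom_seq = genome[stack.chrom]
    dom_s, dom_e, _ = stack.members[stack.dominant]
    best = None   # (length, paired_fraction, -start, payload)
    for ws, we in _window_coords(stack, len(chrom_seq)):
        seq = chrom_seq[ws:we].upper()
        if stack.strand == "-":
            seq = revcomp(seq)
        fold = fold_hairpin(seq)
        ok, _reason = validate_hairpin(fold, seq, stem_min=stem_min,
                                       paired_fraction_min=paired_fraction_min)
        if not ok or fold.stem_arms is None:
            continue
        # dominant read on the oriented window
        if stack.strand == "+":
            hs, he = dom_s - ws, dom_e - ws
        else:
            hs, he = we - dom_e, we - dom_s
        (l5s, l5e), (l3s, l3e) = fold.stem_arms
        if l5s <= hs and he <= l5e:
            arm = "5p"
        elif l3s <= hs and he <= l3e:
            arm = "3p"
        else:
            continue
        key = (we - ws, fold.paired_fraction, -ws)
        if best is None or key > best[0]:
            best = (key, (ws, we, seq, fold, hs, he, arm))
    if best is None:
        return None, "no_hairpin"
    ws, we, seq, fold, hs, he, arm = best[1]
    star = _star_support(stack, fold, hs, he, ws, we)
    hairpin = HairpinLocus(
        id=f"novel_{stack.chrom}_{ws}_{stack.strand}",
        family="novel", chrom=stack.chrom, start=ws, end=we,
        strand=stack.strand, seq=seq, fold=fold, provenance="novel",
    )
    setattr(hairpin, "mature_5p" if arm == "5p" else "mature_3p",
            (stack.dominant, hs))
    pred = NovelPrediction(hairpin=hairpin, mature=stack.dominant,
                           mature_hp=(hs, he), star_support=star)
    return pred, "ok"


def _partner(fold, pos: int, search: int = 3) -> int | None:
    """Pairing partner of a position, tolerating small unpaired offsets."""
    for d in range(search + 1):
        for p in (pos - d, pos + d):
            j = fold.partner.get(p)
            if j is not None:
                # re-project so that the returned partner corresponds to pos
                return j + (pos - p) * (-1)
    return None


def _star_support(stack: CandidateStack, fold, mat_s: int, mat_e: int,
                  ws: int, we: int, tol: int = 1) -> bool:
    """Opposite-arm reads forming a 2-nt 3'-overhang duplex with the mature."""
    p_start = _partner(fold, mat_s)
    if p_start is None:
        return False
    for hs, he in getattr(stack, "star_candidates", []):
        # duplex overhangs: star 3' end vs partner of mature 5' start,
        # and mature 3' end vs partner of star 5' start
        o1 = (he - 1) - p_start
        p_star = _partner(fold, hs)
        if p_star is None:
            continue
        o2 = (mat_e - 1) - p_star
        if abs(o1 - 2) <= tol and abs(o2 - 2) <= tol:
            return True
    return False


def predict_novel(mapping: dict[str, list[MatchLocus]],
                  total_counts: dict[str, float],
                  genome: dict[str, str],
                  known_hairpins: list[HairpinLocus] = (),
                  min_count: float = 10,
                  min_homogeneity: float = 0.8) -> tuple[list[NovelPrediction],
                                                         pd.DataFrame]:
    """Full novel-prediction pass; returns predictions and an audit table."""
    stacks = find_stacks(mapping, total_counts, masked_hairpins=known_hairpins,
                         min_count=min_count)
    preds: list[NovelPrediction] = []
    audit = []
    for st in stacks:
        pred, reason = call_novel(st, genome, min_homogeneity=min_homogeneity)
        if pred is not None:
            _fill_star(pred, st, stacks)
            preds.append(pred)
        audit.append({"chrom": st.chrom, "start": st.start, "end": st.end,
                      "strand": st.strand, "total": st.total,
                      "homogeneity5": round(st.homogeneity5, 4),
                      "status": "called" if pred else "rejected",
                      "reason": reason})
    group_predictions(preds)
    return preds, pd.DataFrame(
        audit, columns=["chrom", "start", "end", "strand", "total",
                        "homogeneity5", "status", "reason"])


def _fill_star(pred: NovelPrediction, stack: CandidateStack,
               stacks: list[CandidateStack]) -> None:
    """Re-evaluate star support using neighbouring opposite-arm stacks."""
    h = pred.hairpin
    cand = []
    for other in stacks:
        if other is stack or other.chrom != h.chrom or other.strand != h.strand:
            continue
        if other.start >= h.start and other.end <= h.end:
            for s, e, _c in other.members.values():
                if h.strand == "+":
                    cand.append((s - h.start, e - h.start))
                else:
                    cand.append((h.end - e, h.end - s))
    stack.star_candidates = cand
    pred.star_support = _star_support(stack, h.fold, *pred.mature_hp, h.start,
                                      h.end)


def matures_equivalent(a: str, b: str, max_offset: int = 2) -> bool:
    """True iff the two matures differ only by 5'/3' end offsets <= 2 nt."""
    for o in range(-max_offset, max_offset + 1):
        # b starts at offset o relative to a
        end_diff = (o + len(b)) - len(a)
        if abs(end_diff) > max_offset:
            continue
        s = max(0, o)
        e = min(len(a), o + len(b))
        if e <= s:
            continue
        if a[s:e] == b[s - o:e - o]:
            return True
    return False


def group_predictions(predictions: list[NovelPrediction]) -> dict:
    """Single-linkage grouping by mature-sequence equivalence.

    Assigns ``group`` ids in place and returns the summary counts:
    hairpins, groups, unique matures.
    """
    n = len(predictions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if matures_equivalent(predictions[i].mature, predictions[j].mature):
                parent[find(i)] = find(j)
    roots = {}
    for i, pred in enumerate(predictions):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
        pred.group = roots[r]
    return {
        "hairpins": n,
        "groups": len(roots),
        "unique_matures": len({p.mature for p in predictions}),
    }


def predictions_table(predictions: list[NovelPrediction]) -> pd.DataFrame:
    rows = [{
        "hairpin": p.hairpin.id, "chrom": p.hairpin.chrom,
        "start": p.hairpin.start, "end": p.hairpin.end,
        "strand": p.hairpin.strand, "mature": p.mature,
        "star_support": p.star_support, "group": p.group,
    } for p in predictions]
    return pd.DataFrame(rows, columns=["hairpin", "chrom", "start", "end",
                                       "strand", "mature", "star_support",
                                       "group"])
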