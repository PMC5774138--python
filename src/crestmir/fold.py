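"""RNA secondary structure by maximum base pairing (Nussinov DP).

The annotation and novel-prediction stages only need a deterministic,
auditable structure check — does a candidate locus fold into a single
clean stem-loop? — so the fold is the classic maximum-pairing dynamic
programme (Watson-Crick plus GU wobble, minimum loop 3) rather than a
thermodynamic model. Validation criteria on top of the fold make the
"typical hairpin structure" call explicit: one dominant terminal loop,
a stem of at least ``stem_min`` pairs, and a paired fraction of at
least ``paired_fraction_min``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from numba import njit

MIN_LOOP = 3
#: minimal number of stacked pairs for a terminal loop to count as a stem
STEM_COUNT_MIN = 4
#: a junction enclosing at most this many nt is a terminal loop, not a fork
LOOP_SPAN_MAX = 30

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# allowed pairs: AU, UA, GC, CG, GU, UG
_PAIRABLE = np.zeros((4, 4), dtype=np.bool_)
for _a, _b in [(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]:
    _PAIRABLE[_a, _b] = True


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENCODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - contract violation
        raise ValueError(f"non-ACGTU base in sequence: {exc}") from None


@njit(cache=True)
def _nussinov_table(x, pairable, min_loop):
    n = x.shape[0]
    dp = np.zeros((n, n), dtype=np.int16)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if pairable[x[i], x[k]]:
                    inner = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    outer = dp[k + 1, j] if k + 1 <= j else 0
                    cand = inner + outer + 1
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp


def _traceback(dp: np.ndarray, x: np.ndarray) -> list[tuple[int, int]]:
    """Recover one optimal nested pairing.

    Deterministic tie-break: leave i unpaired if that is optimal,
    otherwise pair i with the smallest j achieving the optimum.
    """
    pairs: list[tuple[int, int]] = []
    stack = [(0, x.shape[0] - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        if dp[i, j] == dp[i + 1, j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + MIN_LOOP + 1, j + 1):
            if not _PAIRABLE[x[i], x[k]]:
                continue
            inner = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
            outer = dp[k + 1, j] if k + 1 <= j else 0
            if inner + outer + 1 == dp[i, j]:
                pairs.append((i, k))
                stack.append((i + 1, k - 1))
                if k + 1 <= j:
                    stack.append((k + 1, j))
                break
    pairs.sort()
    return pairs


@dataclass
class StructureFold:
    """A nested pairing of a sequence."""

    seq_len: int
    pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_paired(self) -> int:
        return len(self.pairs)

    @property
    def paired_fraction(self) -> float:
        return 2.0 * len(self.pairs) / self.seq_len if self.seq_len else 0.0

    @cached_property
    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    @cached_property
    def _forest(self):
        """Nesting forest of pairs: (children, subtree_pair_counts, roots)."""
        pairs = self.pairs  # sorted by i; nested (non-crossing)
        children: dict[int, list[int]] = {k: [] for k in range(len(pairs))}
        roots: list[int] = []
        stack: list[int] = []
        for k, (i, j) in enumerate(pairs):
            while stack and pairs[stack[-1]][1] < i:
                stack.pop()
            if stack:
                children[stack[-1]].append(k)
            else:
                roots.append(k)
            stack.append(k)
        subtree = [1] * len(pairs)
        for k in range(len(pairs) - 1, -1, -1):
            for c in children[k]:
                subtree[k] += subtree[c]
        return children, subtree, roots

    @cached_property
    def stems(self) -> list[tuple[list[int], bool]]:
        """Maximal helix chains ``(pair indices, ends_in_loop)``.

        A chain follows single-child nesting; a branch with at most one
        substantial child subtree (>= 3 pairs) continues through that
        child — smaller siblings are fold noise, not real stems. A
        junction enclosing no more than ``LOOP_SPAN_MAX`` nt is a
        terminal loop with internal substructure (which is swallowed),
        so ``ends_in_loop`` is True there and at plain hairpin loops,
        False at genuine multi-branch junctions.
        """
        children, subtree, roots = self._forest
        chains: list[tuple[list[int], bool]] = []
        agenda = list(roots)
        while agenda:
            k = agenda.pop()
            chain = [k]
            while True:
                kids = children[chain[-1]]
                big = [c for c in kids if subtree[c] >= 3]
                if len(kids) == 1:
                    chain.append(kids[0])
                    continue
                if len(big) == 1:
                    agenda.extend(c for c in kids if c != big[0])
                    chain.append(big[0])
                    continue
                i, j = self.pairs[chain[-1]]
                if len(big) == 0 or j - i - 1 <= LOOP_SPAN_MAX:
                    chains.append((chain, True))   # loop (maybe with noise)
                else:
                    agenda.extend(kids)
                    chains.append((chain, False))  # multi-branch junction
                break
        return chains

    @cached_property
    def terminal_loops(self) -> list[tuple[int, int, int]]:
        """Hairpin loops as ``(i, j, stem_depth)`` of their closing pair.

        ``stem_depth`` is the length of the unbranched helix chain
        (bulges included) closing the loop.
        """
        out = []
        for chain, ends_in_loop in self.stems:
            if not ends_in_loop:
                continue
            i, j = self.pairs[chain[-1]]
            out.append((i, j, len(chain)))
        out.sort(key=lambda t: t[0])
        return out

    @cached_property
    def main_loop(self) -> tuple[int, int, int] | None:
        """The terminal loop with the deepest stem (ties: leftmost)."""
        if not self.terminal_loops:
            return None
        return max(self.terminal_loops, key=lambda t: (t[2], -t[0]))

    @property
    def loop_len(self) -> int:
        if self.main_loop is None:
            return 0
        i, j, _ = self.main_loop
        return j - i - 1

    @cached_property
    def stem_arms(self) -> tuple[tuple[int, int], tuple[int, int]] | None:
        """Half-open 5' and 3' intervals spanned by the main stem."""
        if self.main_loop is None:
            return None
        i, j, _ = self.main_loop
        for chain, ends_in_loop in self.stems:
            if ends_in_loop and self.pairs[chain[-1]] == (i, j):
                ps = [self.pairs[k] for k in chain]
                left = (min(a for a, _ in ps), max(a for a, _ in ps) + 1)
                right = (min(b for _, b in ps), max(b for _, b in ps) + 1)
                return left, right
        return None

    @cached_property
    def longest_helix_run(self) -> int:
        """Longest run of consecutively stacked pairs (i,j),(i+1,j-1),..."""
        pairs = set(self.pairs)
        best = 0
        for i, j in self.pairs:
            if (i - 1, j + 1) in pairs:
                continue
            run = 1
            while (i + run, j - run) in pairs:
                run += 1
            best = max(best, run)
        return best

    @property
    def loop_midpoint(self) -> int:
        """Split point between the 5' and 3' sides of the hairpin."""
        if self.main_loop is None:
            return self.seq_len // 2
        i, j, _ = self.main_loop
        return (i + j + 1) // 2


def fold_hairpin(seq: str) -> StructureFold:
    """Maximum-pairing fold of a candidate hairpin (20-300 nt)."""
    n = len(seq)
    if n < 20 or n > 300:
        raise ValueError(f"hairpin length {n} outside the 20-300 nt range")
    x = encode(seq)
    dp = _nussinov_table(x, _PAIRABLE, MIN_LOOP)
    return StructureFold(seq_len=n, pairs=_traceback(dp, x))


def max_pairing_score(seq: str) -> int:
    """DP optimum without traceback (used by tests and window scans)."""
    x = encode(seq)
    if x.shape[0] <= MIN_LOOP:
        return 0
    return int(_nussinov_table(x, _PAIRABLE, MIN_LOOP)[0, x.shape[0] - 1])


def validate_hairpin(
    fold: StructureFold,
    seq: str,
    stem_min: int = 15,
    paired_fraction_min: float = 0.4,
    helix_min: int = 8,
) -> tuple[bool, str | None]:
    """Pass/fail check that a fold looks like a canonical pre-miRNA.

    Checks, in order: overall paired fraction, a single dominant
    terminal loop (stems shallower than ``STEM_COUNT_MIN`` pairs are
    ignored as fold noise), a main stem of >= ``stem_min`` pairs, and a
    contiguous helix of >= ``helix_min`` stacked pairs — maximum-pairing
    folds of random sequence reach deep but heavily bulged stems, and
    the long uninterrupted helix is what separates a genuine pre-miRNA
    stem from that background.
    """
    if fold.paired_fraction < paired_fraction_min:
        return False, "paired_fraction"
    real_loops = [t for t in fold.terminal_loops if t[2] >= STEM_COUNT_MIN]
    if not real_loops:
        return False, "stem_too_short"
    if len(real_loops) > 1:
        return False, "multi_loop"
    if real_loops[0][2] < stem_min:
        return False, "stem_too_short"
    if fold.longest_helix_run < helix_min:
        return False, "helix_too_short"
    return True, None
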