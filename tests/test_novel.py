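"""Novel miRNA prediction: stacks, window calls, grouping."""

import numpy as np
import pytest

from crestmir.io import revcomp
from crestmir.mapping import MatchLocus, map_exact
from crestmir.novel import (CandidateStack, call_novel, find_stacks,
                            group_predictions, matures_equivalent,
                            predict_novel)

BASES = np.array(list("ACGT"))


def rand_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


def make_hairpin(rng, stem=25, loop=13):
    s = rand_seq(rng, stem)
    return s + rand_seq(rng, loop) + revcomp(s)


class TestFindStacks:
    def test_single_sequence_pileup(self):
        rng = np.random.default_rng(0)
        genome = {"c": rand_seq(rng, 500)}
        read = genome["c"][100:122]
        mapping = map_exact([read], genome)
        stacks = find_stacks(mapping, {read: 100.0})
        assert len(stacks) == 1
        st = stacks[0]
        assert (st.start, st.end) == (100, 122)
        assert st.homogeneity5 == 1.0
        assert st.dominant == read

    def test_scattered_single_reads_make_no_stacks(self):
        rng = np.random.default_rng(1)
        genome = {"c": rand_seq(rng, 5000)}
        reads = [genome["c"][i:i + 22] for i in range(0, 4000, 500)]
        mapping = map_exact(reads, genome)
        counts = {r: 1.0 for r in reads}
        assert find_stacks(mapping, counts, min_count=10) == []

    def test_wide_pileups_dropped_by_span(self):
        rng = np.random.default_rng(2)
        genome = {"c": rand_seq(rng, 300)}
        reads = [genome["c"][i:i + 22] for i in range(50, 110, 3)]
        mapping = map_exact(reads, genome)
        counts = {r: 5.0 for r in reads}
        assert find_stacks(mapping, counts, min_count=10, max_span=40) == []

    def test_masked_hairpins_excluded(self, small_study, small_mapping,
                                      small_collapsed, small_annotation):
        hairpins, _ = small_annotation
        totals = dict(zip(small_collapsed.sequences,
                          small_collapsed.total_counts().astype(float)))
        stacks = find_stacks(small_mapping, totals, masked_hairpins=hairpins)
        for st in stacks:
            for h in hairpins:
                if h.chrom == st.chrom:
                    assert st.end <= h.start or st.start >= h.end


def _stack_for(genome, mature_start, mature_len=23, strand="+",
               homogeneity=1.0, chrom="c"):
    seq = genome[chrom][mature_start:mature_start + mature_len]
    if strand == "-":
        seq = revcomp(seq)
    return CandidateStack(
        chrom=chrom, strand=strand, start=mature_start,
        end=mature_start + mature_len,
        members={seq: (mature_start, mature_start + mature_len, 100.0)},
        total=100.0, dominant=seq, homogeneity5=homogeneity)


class TestCallNovel:
    def test_planted_hairpin_called_with_longest_window(self):
        rng = np.random.default_rng(3)
        hp = make_hairpin(rng)
        genome = {"c": rand_seq(rng, 300) + hp + rand_seq(rng, 300)}
        stack = _stack_for(genome, 302)  # 5p arm region of the hairpin
        pred, reason = call_novel(stack, genome)
        assert reason == "ok"
        h = pred.hairpin
        assert h.start <= 300 and h.end >= 300 + len(hp) - 5
        # longest-window rule against exhaustive enumeration of the same
        # candidate set
        from crestmir.novel import _window_coords
        from crestmir.fold import fold_hairpin, validate_hairpin
        best_len = 0
        for ws, we in _window_coords(stack, len(genome["c"])):
            seq = genome["c"][ws:we]
            f = fold_hairpin(seq)
            ok, _ = validate_hairpin(f, seq)
            if ok and f.stem_arms is not None:
                (a, b), (c2, d) = f.stem_arms
                hs, he = stack.start - ws, stack.end - ws
                if (a <= hs and he <= b) or (c2 <= hs and he <= d):
                    best_len = max(best_len, we - ws)
        assert h.end - h.start == best_len

    def test_unstructured_locus_rejected(self):
        rng = np.random.default_rng(4)
        genome = {"c": rand_seq(rng, 800)}
        stack = _stack_for(genome, 400)
        pred, reason = call_novel(stack, genome)
        assert pred is None and reason == "no_hairpin"

    def test_imprecise_processing_rejected(self):
        rng = np.random.default_rng(5)
        hp = make_hairpin(rng)
        genome = {"c": rand_seq(rng, 100) + hp + rand_seq(rng, 100)}
        stack = _stack_for(genome, 102, homogeneity=0.5)
        pred, reason = call_novel(stack, genome)
        assert pred is None and reason == "imprecise_processing"


class TestStarSupport:
    def _planted(self):
        """A perfect stem-loop with matures in canonical Dicer register:
        5p = [2, 25), 3p = [40, 63) of a 25+13+25+2 hairpin, giving the
        2-nt 3' overhang on both duplex ends."""
        rng = np.random.default_rng(6)
        stem = rand_seq(rng, 25)
        # two stem transitions keep arm reads strand-unambiguous (a
        # perfect stem is a palindrome and maps both strands)
        trans = {"A": "G", "G": "A", "C": "T", "T": "C"}
        right = list(revcomp(stem))
        for pos in (5, 15):
            right[pos] = trans[right[pos]]
        hp = stem + rand_seq(rng, 13) + "".join(right) + rand_seq(rng, 2)
        genome = {"c": rand_seq(rng, 200) + hp + rand_seq(rng, 200)}
        return genome, 200, hp

    def test_two_nt_overhang_duplex_flagged(self):
        genome, off, hp = self._planted()
        arm5 = hp[2:25]
        arm3 = hp[40:63]
        mapping = map_exact([arm5, arm3], genome)
        totals = {arm5: 100.0, arm3: 30.0}
        preds, audit = predict_novel(mapping, totals, genome, min_count=10)
        assert len(preds) == 2
        assert all(p.star_support for p in preds)

    def test_no_star_without_opposite_arm_reads(self):
        genome, off, hp = self._planted()
        arm5 = hp[2:25]
        mapping = map_exact([arm5], genome)
        preds, _ = predict_novel(mapping, {arm5: 100.0}, genome, min_count=10)
        assert len(preds) == 1
        assert not preds[0].star_support

    def test_shifted_register_not_starred(self):
        """Opposite-arm reads without the 2-nt 3' overhang register."""
        genome, off, hp = self._planted()
        arm5 = hp[2:25]
        shifted3 = hp[45:63]   # 5' end 5 nt inside the canonical register
        mapping = map_exact([arm5, shifted3], genome)
        preds, _ = predict_novel(mapping, {arm5: 100.0, shifted3: 30.0},
                                 genome, min_count=10)
        by_arm = {p.mature: p for p in preds}
        assert arm5 in by_arm
        assert not by_arm[arm5].star_support


class TestGrouping:
    def test_matures_equivalent_rules(self):
        a = "TAGGTAGTTTCATGTTGTTGGG"
        assert matures_equivalent(a, a)
        assert matures_equivalent(a, a[2:])          # 5' offset 2
        assert matures_equivalent(a, a[:-2])         # 3' offset 2
        assert matures_equivalent(a[1:], a[:-1])
        assert not matures_equivalent(a, a[3:])      # offset 3
        assert not matures_equivalent(a, revcomp(a))

    def _pred(self, mature, idx):
        from crestmir.annotate import HairpinLocus
        from crestmir.fold import StructureFold
        from crestmir.novel import NovelPrediction
        hp = HairpinLocus(id=f"n{idx}", family="novel", chrom="c",
                          start=idx * 100, end=idx * 100 + 60, strand="+",
                          seq="", fold=StructureFold(seq_len=60),
                          provenance="novel")
        return NovelPrediction(hairpin=hp, mature=mature,
                               mature_hp=(0, len(mature)), star_support=False)

    def test_identical_matures_share_group(self):
        m = "ACGTACGTACGTACGTACGTAC"
        preds = [self._pred(m, 0), self._pred(m, 1)]
        counts = group_predictions(preds)
        assert counts == {"hairpins": 2, "groups": 1, "unique_matures": 1}

    def test_disjoint_matures_separate_groups(self):
        preds = [self._pred("A" * 10 + "CGT" * 4, 0),
                 self._pred("G" * 10 + "TTA" * 4, 1)]
        counts = group_predictions(preds)
        assert counts["groups"] == 2

    def test_family_fixture_counts(self):
        """3 copies of one mature (one shifted by 1 nt) + 2 singletons:
        5 hairpins, 3 groups, 4 unique matures."""
        m = "TACGGATTCAGGCATTCAAGGA"
        preds = [self._pred(m, 0), self._pred(m, 1), self._pred(m[1:], 2),
                 self._pred("ACCGGTTTACGGATCAGGTCAA", 3),
                 self._pred("GGGTTTCCCAAATTTGGGACAT", 4)]
        counts = group_predictions(preds)
        assert counts == {"hairpins": 5, "groups": 3, "unique_matures": 4}
        assert preds[0].group == preds[1].group == preds[2].group

    def test_count_constraints(self, small_study, small_mapping,
                               small_collapsed, small_annotation):
        genome, _truth, _libs = small_study
        hairpins, _ = small_annotation
        totals = dict(zip(small_collapsed.sequences,
                          small_collapsed.total_counts().astype(float)))
        preds, _ = predict_novel(small_mapping, totals, genome,
                                 known_hairpins=hairpins)
        counts = group_predictions(preds)
        assert counts["groups"] <= counts["hairpins"]
        assert counts["groups"] <= counts["unique_matures"] or \
            counts["unique_matures"] == 0
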