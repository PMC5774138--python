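"""Counting, isomiR classification, arm switching, profiling views."""

import numpy as np
import pandas as pd
import pytest

from crestmir.annotate import HairpinLocus
from crestmir.fold import fold_hairpin
from crestmir.io import revcomp
from crestmir.mapping import MatchLocus, map_exact
from crestmir.preprocess import CollapsedReadSet
from crestmir.quantify import (CountMatrix, arm_profiles, classify_isomirs,
                               count_arms, count_to_hairpins,
                               detect_arm_switch, isomir_offsets,
                               profile_views, reads_by_hairpin)

BASES = np.array(list("ACGT"))


def _hairpin(chrom, start, seq, hp_id="h1", family="fam", strand="+"):
    return HairpinLocus(id=hp_id, family=family, chrom=chrom, start=start,
                        end=start + len(seq), strand=strand, seq=seq,
                        fold=fold_hairpin(seq))


def _stem_loop(rng, stem=25, loop=13):
    s = "".join(BASES[rng.integers(0, 4, stem)])
    lp = "".join(BASES[rng.integers(0, 4, loop)])
    return s + lp + revcomp(s)


class TestCountToHairpins:
    def _setup(self):
        rng = np.random.default_rng(0)
        hp1 = _stem_loop(rng)
        hp2 = _stem_loop(rng)
        pad = "".join(BASES[rng.integers(0, 4, 50)])
        genome = {"c": pad + hp1 + pad + hp2 + pad}
        h1 = _hairpin("c", 50, hp1, "h1")
        h2 = _hairpin("c", 50 + len(hp1) + 50, hp2, "h2")
        return genome, h1, h2

    def test_full_count_to_containing_hairpin(self):
        genome, h1, h2 = self._setup()
        read = h1.seq[2:25]
        crs = CollapsedReadSet(sequences=[read], counts=np.array([[7]]),
                               libraries=["L1"])
        mapping = map_exact(crs, genome)
        totals = pd.Series([7], index=["L1"])
        cm = count_to_hairpins(mapping, [h1, h2], crs, totals, {"L1": "t"})
        assert cm.raw.loc["h1", "L1"] == 7
        assert cm.raw.loc["h2", "L1"] == 0

    def test_multimapper_full_count_to_every_hairpin(self):
        rng = np.random.default_rng(1)
        hp = _stem_loop(rng)
        genome = {"c": "T" * 30 + hp + "G" * 30 + hp + "T" * 30}
        h1 = _hairpin("c", 30, hp, "h1")
        h2 = _hairpin("c", 30 + len(hp) + 30, hp, "h2")
        read = hp[2:25]
        crs = CollapsedReadSet(sequences=[read], counts=np.array([[10]]),
                               libraries=["L1"])
        mapping = map_exact(crs, genome)
        totals = pd.Series([10], index=["L1"])
        cm = count_to_hairpins(mapping, [h1, h2], crs, totals, {"L1": "t"})
        assert cm.raw.loc["h1", "L1"] == 10 and cm.raw.loc["h2", "L1"] == 10
        frac = count_to_hairpins(mapping, [h1, h2], crs, totals, {"L1": "t"},
                                 multimap="fractional")
        assert frac.raw.loc["h1", "L1"] == pytest.approx(5.0)

    def test_strand_mismatch_not_counted(self):
        # an unstructured interval so the reverse-complement read cannot
        # also occur forward inside it (a perfect stem would contain it)
        rng = np.random.default_rng(5)
        region = "".join(BASES[rng.integers(0, 4, 60)])
        genome = {"c": "T" * 30 + region + "T" * 30}
        h1 = _hairpin("c", 30, region)
        read = revcomp(region[2:25])
        crs = CollapsedReadSet(sequences=[read], counts=np.array([[4]]),
                               libraries=["L1"])
        mapping = map_exact(crs, genome)
        assert all(m.strand == "-" for m in mapping[read])
        cm = count_to_hairpins(mapping, [h1], crs, pd.Series([4], index=["L1"]),
                               {"L1": "t"})
        assert cm.raw.loc["h1", "L1"] == 0

    def test_column_sums_bounded_by_matched_totals(
            self, small_mapping, small_collapsed, small_annotation,
            matched_totals, tissue_map):
        hairpins, _ = small_annotation
        cm = count_to_hairpins(small_mapping, hairpins, small_collapsed,
                               matched_totals, tissue_map,
                               multimap="fractional")
        assert (cm.raw.sum(axis=0) <= matched_totals + 1e-9).all()

    def test_simulated_counts_match_truth_within_noise(
            self, small_study, small_config, small_mapping, small_collapsed,
            small_annotation, matched_totals, tissue_map):
        """Per-hairpin counts track the simulator's expected NB means."""
        from crestmir.simulate import expected_unit_means
        _g, truth, libs = small_study
        hairpins, _ = small_annotation
        cm = count_to_hairpins(small_mapping, hairpins, small_collapsed,
                               matched_totals, tissue_map)
        by_locus = {(t.chrom, t.start, t.end, t.strand): t
                    for t in truth.hairpins}
        lib = libs["NC"].library
        means = expected_unit_means(truth, small_config, "NC")
        checked = 0
        for hp in hairpins:
            t = by_locus.get((hp.chrom, hp.start, hp.end, hp.strand))
            if t is None or t.unit.startswith("mir-427"):
                continue
            mean = means[t.unit]
            if mean < 30:
                continue
            got = cm.raw.loc[hp.id, lib]
            sd = np.sqrt(mean + small_config.nb_dispersion * mean ** 2)
            assert abs(got - mean) < 5 * sd + 10
            checked += 1
        assert checked >= 5


class TestIsomiR:
    def test_offset_arithmetic(self):
        assert isomir_offsets(10, 33, 10, 33) == (0, 0)
        assert isomir_offsets(12, 33, 10, 33) == (2, 0)
        assert isomir_offsets(9, 32, 10, 33) == (-1, -1)

    def test_non_overlapping_variant_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            isomir_offsets(40, 60, 10, 33)

    def test_inverse_consistency(self):
        """reference + offsets reconstructs the variant interval."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            rs, re_ = 10, 33
            d5, d3 = int(rng.integers(-5, 6)), int(rng.integers(-5, 6))
            vs, ve = rs + d5, re_ + d3
            if ve <= vs or min(ve, re_) <= max(vs, rs):
                continue
            assert isomir_offsets(vs, ve, rs, re_) == (d5, d3)

    def test_classification_against_reference(self):
        rng = np.random.default_rng(3)
        hp_seq = _stem_loop(rng)
        genome = {"c": "T" * 20 + hp_seq + "T" * 20}
        h = _hairpin("c", 20, hp_seq)
        h.mature_5p = (hp_seq[2:25], 2)
        variants = [hp_seq[2:25], hp_seq[4:25], hp_seq[2:24]]
        crs = CollapsedReadSet(sequences=sorted(set(variants)),
                               counts=np.array([[5]] * len(set(variants))),
                               libraries=["L1"])
        mapping = map_exact(crs, genome)
        recs = classify_isomirs(h, mapping, crs)
        got = {(r.seq, r.offset5, r.offset3) for r in recs}
        assert (hp_seq[2:25], 0, 0) in got
        assert (hp_seq[4:25], 2, 0) in got
        assert (hp_seq[2:24], 0, -1) in got

    def test_simulated_offset_distribution_recovered(
            self, small_study, small_config, small_mapping, small_collapsed,
            small_annotation):
        """The empirical 5' offset histogram matches the configured
        distribution within multinomial error."""
        from crestmir.annotate import assign_arms
        _g, truth, _libs = small_study
        hairpins, _ = small_annotation
        by_hp = reads_by_hairpin(hairpins, small_mapping, small_collapsed)
        frame = small_collapsed.to_frame()
        by_locus = {(t.chrom, t.start, t.end, t.strand): t
                    for t in truth.hairpins}
        counts = {}
        for hp in hairpins:
            t = by_locus.get((hp.chrom, hp.start, hp.end, hp.strand))
            if t is None:
                continue
            hp.mature_5p = (t.arm5[0], hp.seq.find(t.arm5[0]))
            hp.mature_3p = (t.arm3[0], hp.seq.find(t.arm3[0]))
            for r in classify_isomirs(hp, reads=by_hp[hp.id], frame=frame):
                counts[r.offset5] = counts.get(r.offset5, 0) \
                    + int(r.counts.sum())
        total = sum(counts.values())
        assert total > 5000
        frac0 = counts.get(0, 0) / total
        expected = small_config.isomir_offset_probs["p5"][0]
        assert abs(frac0 - expected) < 0.05


class TestArmSwitch:
    def _profiles(self, data):
        rows = []
        for hp, tissue, lib, c5, c3 in data:
            tot = c5 + c3
            rows.append({"hairpin": hp, "library": lib, "tissue": tissue,
                         "c5": c5, "c3": c3, "total": tot,
                         "r": c5 / tot if tot else np.nan})
        return pd.DataFrame(rows)

    def test_planted_switch_flagged(self):
        data = []
        for i in range(3):
            data.append(("h", "blastula", f"b{i}", 90, 10))
            data.append(("h", "neural", f"n{i}", 5, 95))
        res = detect_arm_switch(self._profiles(data), "blastula", "neural")
        assert res.loc[0, "switched"]

    def test_constant_ratio_not_flagged(self):
        data = []
        for i in range(3):
            data.append(("h", "blastula", f"b{i}", 50, 50))
            data.append(("h", "neural", f"n{i}", 50, 50))
        res = detect_arm_switch(self._profiles(data), "blastula", "neural")
        assert not res.loc[0, "switched"]

    def test_below_min_total_reported_insufficient(self):
        data = [("h", "blastula", "b0", 10, 5), ("h", "neural", "n0", 90, 10)]
        res = detect_arm_switch(self._profiles(data), "blastula", "neural")
        assert res.loc[0, "status"] == "insufficient_data"
        assert not res.loc[0, "switched"]

    def test_unknown_tissue_raises(self):
        data = [("h", "blastula", "b0", 90, 10)]
        with pytest.raises(ValueError, match="absent"):
            detect_arm_switch(self._profiles(data), "blastula", "oviduct")


class TestProfileViews:
    def _matrix(self):
        raw = pd.DataFrame(
            {"L1": [670, 200, 100, 30], "L2": [660, 210, 100, 30]},
            index=["m427_1", "mA_1", "mB_1", "mC_1"])
        totals = pd.Series([1000, 1000], index=["L1", "L2"])
        rpm = raw / totals * 1e6
        return CountMatrix(raw=raw, rpm=rpm,
                           tissue_map={"L1": "NC", "L2": "NC"},
                           matched_totals=totals)

    def test_family_fraction_mirrors_67_percent(self):
        cm = self._matrix()
        fams = {"m427_1": "mir-427", "mA_1": "mir-a", "mB_1": "mir-b",
                "mC_1": "mir-c"}
        views = profile_views(cm, fams)
        assert views["family_fraction"].loc["mir-427", "NC"] == pytest.approx(
            0.665, abs=0.01)

    def test_excluded_family_absent_from_top(self):
        cm = self._matrix()
        fams = {"m427_1": "mir-427", "mA_1": "mir-a", "mB_1": "mir-b",
                "mC_1": "mir-c"}
        views = profile_views(cm, fams, exclude=["mir-427"], n=2)
        top = views["top"]["NC"]
        assert "m427_1" not in top.index
        assert list(top.index) == ["mA_1", "mB_1"]

    def test_n_larger_than_rows_returns_all(self):
        cm = self._matrix()
        views = profile_views(cm, {}, exclude=[], n=100)
        assert len(views["top"]["NC"]) == 4

    def test_heatmap_is_replicate_mean(self):
        cm = self._matrix()
        views = profile_views(cm, {})
        assert views["heatmap"].loc["mA_1", "NC"] == pytest.approx(
            (200 + 210) / 2 * 1000)
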