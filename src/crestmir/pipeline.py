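"""End-to-end orchestration: simulate -> trim -> map -> annotate ->
quantify -> isomiR -> DE -> novel -> 29-nt analysis.

Driven by one flat YAML config; every stage persists its output in a
documented text format and contributes tallies to the run report. All
randomness flows from the single root seed, so a rerun with the same
config is byte-identical (timings live only in report.json).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import (AnnotConfig, HomologySearcher, abundance_filter,
                       annotate_genome, assign_arms, hairpins_to_gff)
from .diffexp import build_enrichment_sets, nb_wald_test, size_factors
from .io import read_fasta, read_fastq, read_gff3, write_fasta, write_gff3, write_json
from .long_srna import (clusters_table, detect_clusters, feature_enrichment,
                        fraction_in_clusters, intervals_from_gff)
from .mapping import GenomeIndex, map_exact, mapping_to_frame, size_class_profile
from .novel import predict_novel, predictions_table
from .preprocess import TrimConfig, collapse, trim_library
from .quantify import (arm_profiles, classify_isomirs, count_arms,
                       count_to_hairpins, detect_arm_switch, isomir_table,
                       profile_views, reads_by_hairpin)
from .simulate import SimConfig, write_study

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, reason: str):
        super().__init__(f"[{stage}] {reason}")
        self.stage = stage
        self.reason = reason


@dataclass
class RunConfig:
    outdir: str = "crestmir_run"
    seed: int = 0
    simulate: SimConfig | None = None
    genome: str | None = None          # used when simulate is None
    precursors: str | None = None
    annotation: str | None = None      # gene-model GFF3
    fastq: dict[str, str] = field(default_factory=dict)   # library -> path
    tissue_map: dict[str, str] = field(default_factory=dict)
    trim: TrimConfig = field(default_factory=TrimConfig)
    annot: AnnotConfig = field(default_factory=AnnotConfig)
    de_alpha: float = 0.01
    tissues: tuple[str, ...] = ("NC", "neural", "ectoderm", "blastula")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "simulate" in kwargs and kwargs["simulate"] is not None:
            sim = dict(kwargs["simulate"])
            sim.setdefault("seed", kwargs.get("seed", 0))
            for key in ("tissues",):
                if key in sim:
                    sim[key] = tuple(sim[key])
            kwargs["simulate"] = SimConfig(**sim)
        if "trim" in kwargs:
            kwargs["trim"] = TrimConfig(**kwargs["trim"])
        if "annot" in kwargs:
            kwargs["annot"] = AnnotConfig(**kwargs["annot"])
        if "tissues" in kwargs:
            kwargs["tissues"] = tuple(kwargs["tissues"])
        return cls(**kwargs)

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("genome", "precursors"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise PipelineError("validate", f"missing input path: {name}")
            for lib, p in self.fastq.items():
                if not Path(p).exists():
                    raise PipelineError("validate", f"missing FASTQ for {lib}")
            if not self.fastq:
                raise PipelineError("validate", "no FASTQ libraries configured")
            missing = set(self.fastq) - set(self.tissue_map)
            if missing:
                raise PipelineError("validate",
                                    f"libraries without tissue label: {missing}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also persisted)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "stages": {}, "seconds": {}}
    t_all = time.time()

    def stage(name):
        logger.info("stage: %s", name)
        return time.time()

    # --- inputs -----------------------------------------------------------
    t = stage("inputs")
    if config.simulate is not None:
        simdir = outdir / "inputs"
        genome, truth, libs = write_study(simdir, config.simulate)
        queries = read_fasta(simdir / "precursors.fa")
        gene_gff = read_gff3(simdir / "genes.gff3")
        fastq_paths = {lib.library: simdir / f"{lib.library}.fastq"
                       for lib in libs}
        tissue_map = {lib.library: lib.tissue for lib in libs}
        report["stages"]["inputs"] = {
            "libraries": len(libs),
            "planted_hairpins": len(truth.hairpins),
        }
    else:
        genome = read_fasta(config.genome)
        queries = read_fasta(config.precursors)
        gene_gff = read_gff3(config.annotation) if config.annotation else None
        fastq_paths = {k: Path(v) for k, v in config.fastq.items()}
        tissue_map = dict(config.tissue_map)
        report["stages"]["inputs"] = {"libraries": len(fastq_paths)}
    report["seconds"]["inputs"] = round(time.time() - t, 2)

    # --- trim + collapse --------------------------------------------------
    t = stage("trim")
    counters = {}
    tallies = {}
    for lib in sorted(fastq_paths):
        seqs = (s for _n, s, _q in read_fastq(fastq_paths[lib]))
        counters[lib], tallies[lib] = trim_library(seqs, config.trim)
    collapsed = collapse(counters, tallies)
    collapsed.write_tsv(outdir / "collapsed.tsv")
    collapsed.write_collapsed_fasta(outdir / "collapsed.fa")
    report["stages"]["trim"] = {lib: tallies[lib] for lib in sorted(tallies)}
    report["seconds"]["trim"] = round(time.time() - t, 2)

    # --- map --------------------------------------------------------------
    t = stage("map")
    index = GenomeIndex(genome)
    mapping = map_exact(collapsed, index)
    mapping_to_frame(mapping).to_csv(outdir / "mapping.tsv", sep="\t", index=False)
    n_mapped = sum(1 for s in mapping if mapping[s])
    if n_mapped == 0:
        raise PipelineError("map", "no sequence mapped to the genome")
    report["stages"]["map"] = {
        "sequences": collapsed.n_sequences, "mapped_sequences": n_mapped}
    report["seconds"]["map"] = round(time.time() - t, 2)

    # --- annotate ---------------------------------------------------------
    t = stage("annotate")
    searcher = HomologySearcher(genome, config.annot)
    hairpins, audit = annotate_genome(genome, queries, config.annot,
                                      searcher=searcher)
    matched_totals = _matched_totals(collapsed, mapping)
    cm_all = count_to_hairpins(mapping, hairpins, collapsed, matched_totals,
                               tissue_map)
    totals = cm_all.raw.sum(axis=1).to_dict()
    hairpins = abundance_filter(hairpins, totals, config.annot)
    by_hp = reads_by_hairpin(hairpins, mapping, collapsed)
    for h in hairpins:
        assign_arms(h, reads=by_hp[h.id])
    audit.to_csv(outdir / "annotation_audit.tsv", sep="\t", index=False)
    write_gff3(outdir / "hairpins.gff3", hairpins_to_gff(hairpins))
    write_fasta(outdir / "hairpins.fa", [(h.id, h.seq) for h in hairpins])
    matures = []
    for h in hairpins:
        for arm, mat in (("5p", h.mature_5p), ("3p", h.mature_3p)):
            if mat is not None:
                matures.append((f"{h.id}-{arm}", mat[0]))
    write_fasta(outdir / "matures.fa", matures)
    report["stages"]["annotate"] = {
        "candidates": int(len(audit)), "hairpins": len(hairpins)}
    report["seconds"]["annotate"] = round(time.time() - t, 2)

    # --- quantify ---------------------------------------------------------
    t = stage("quantify")
    cm = count_to_hairpins(mapping, hairpins, collapsed, matched_totals,
                           tissue_map)
    cm.raw.to_csv(outdir / "hairpin_counts.tsv", sep="\t")
    cm.rpm.to_csv(outdir / "hairpin_rpm.tsv", sep="\t")
    arms = count_arms(mapping, hairpins, collapsed, matched_totals, tissue_map)
    arms.raw.to_csv(outdir / "arm_counts.tsv", sep="\t")
    profile = size_class_profile(
        collapsed, mapping,
        mirna_intervals=[(h.chrom, h.start, h.end, h.strand) for h in hairpins])
    profile.rpm.to_csv(outdir / "size_profile_rpm.tsv", sep="\t")
    if profile.mirna_fraction is not None:
        profile.mirna_fraction.to_csv(outdir / "size_profile_mirna_fraction.tsv",
                                      sep="\t")
    report["stages"]["quantify"] = {
        "hairpin_rows": int(cm.raw.shape[0]),
        "total_hairpin_reads": int(cm.raw.to_numpy().sum()),
    }
    report["seconds"]["quantify"] = round(time.time() - t, 2)

    # --- isomiR + arm switching ------------------------------------------
    t = stage("isomir")
    frame = collapsed.to_frame()
    iso_records = []
    for h in hairpins:
        iso_records.extend(classify_isomirs(h, reads=by_hp[h.id], frame=frame))
    isomir_table(iso_records).to_csv(outdir / "isomirs.tsv", sep="\t",
                                     index=False)
    profiles = arm_profiles(arms)
    profiles.to_csv(outdir / "arm_profiles.tsv", sep="\t", index=False)
    switch_frames = []
    for a, b in itertools.combinations(config.tissues, 2):
        sw = detect_arm_switch(profiles, a, b)
        sw.insert(1, "tissue_a", a)
        sw.insert(2, "tissue_b", b)
        sw = sw.rename(columns={f"r_{a}": "r_a", f"r_{b}": "r_b"})
        switch_frames.append(sw)
    pd.concat(switch_frames, ignore_index=True).to_csv(
        outdir / "arm_switches.tsv", sep="\t", index=False)
    cm_frac = count_to_hairpins(mapping, hairpins, collapsed, matched_totals,
                                tissue_map, multimap="fractional")
    views = profile_views(cm_frac, {h.id: h.family for h in hairpins})
    views["family_fraction"].to_csv(outdir / "family_fraction.tsv", sep="\t")
    views["heatmap"].to_csv(outdir / "heatmap_rpm.tsv", sep="\t")
    top_rows = []
    for tissue, ser in views["top"].items():
        for rank, (hp, rpm) in enumerate(ser.items(), 1):
            top_rows.append({"tissue": tissue, "rank": rank, "hairpin": hp,
                             "mean_rpm": rpm})
    pd.DataFrame(top_rows).to_csv(outdir / "top10.tsv", sep="\t", index=False)
    report["stages"]["isomir"] = {"isomir_records": len(iso_records)}
    report["seconds"]["isomir"] = round(time.time() - t, 2)

    # --- differential expression -----------------------------------------
    t = stage("diffexp")
    sf = size_factors(cm.raw)
    libs_by_tissue = {
        tis: sorted(l for l, tt in tissue_map.items() if tt == tis)
        for tis in config.tissues}
    de_results = {}
    for a, b in itertools.combinations(config.tissues, 2):
        if len(libs_by_tissue[a]) < 2 or len(libs_by_tissue[b]) < 2:
            continue
        res = nb_wald_test(cm.raw, sf, libs_by_tissue[a], libs_by_tissue[b],
                           alpha_level=config.de_alpha)
        de_results[(a, b)] = res
        res.to_csv(outdir / f"de_{a}_vs_{b}.tsv", sep="\t")
    n_pairs = len(list(itertools.combinations(config.tissues, 2)))
    if len(config.tissues) == 4 and len(de_results) == n_pairs:
        sets = build_enrichment_sets(de_results, alpha=config.de_alpha,
                                     tissues=config.tissues)
        write_json(outdir / "enrichment_sets.json", dataclasses.asdict(sets))
        report["stages"]["diffexp"] = {
            "comparisons": len(de_results),
            "nc_enriched": len(sets.nc_enriched),
            "shared_nc_blastula": len(sets.shared_nc_blastula)}
    else:
        report["stages"]["diffexp"] = {"comparisons": len(de_results)}
    report["seconds"]["diffexp"] = round(time.time() - t, 2)

    # --- novel prediction -------------------------------------------------
    t = stage("novel")
    total_counts = dict(zip(collapsed.sequences,
                            collapsed.total_counts().astype(float)))
    preds, novel_audit = predict_novel(mapping, total_counts, genome,
                                       known_hairpins=hairpins)
    predictions_table(preds).to_csv(outdir / "novel_predictions.tsv", sep="\t",
                                    index=False)
    novel_audit.to_csv(outdir / "novel_audit.tsv", sep="\t", index=False)
    write_gff3(outdir / "novel.gff3", hairpins_to_gff([p.hairpin for p in preds]))
    report["stages"]["novel"] = {"stacks": int(len(novel_audit)),
                                 "predictions": len(preds)}
    report["seconds"]["novel"] = round(time.time() - t, 2)

    # --- 29-nt analysis ---------------------------------------------------
    t = stage("long_srna")
    clusters = detect_clusters(mapping, total_counts)
    clusters_table(clusters).to_csv(outdir / "srna_clusters.tsv", sep="\t",
                                    index=False)
    frac = fraction_in_clusters(mapping, total_counts, clusters)
    long_report = {"n_clusters": len(clusters),
                   "fraction_29nt_in_clusters": frac}
    if gene_gff is not None:
        for feature in ("exon", "intron"):
            iv = intervals_from_gff(gene_gff, feature)
            res = feature_enrichment(mapping, total_counts, iv, feature=feature)
            long_report[f"{feature}_enrichment"] = (
                None if res is None else dataclasses.asdict(res))
    write_json(outdir / "long_srna.json", long_report)
    report["stages"]["long_srna"] = {"clusters": len(clusters)}
    report["seconds"]["long_srna"] = round(time.time() - t, 2)

    report["seconds"]["total"] = round(time.time() - t_all, 2)
    report["parameters"] = {
        "trim": dataclasses.asdict(config.trim),
        "annot": dataclasses.asdict(config.annot),
        "de_alpha": config.de_alpha,
        "seed": config.seed,
    }
    write_json(outdir / "report.json", report)
    return report


def _matched_totals(collapsed, mapping) -> pd.Series:
    import numpy as np
    matched = np.array([bool(mapping.get(s)) for s in collapsed.sequences])
    return pd.Series(collapsed.counts[matched].sum(axis=0),
                     index=collapsed.libraries)
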