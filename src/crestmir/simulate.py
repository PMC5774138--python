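"""Planted-truth simulator for HD-adapter small-RNA-seq libraries.

Generates a toy genome carrying stem-loop miRNA precursors (including a
miR-427-like tandem repeat of ~1.2 kb units with five isoform hairpins),
a 29-nt small-RNA cluster locus and a handful of gene models, then
simulates sequencing libraries whose reads have the HD-adapter layout

    [4 degenerate nt][insert][4 degenerate nt][3' adapter TGGAATTC...]

padded/truncated to a fixed read length (adapter run-through, as on a
HiSeq). Insert counts per precursor follow a negative binomial with
mean m and variance m + a*m^2; the insert population is bimodal: 23-nt
mature miRNA arms (with isomiR end heterogeneity) against a ~29-nt
background drawn from the cluster locus and random genome positions.
Tissue identity drives the miRNA read fraction, arm-switching and
planted differential expression, so every downstream stage of the
pipeline can be tested against recorded ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import revcomp, write_fasta, write_fastq, write_gff3, write_json

DEFAULT_TISSUES = ("NC", "neural", "ectoderm", "blastula")

#: miRNA share of genome-matched reads per tissue (study conditions)
DEFAULT_MIRNA_FRACTION = {
    "NC": 0.15,
    "neural": 0.161,
    "ectoderm": 0.18,
    "blastula": 0.056,
}

#: share of miRNA reads carried by the miR-427-like repeat family
DEFAULT_MIR427_SHARE = {"NC": 0.67, "neural": 0.67, "ectoderm": 0.67, "blastula": 0.74}

#: relative expression of the five repeat isoforms (C dominant)
ISOFORM_SPLIT = (0.15, 0.10, 0.40, 0.20, 0.15)

#: mature 5' ends are precise, 3' ends ragged — canonical form dominant
DEFAULT_ISOMIR_OFFSETS = {
    "p5": {0: 0.90, 1: 0.04, -1: 0.04, 2: 0.01, -2: 0.01},
    "p3": {0: 0.60, 1: 0.20, -1: 0.20},
}

DEFAULT_BACKGROUND_LENGTHS = {27: 0.05, 28: 0.10, 29: 0.65, 30: 0.15, 31: 0.05}

#: Illumina TruSeq small-RNA 3' adapter (first 8 nt = the trim octamer)
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGGAACTCCAGTCAC"

ARM_LEN = 23
HAIRPIN_FLANK = 2   # nt of stem outside each mature (gives 2-nt 3' overhangs)
LOOP_LEN = 13
HAIRPIN_TAIL = 2    # unpaired 3' tail so +1 3'-isomiRs stay inside the locus
HAIRPIN_LEN = 2 * (HAIRPIN_FLANK + ARM_LEN) + LOOP_LEN + HAIRPIN_TAIL  # 65 nt

_ALPHABET = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class SizingError(ValueError):
    """Genome too small to host all planted loci."""


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 100_000
    n_hairpin_loci: int = 40
    n_novel: int = 5
    repeat_unit_length: int = 1200
    repeat_copies: int = 3
    n_isoforms: int = 5
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    replicates_per_tissue: int = 3
    depth_per_library: int = 200_000
    nb_dispersion: float = 0.1
    # (unit id, tissue, 5p fraction there, 5p fraction elsewhere)
    arm_switch_spec: list[tuple[str, str, float, float]] = field(
        default_factory=lambda: [("mir-427-A", "blastula", 0.90, 0.05)]
    )
    # (unit id, tissue, log2 fold change); defaults planted after genome ids
    de_spec: list[tuple[str, str, float]] | None = None
    mirna_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIRNA_FRACTION)
    )
    mir427_share: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIR427_SHARE)
    )
    cluster_fraction: float = 0.05
    cluster_locus_length: int = 2000
    background_lengths: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_LENGTHS)
    )
    exon_bias_29nt: float | None = None
    isomir_offset_probs: dict[str, dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ISOMIR_OFFSETS.items()}
    )
    adapter_sequence: str = DEFAULT_ADAPTER
    hd_len: int = 4
    read_length: int = 50
    query_divergence: float = 0.05
    n_genes: int = 5
    exon_length: int = 300
    intron_length: int = 500

    def __post_init__(self):
        if self.depth_per_library < 0:
            raise ValueError("depth must be >= 0")
        if not self.adapter_sequence.startswith("TGGAATTC"):
            raise ValueError("adapter must begin with TGGAATTC")
        for name in ("cluster_fraction",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for d in (self.mirna_fraction, self.mir427_share):
            for t, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"fraction for {t} outside [0, 1]")


@dataclass
class TruthHairpin:
    id: str
    chrom: str
    start: int           # 0-based half-open genomic interval
    end: int
    strand: str
    seq: str             # 5'->3' hairpin sequence
    family: str
    unit: str            # expression unit (isoform id for repeat copies)
    arm5: tuple[str, int, int]   # (sequence, genomic start, genomic end)
    arm3: tuple[str, int, int]
    known: bool = True


@dataclass
class GeneModel:
    id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class GroundTruth:
    chrom: str
    genome_length: int
    hairpins: list[TruthHairpin]
    cluster_locus: tuple[str, int, int]
    gene_models: list[GeneModel]
    unit_weights: dict[str, float]          # base expression weight per unit
    arm5_fraction: dict[str, float]         # base 5p fraction per unit
    de_spec: list[tuple[str, str, float]]
    arm_switch_spec: list[tuple[str, str, float, float]]
    # genome sequence is attached by generate_genome / attach_genome and is
    # not serialised with the truth JSON
    _genome: dict[str, str] | None = field(default=None, repr=False, compare=False)

    def attach_genome(self, genome: dict[str, str]) -> "GroundTruth":
        self._genome = genome
        return self

    def genome_seq(self) -> str:
        if self._genome is None:
            raise RuntimeError("no genome attached; call truth.attach_genome()")
        return self._genome[self.chrom]

    def units(self) -> list[str]:
        seen: dict[str, TruthHairpin] = {}
        for h in self.hairpins:
            seen.setdefault(h.unit, h)
        return list(seen)

    def unit_hairpin(self, unit: str) -> TruthHairpin:
        for h in self.hairpins:
            if h.unit == unit:
                return h
        raise KeyError(unit)

    def expected_arm5_fraction(self, unit: str, tissue: str) -> float:
        for u, t, frac_there, frac_else in self.arm_switch_spec:
            if u == unit:
                return frac_there if tissue == t else frac_else
        return self.arm5_fraction[unit]

    def de_multiplier(self, unit: str, tissue: str) -> float:
        m = 1.0
        for u, t, lfc in self.de_spec:
            if u == unit and t == tissue:
                m *= 2.0 ** lfc
        return m


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

_ALPH_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    idx = rng.integers(0, 4, size=n, dtype=np.uint8)
    return _ALPH_BYTES[idx].tobytes().decode("ascii")


def _inject_transitions(rng: np.random.Generator, seq: str, k: int) -> str:
    """Mutate k positions with transitions (keeps folds near-stable)."""
    s = list(seq)
    if k <= 0:
        return seq
    for pos in rng.choice(len(s), size=min(k, len(s)), replace=False):
        s[pos] = _TRANSITION[s[pos]]
    return "".join(s)


def _make_hairpin(rng: np.random.Generator, arm3_seq: str | None = None) -> str:
    """A stem-loop: 25-nt stem + 13-nt loop + (near-)revcomp stem + 2-nt tail.

    The mature arms sit at [2, 25) and [40, 63) of the 65-nt hairpin so
    that the 5p/3p duplex carries the canonical 2-nt 3' overhangs and
    +1 3'-end isomiRs of the 3p arm stay inside the locus. Up to 2
    transition mismatches are injected into the 5' stem half.
    """
    if arm3_seq is None:
        right = _random_seq(rng, HAIRPIN_FLANK + ARM_LEN)
    else:
        right = _random_seq(rng, HAIRPIN_FLANK) + arm3_seq
    left = _inject_transitions(rng, revcomp(right), int(rng.integers(0, 3)))
    return (left + _random_seq(rng, LOOP_LEN) + right
            + _random_seq(rng, HAIRPIN_TAIL))


def _arms_of(hp_start: int, strand: str) -> tuple[tuple[int, int], tuple[int, int]]:
    """Genomic intervals of the 5p and 3p matures of a planted hairpin."""
    a5 = (HAIRPIN_FLANK, HAIRPIN_FLANK + ARM_LEN)
    a3 = (HAIRPIN_LEN - ARM_LEN - HAIRPIN_TAIL, HAIRPIN_LEN - HAIRPIN_TAIL)
    if strand == "+":
        return (
            (hp_start + a5[0], hp_start + a5[1]),
            (hp_start + a3[0], hp_start + a3[1]),
        )
    end = hp_start + HAIRPIN_LEN
    return ((end - a5[1], end - a5[0]), (end - a3[1], end - a3[0]))


def generate_genome(config: SimConfig) -> tuple[dict[str, str], GroundTruth]:
    """Build the toy genome and its ground truth. Deterministic in seed."""
    rng = np.random.default_rng([int(config.seed), 101])
    chrom = "chr1"

    # --- feature blocks ---------------------------------------------------
    blocks: list[tuple[str, str, dict]] = []  # (kind, sequence, meta)

    singleton_units: list[str] = []
    n_known = config.n_hairpin_loci - config.n_novel
    if n_known < 0:
        raise ValueError("n_novel exceeds n_hairpin_loci")
    for i in range(config.n_hairpin_loci):
        known = i < n_known
        unit = f"mir-{100 + i}" if known else f"nov-{i - n_known + 1}"
        hp = _make_hairpin(rng)
        strand = "+" if rng.random() < 0.5 else "-"
        blocks.append(("hairpin", hp if strand == "+" else revcomp(hp),
                       {"unit": unit, "strand": strand, "known": known,
                        "family": unit}))
        singleton_units.append(unit)

    # miR-427-like repeat: one unit sequence, tandem copies
    iso_letters = [chr(ord("A") + i) for i in range(config.n_isoforms)]
    iso_hairpins = {}
    seed7 = _random_seq(rng, 7)
    for letter in iso_letters:
        arm3 = _random_seq(rng, 1) + seed7 + _random_seq(rng, ARM_LEN - 8)
        iso_hairpins[letter] = _make_hairpin(rng, arm3_seq=arm3)
    if config.repeat_copies > 0:
        spacing = config.repeat_unit_length // max(config.n_isoforms, 1)
        if spacing < HAIRPIN_LEN + 20:
            raise SizingError("repeat unit too short for its isoform hairpins")
        unit_seq = list(_random_seq(rng, config.repeat_unit_length))
        iso_offsets = {}
        for i, letter in enumerate(iso_letters):
            off = i * spacing + 30
            unit_seq[off:off + HAIRPIN_LEN] = iso_hairpins[letter]
            iso_offsets[letter] = off
        blocks.append(("repeat", "".join(unit_seq) * config.repeat_copies,
                       {"offsets": iso_offsets}))

    blocks.append(("cluster", _random_seq(rng, config.cluster_locus_length), {}))

    gene_len = (config.n_genes and
                3 * config.exon_length + 2 * config.intron_length)
    for g in range(config.n_genes):
        blocks.append(("gene", _random_seq(rng, gene_len),
                       {"id": f"gene{g + 1}",
                        "strand": "+" if g % 2 == 0 else "-"}))

    # --- placement --------------------------------------------------------
    total = sum(len(s) for _, s, _ in blocks)
    min_gap = 50
    free = config.genome_length - total - min_gap * (len(blocks) + 1)
    if free < 0:
        raise SizingError(
            f"genome_length {config.genome_length} cannot host {total} nt "
            f"of planted features"
        )
    order = rng.permutation(len(blocks))
    cuts = np.sort(rng.integers(0, free + 1, size=len(blocks)))
    gaps = np.diff(np.concatenate([[0], cuts, [free]])) + min_gap

    genome_parts: list[str] = []
    pos = 0
    hairpins: list[TruthHairpin] = []
    cluster_locus = None
    gene_models: list[GeneModel] = []

    def _record_hairpin(unit, family, start, strand, known, seq_fwd):
        hp_seq = seq_fwd if strand == "+" else revcomp(seq_fwd)
        (a5s, a5e), (a3s, a3e) = _arms_of(start, strand)
        gslice = seq_fwd
        def sub(s, e):
            raw = gslice[s - start:e - start]
            return raw if strand == "+" else revcomp(raw)
        hairpins.append(TruthHairpin(
            id=unit if family != "mir-427" else unit,
            chrom=chrom, start=start, end=start + HAIRPIN_LEN, strand=strand,
            seq=hp_seq, family=family, unit=unit,
            arm5=(sub(a5s, a5e), a5s, a5e),
            arm3=(sub(a3s, a3e), a3s, a3e),
            known=known,
        ))

    for gi, bi in enumerate(order):
        kind, seq, meta = blocks[bi]
        genome_parts.append(_random_seq(rng, int(gaps[gi])))
        pos += int(gaps[gi])
        start = pos
        genome_parts.append(seq)
        pos += len(seq)
        if kind == "hairpin":
            _record_hairpin(meta["unit"], meta["family"], start,
                            meta["strand"], meta["known"], seq)
        elif kind == "repeat":
            for copy in range(config.repeat_copies):
                base = start + copy * config.repeat_unit_length
                for letter, off in meta["offsets"].items():
                    hstart = base + off
                    hseq = seq[hstart - start:hstart - start + HAIRPIN_LEN]
                    h = TruthHairpin(
                        id=f"mir-427-{letter}.{copy + 1}",
                        chrom=chrom, start=hstart, end=hstart + HAIRPIN_LEN,
                        strand="+", seq=hseq, family="mir-427",
                        unit=f"mir-427-{letter}",
                        arm5=(hseq[HAIRPIN_FLANK:HAIRPIN_FLANK + ARM_LEN],
                              *_arms_of(hstart, "+")[0]),
                        arm3=(hseq[HAIRPIN_LEN - ARM_LEN - HAIRPIN_TAIL:
                                   HAIRPIN_LEN - HAIRPIN_TAIL],
                              *_arms_of(hstart, "+")[1]),
                        known=True,
                    )
                    hairpins.append(h)
        elif kind == "cluster":
            cluster_locus = (chrom, start, start + len(seq))
        elif kind == "gene":
            exons = []
            p = start
            for _ in range(3):
                exons.append((p, p + config.exon_length))
                p += config.exon_length + config.intron_length
            gene_models.append(GeneModel(
                id=meta["id"], chrom=chrom, start=start, end=start + len(seq),
                strand=meta["strand"], exons=exons,
            ))
    genome_parts.append(_random_seq(rng, int(gaps[-1])))
    pos += int(gaps[-1])
    if pos < config.genome_length:
        genome_parts.append(_random_seq(rng, config.genome_length - pos))
    genome = {chrom: "".join(genome_parts)}

    # --- expression ground truth -----------------------------------------
    unit_weights: dict[str, float] = {}
    arm5_fraction: dict[str, float] = {}
    for unit in singleton_units:
        unit_weights[unit] = float(rng.lognormal(0.0, 1.0))
        arm5_fraction[unit] = float(rng.uniform(0.2, 0.8))
    singleton_total = sum(unit_weights.values())
    if config.repeat_copies > 0:
        # family weight per tissue is applied at simulation time; store the
        # isoform split here against a nominal unit weight of 1
        for letter, split in zip(iso_letters, ISOFORM_SPLIT[:config.n_isoforms]):
            unit = f"mir-427-{letter}"
            unit_weights[unit] = split
            arm5_fraction[unit] = float(rng.uniform(0.2, 0.8))

    de_spec = config.de_spec
    if de_spec is None:
        # plant effects on well-expressed hairpins, but not the largest
        # ones: per-tissue miRNA pools are fixed, so boosting a large
        # slice of the pool 4x would depress every other hairpin and
        # turn the planted contrast into a global composition shift
        ranked = sorted(singleton_units[:n_known],
                        key=lambda u: -unit_weights[u])
        start = len(ranked) // 3
        picked = ranked[start:start + 5]
        de_spec = []
        for u in picked[:3]:
            de_spec.append((u, "NC", 2.0))
        for u in picked[3:5]:
            de_spec.append((u, "NC", 2.0))
            de_spec.append((u, "blastula", 2.0))

    truth = GroundTruth(
        chrom=chrom, genome_length=config.genome_length, hairpins=hairpins,
        cluster_locus=cluster_locus or (chrom, 0, 0),
        gene_models=gene_models,
        unit_weights=unit_weights, arm5_fraction=arm5_fraction,
        de_spec=list(de_spec), arm_switch_spec=list(config.arm_switch_spec),
    )
    truth.attach_genome(genome)
    return genome, truth


def expected_unit_means(truth: GroundTruth, config: SimConfig,
                        tissue: str) -> dict[str, float]:
    """Expected insert count per expression unit in one library.

    Differential-expression multipliers act on the singleton weights
    before the miR-427-like family is scaled to its per-tissue share of
    miRNA reads, so that share holds in every tissue regardless of the
    planted DE.
    """
    singles = [u for u in truth.units() if not u.startswith("mir-427-")]
    isos = [u for u in truth.units() if u.startswith("mir-427-")]
    weights = {u: truth.unit_weights[u] * truth.de_multiplier(u, tissue)
               for u in singles}
    s_total = sum(weights.values())
    share = config.mir427_share.get(tissue, 0.67) if isos else 0.0
    fam_total = share / (1.0 - share) * s_total if isos else 0.0
    iso_split = sum(truth.unit_weights[u] for u in isos) or 1.0
    for u in isos:
        weights[u] = (fam_total * truth.unit_weights[u] / iso_split
                      * truth.de_multiplier(u, tissue))
    total = sum(weights.values())
    depth_mirna = config.depth_per_library * config.mirna_fraction.get(tissue, 0.1)
    return {u: depth_mirna * w / total for u, w in weights.items()}


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

@dataclass
class LibrarySim:
    """One simulated library plus its per-read ground truth."""

    library: str
    tissue: str
    replicate: int
    reads: list[tuple[str, str, str]]        # (name, sequence, quality)
    inserts: list[str]                        # planted insert per read
    source: list[tuple]                       # ("mirna", unit, arm, d5, d3) or
                                              # ("bg", chrom, start, end, strand)

    def insert_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.inserts:
            out[s] = out.get(s, 0) + 1
        return out


def library_rng(config: SimConfig, tissue: str, replicate: int) -> np.random.Generator:
    t_idx = list(config.tissues).index(tissue)
    return np.random.default_rng([int(config.seed), 211, t_idx, int(replicate)])


def _nb(rng, mean: float, alpha: float, size=None):
    if mean <= 0:
        return np.zeros(size or 1, dtype=np.int64) if size else 0
    if alpha <= 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / alpha
    return rng.negative_binomial(n, n / (n + mean), size=size)


def _arm_insert(genome_seq: str, arm: tuple[str, int, int], strand: str,
                d5: int, d3: int) -> str:
    _, s, e = arm
    if strand == "+":
        gs, ge = s + d5, e + d3
        return genome_seq[gs:ge]
    gs, ge = s - d3, e - d5
    return revcomp(genome_seq[gs:ge])


def simulate_library(truth: GroundTruth, tissue: str, replicate: int,
                     config: SimConfig,
                     rng: np.random.Generator | None = None) -> LibrarySim:
    if tissue not in config.tissues:
        raise ValueError(f"unknown tissue label: {tissue!r}")
    if rng is None:
        rng = library_rng(config, tissue, replicate)
    gseq = truth.genome_seq()

    inserts: list[str] = []
    source: list[tuple] = []

    means = expected_unit_means(truth, config, tissue)
    p5 = config.isomir_offset_probs["p5"]
    p3 = config.isomir_offset_probs["p3"]
    d5_vals = np.array(sorted(p5))
    d5_probs = np.array([p5[k] for k in sorted(p5)], dtype=float)
    d5_probs /= d5_probs.sum()
    d3_vals = np.array(sorted(p3))
    d3_probs = np.array([p3[k] for k in sorted(p3)], dtype=float)
    d3_probs /= d3_probs.sum()

    alpha = config.nb_dispersion
    for unit in sorted(means):
        mean = means[unit]
        count = int(_nb(rng, mean, alpha))
        if count == 0:
            continue
        hp = truth.unit_hairpin(unit)
        frac5 = truth.expected_arm5_fraction(unit, tissue)
        n5 = int(rng.binomial(count, frac5))
        for arm_name, n_arm in (("5p", n5), ("3p", count - n5)):
            if n_arm == 0:
                continue
            arm = hp.arm5 if arm_name == "5p" else hp.arm3
            d5s = rng.choice(d5_vals, size=n_arm, p=d5_probs)
            d3s = rng.choice(d3_vals, size=n_arm, p=d3_probs)
            combos, counts = np.unique(
                np.stack([d5s, d3s], axis=1), axis=0, return_counts=True)
            for (d5, d3), c in zip(combos, counts):
                ins = _arm_insert(gseq, arm, hp.strand, int(d5), int(d3))
                inserts.extend([ins] * int(c))
                source.extend([("mirna", unit, arm_name, int(d5), int(d3))] * int(c))

    # background ~29-nt class
    bg_frac = 1.0 - config.mirna_fraction.get(tissue, 0.1)
    n_bg = int(rng.poisson(config.depth_per_library * bg_frac))
    if n_bg > 0:
        glen = len(gseq)
        lens = np.array(sorted(config.background_lengths))
        lprob = np.array([config.background_lengths[k] for k in lens], dtype=float)
        lprob /= lprob.sum()
        read_lens = rng.choice(lens, size=n_bg, p=lprob)
        in_cluster = rng.random(n_bg) < config.cluster_fraction
        strands = np.where(rng.random(n_bg) < 0.5, "+", "-")
        _, cs, ce = truth.cluster_locus
        exon_iv = [iv for g in truth.gene_models for iv in g.exons]
        for i in range(n_bg):
            L = int(read_lens[i])
            if in_cluster[i] and ce - cs > L:
                s = int(rng.integers(cs, ce - L))
            elif (config.exon_bias_29nt is not None and exon_iv and L == 29
                  and rng.random() < config.exon_bias_29nt):
                es, ee = exon_iv[int(rng.integers(0, len(exon_iv)))]
                s = int(rng.integers(es, max(es + 1, ee - L)))
            else:
                s = int(rng.integers(0, glen - L))
            sub = gseq[s:s + L]
            ins = sub if strands[i] == "+" else revcomp(sub)
            inserts.append(ins)
            source.append(("bg", truth.chrom, s, s + L, str(strands[i])))

    # assemble HD reads
    n = len(inserts)
    perm = rng.permutation(n)
    hd = _ALPHABET[rng.integers(0, 4, size=(n, 2 * config.hd_len))]
    adapter = config.adapter_sequence
    pad = adapter + "A" * config.read_length
    reads: list[tuple[str, str, str]] = []
    lib = f"{tissue}_{replicate}"
    qual = "I" * config.read_length
    out_inserts: list[str] = []
    out_source: list[tuple] = []
    for ridx, i in enumerate(perm):
        ins = inserts[i]
        h = hd[ridx]
        seq = ("".join(h[:config.hd_len]) + ins + "".join(h[config.hd_len:]) + pad)
        seq = seq[:config.read_length]
        reads.append((f"{lib}_{ridx}", seq, qual))
        out_inserts.append(ins)
        out_source.append(source[i])
    return LibrarySim(library=lib, tissue=tissue, replicate=replicate,
                      reads=reads, inserts=out_inserts, source=out_source)


def simulate_study(config: SimConfig):
    """Genome + truth + all libraries. Returns (genome, truth, libs)."""
    genome, truth = generate_genome(config)
    libs = []
    for tissue in config.tissues:
        for rep in range(1, config.replicates_per_tissue + 1):
            libs.append(simulate_library(truth, tissue, rep, config))
    return genome, truth, libs


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def precursor_queries(truth: GroundTruth, config: SimConfig,
                      rng: np.random.Generator | None = None) -> dict[str, str]:
    """Known-precursor FASTA records, with homolog-level divergence.

    Emulates querying another species' miRBase precursors: each known
    unit's hairpin is emitted once with transition divergence at rate
    ``config.query_divergence``. Novel units are withheld.
    """
    if rng is None:
        rng = np.random.default_rng([int(config.seed), 307])
    out: dict[str, str] = {}
    for unit in truth.units():
        hp = truth.unit_hairpin(unit)
        if not hp.known:
            continue
        k = int(rng.binomial(len(hp.seq), config.query_divergence))
        out[f"qry-{unit}"] = _inject_transitions(rng, hp.seq, k)
    return out


def write_truth(path, truth: GroundTruth) -> None:
    obj = dataclasses.asdict(truth)
    obj.pop("_genome", None)
    write_json(path, obj)


def load_truth(path) -> GroundTruth:
    obj = json.loads(Path(path).read_text())
    obj["hairpins"] = [TruthHairpin(**{**h, "arm5": tuple(h["arm5"]),
                                       "arm3": tuple(h["arm3"])})
                       for h in obj["hairpins"]]
    obj["gene_models"] = [GeneModel(**{**g, "exons": [tuple(e) for e in g["exons"]]})
                          for g in obj["gene_models"]]
    obj["cluster_locus"] = tuple(obj["cluster_locus"])
    obj["de_spec"] = [tuple(x) for x in obj["de_spec"]]
    obj["arm_switch_spec"] = [tuple(x) for x in obj["arm_switch_spec"]]
    return GroundTruth(**obj)


def write_gene_models(path, truth: GroundTruth) -> None:
    rows = []
    for g in truth.gene_models:
        rows.append(dict(seqid=g.chrom, type="gene", start=g.start, end=g.end,
                         strand=g.strand, attributes=f"ID={g.id}"))
        for k, (s, e) in enumerate(g.exons, 1):
            rows.append(dict(seqid=g.chrom, type="exon", start=s, end=e,
                             strand=g.strand,
                             attributes=f"ID={g.id}.e{k};Parent={g.id}"))
    write_gff3(path, rows)


def write_study(outdir, config: SimConfig):
    """Simulate and persist genome, truth, queries, gene models, FASTQs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth, libs = simulate_study(config)
    write_fasta(outdir / "genome.fa", genome.items())
    write_truth(outdir / "truth.json", truth)
    write_gene_models(outdir / "genes.gff3", truth)
    write_fasta(outdir / "precursors.fa", precursor_queries(truth, config).items())
    for lib in libs:
        write_fastq(outdir / f"{lib.library}.fastq", lib.reads)
    return genome, truth, libs
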