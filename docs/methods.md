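# Methods

`crestmir` re-implements, as a tested pipeline, the computational
analysis of HD-adapter small-RNA sequencing libraries from *Xenopus
laevis* explants (neural crest, neural, ectoderm and blastula animal
caps): read cleaning, exact genome mapping, homology-based miRNA
hairpin annotation, isomiR and arm-switch quantification,
negative-binomial differential expression, rule-based novel miRNA
prediction, and characterisation of the 29-nt small-RNA class. All
stages are exercised end-to-end on synthetic libraries with planted
ground truth; this note records the models, the parameters that
matter, and the design choices made where the procedure was genuinely
open.

## Read model and trimming

HD (high-definition) adapters carry four degenerate nucleotides at
each ligating end, so a sequenced read is

    [4 random nt][insert][4 random nt][3' adapter TGGAATTC...]

padded by adapter run-through to a fixed read length (50 nt by
default; the real read length is instrument-dependent and
configurable). The trimmer cuts at the **leftmost** perfect match of
the adapter's first 8 nt (`TGGAATTC`), then removes the two 4-nt HD
signatures. A read is discarded, with a reason code, when no octamer
occurs, when the pre-adapter remainder is shorter than `2*hd_len+1`
(no room for both HD signatures plus a 1-nt insert), or when the
insert contains an N (downstream mapping is exact-match). Inserts of
16–35 nt are kept. Leftmost matching is the conservative standard for
3' adapters; the source protocol states only "perfect sequence match",
so this choice and the N policy are explicit here. Per-library
tallies satisfy `raw = kept + sum(discard reasons)` exactly.

Inserts that happen to contain the adapter octamer internally (or
straddling an HD junction) are cut early; at typical insert
compositions this affects well under 0.1% of reads, which is the only
loss mode of the exactness guarantee the tests check.

## Exact mapping

Inserts are mapped full-length with no gaps or mismatches, on both
strands, retaining **all** loci — the miR-427-like repeat cluster is
massively multi-mapping by design. Genomes up to 1 Mb use a hash of
16-nt words with verification extension (16 nt = the minimum kept
insert length); larger genomes use a query-driven vectorised word scan
with the identical contract. Size-class profiles are reads-per-million
(RPM) where the denominator is the per-library count of
**genome-matched** reads.

## Hairpin annotation

Known animal precursor sequences are searched with a seed-and-extend
local aligner: exact 11-nt word seeds, gapped extension under match
+1, mismatch −2, gap open −5, gap extend −2 (extension is delegated to
`Bio.Align.PairwiseAligner` in local mode). Significance uses the
Karlin–Altschul form `E = K·m·n·exp(−λS)` with `n` counting both
strands. `(K, λ)` are fitted once per searcher from the Gumbel moments
of optimal local scores of 48 random query/target pairs (80 nt × 10 kb,
fixed internal seed): `λ = π/(σ√6)`, `K = exp(λ·mean − γ)/(m₀n₀)`.
Hits with `E < 1e-06` are kept. Because a stem-loop is nearly its own
reverse complement, each query tends to produce a weak antisense echo
of every strong hit; per-query dedup is therefore strand-agnostic and
keeps the stronger orientation.

The filter ladder then applies, in order: any query with ≥ 30 hits
loses all of them; hits whose aligned interval is ≤ 55 nt are dropped
(the alignment span is used, since the subsequent extension to the
query's full length would defeat the filter); the candidate interval
is the hit extended symmetrically to the query length; the extracted
sequence must pass the structure check below; hairpins with < 100
reads summed over all libraries are removed unless another member of
their family passes (family rescue; families are parsed from
miRBase-style query names, e.g. `mir-130b-1 → mir-130`).

## Secondary structure

The fold is the classic Nussinov maximum-base-pairing dynamic
programme (Watson–Crick plus GU, minimum loop 3, numba-accelerated),
with a deterministic traceback (leave i unpaired when optimal,
otherwise pair i with the smallest feasible j). A thermodynamic model
is deliberately not used: the pipeline only needs a reproducible,
dependency-free decision "is this a single clean stem-loop?", and the
validation layer makes that decision explicit instead of manual:

1. paired fraction ≥ 0.4;
2. exactly one substantial terminal loop. Pairs are organised into a
   nesting forest; helix *chains* follow single-child nesting,
   continuing through a branch when only one child subtree has ≥ 3
   pairs (smaller siblings are fold noise) and treating a junction
   that encloses ≤ 30 nt as a terminal loop with internal
   substructure. Chains of < 4 pairs do not count as stems;
3. the main chain has ≥ 15 pairs (bulges included);
4. the fold contains a contiguous helix of ≥ 8 stacked pairs.
   Maximum-pairing folds of random sequence reach deep but heavily
   bulged stems; the long uninterrupted helix is what separates a
   genuine pre-miRNA stem from that background (random 70-mers pass
   all four criteria ~2% of the time versus ~99% for planted
   hairpins).

Arm assignment splits the hairpin at the midpoint of the main terminal
loop; each side's mature is its most abundant fully-contained read
(ties to the lexicographically smaller sequence), reads crossing the
midpoint span the loop and count for neither arm, and a read-free side
can take a homology-transferred mature when the query provides one.

## Quantification, isomiRs, arm switching

A read contributes its **full** count to every hairpin whose interval
contains one of its loci on the same strand — the policy the repeat
cluster requires, configurable to fractional weighting. Family-share
views (e.g. "miR-427 constitutes X% of miRNA reads") use the
fractional matrix so each read is counted once, not once per repeat
copy. IsomiRs are classified by signed 5'/3' end offsets against the
called mature, capped at ±5 nt. The arm ratio r = 5p/(5p+3p) is
computed per library (flagged undefined when both arms are empty);
arm-switch detection compares replicate-mean ratios between tissues
with thresholds hi = 0.7, lo = 0.3 and a per-library minimum arm total
of 50 reads — the switch itself is described qualitatively in the
source analysis, so these thresholds are explicit, configurable
choices here. Tissue views report top-10 tables (after excluding the
dominant family), per-tissue family read fractions, and
replicate-mean RPM heatmap matrices.

## Differential expression

The count model is a from-scratch re-implementation of the standard
NB workflow: median-of-ratios size factors (falling back to
positive-subset medians when no row is positive everywhere, with a
logged warning), a per-row NB2 model (variance m + α·m²) with log link
fitted by per-group Newton iterations, and BH adjustment with calls at
padj < 0.01. Dispersion is estimated per row by pooled method of
moments and shrunk 50/50 toward an across-row target. Two numerical
choices matter at n = 3 vs 3 (4 residual df):

- the shrinkage target is the **outlier-clipped (99th percentile)
  mean** of the raw moment estimates, not their median — the median of
  a 4-df variance-based estimator is biased ~17% low, which inflates
  every Wald statistic;
- the Wald statistic is referred to a **t distribution** with
  Satterthwaite df = residual_df / w² = 4·(nA+nB−2) (w = 0.5 is the
  shrinkage weight), because the dispersion estimate itself is noisy
  and a normal reference is anti-conservative.

With these choices null p-values are uniform (KS), the observed FDR at
padj < 0.01 stays below 1% with 10% planted effects, and power at
|log2FC| = 2, mean ≥ 100, dispersion 0.1 is ≈ 0.85.

Enrichment sets are pairwise: NC-enriched = significantly up in NC
against each of neural, ectoderm and blastula ("against all other
tissue types" is read as every-pairwise, not versus a pooled rest
group); NC∩blastula-shared = up in both NC and blastula against neural
and ectoderm, excluding anything DE between NC and blastula. Note a
structural power limit: with dispersion α the Fisher information per
group saturates at n/α, capping the per-contrast |z| near
|log2FC|·ln2·√(n/(2α)) (≈ 5.4 at α = 0.1, n = 3, log2FC = 2) no matter
how deep the libraries are; joint membership over three or four
contrasts at BH-adjusted padj < 0.01 therefore has per-unit power of
roughly 0.45–0.65 under the default conditions, while false entries
remain essentially absent. Tests assert the aggregate behaviour, not
single-realisation membership.

## Novel miRNA prediction

One predictor replaces the original two-tool intersection; its rules
are the documented core both tools share: (1) same-strand read stacks
with gaps ≤ 3 nt, span ≤ 40 nt and total count ≥ 10, outside annotated
hairpins; (2) 5'-end homogeneity ≥ 0.8 (precise Drosha/Dicer
processing); (3) among windows of 60–200 nt containing the stack
(stack-flush and centred anchors at each length), those passing the
hairpin validation with the dominant read fully inside one stem arm —
the **longest** passing window wins, ties to higher paired fraction
then leftmost; (4) star support is flagged when opposite-arm reads
form a duplex with the mature showing the Dicer 2-nt 3' overhang
(± 1 nt, read off the fold's pairing with a ± 3 nt nearest-paired
projection). Predictions are grouped single-linkage: two matures share
a group iff they are identical or differ only by end offsets ≤ 2 nt.

## 29-nt class

Cluster detection is deliberately simpler than a probabilistic piRNA
caller: 25–33-nt read loci merge across gaps ≤ 500 nt, merged
intervals keep ≥ 50 reads, and each cluster reports count-weighted
strand bias, 1U (5'-uridine) fraction, and mean length. The analysis
question is only "what fraction of the 29-nt class is clustered?", and
the transparent detector supports that directly. Degradation and
intron checks are two-proportion z tests (via statsmodels) of the
focal-length exon/intron overlap fraction against all other lengths,
one-sided for enrichment; overlap is any-overlap ≥ 1 nt.

## Synthetic data

The generator plants everything the analysis assumes on a toy genome:
stem-loop precursors (25-bp stems with ≤ 2 transition mismatches,
13-nt loops, 2-nt 3' tails; matures at the Dicer register with 2-nt 3'
overhangs), a miR-427-like tandem repeat (1.2-kb units × 5 copies,
each carrying five isoform hairpins whose 3p arms share a seed), a
2-kb 29-nt cluster locus, and five 3-exon gene models on both strands.
Default conditions mirror the study: four tissues × three replicates
at 2×10⁵ reads per library; per-tissue miRNA read fractions
{NC 0.15, neural 0.161, ectoderm 0.18, blastula 0.056}; the repeat
family at 67% of miRNA reads (74% in blastula), applied after the
planted DE so those shares hold per tissue; isoform split making
isoform C dominant; a planted arm switch for isoform A (5p fraction
0.90 in blastula vs 0.05 elsewhere); NB replicate noise with
dispersion 0.1 (variance m + α·m², matching the DE model so parameter
recovery is well-posed); planted log2FC = 2 on three NC-only and two
NC∩blastula-shared hairpins, carried by well-expressed singletons;
isomiR offsets with precise 5' ends (P(0) = 0.9) and ragged 3' ends
(P(0) = 0.6); and a ~29-nt background (modal lengths 27–31) drawn 5%
from the cluster locus and 95% uniformly, optionally exon-biased for
the degradation positive control. 40 singleton hairpin loci (5 of them
withheld from the precursor queries as "novel") keep the
median-of-ratios anchor on single-copy rows, as in the real ~400-row
matrix. Sequencing error, quality realism and ligation bias are out of
scope: reads carry flat qualities and the HD structure only.

Because every insert is an exact genomic substring, passing tests show
that the pipeline's logic and statistics behave as specified — not
that it is robust to sequencing error or to genomes with repeat
structure beyond the planted cluster.

## Problem sizes and density regimes

Genome size and depth are chosen per analysis so that the read-per-nt
density matches the regime the method assumes on a real (~2.7 Gb)
genome. On the default 100-kb genome with 12 × 2×10⁵ reads, the
density-merging cluster detector saturates (every gap ≤ 500 nt) and
novel-prediction stacks are polluted by background reads — so the
end-to-end run uses the default genome, while cluster-boundary
checks run one library on a 50-Mb genome (sparse scatter), the
in-cluster-fraction check uses 2 Mb at higher depth (more 29-mers,
still no spurious clusters), and novel-prediction recovery uses one
1×10⁵-read library on 20 Mb. Determinism: all randomness descends
from one root seed via `numpy` `default_rng` spawn keys per stage,
tissue and replicate; reruns are byte-identical (timings live only in
`report.json`).

## Known limitations

- The maximum-pairing fold is not thermodynamic; hairpins whose
  biological structure depends on energetics rather than pairing count
  can be mis-validated in either direction.
- The E-value calibration assumes the Gumbel form holds for gapped
  local alignment at these scores (it does empirically here); K and λ
  are composition-blind (uniform-base null).
- The annotation's manual-curation step of the original analysis is
  replaced by the four explicit structure criteria; they are a
  testable stand-in, not a reproduction.
- Arm-switch thresholds (0.7/0.3, min 50) and novel-prediction
  constants (min_count 10, homogeneity 0.8, ≤ 2-nt grouping offsets)
  are explicit choices where the original description is qualitative.
- The cluster detector is density merging, not ProTRAC's probabilistic
  model; boundary accuracy degrades when background scatter sits
  within `max_gap` of a cluster edge.
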