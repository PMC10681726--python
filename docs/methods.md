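# Methods

## Scope and model of the experiment

The package analyses a multiplexed single-cell experiment in which one cell
pool contains three hashtagged conditions — untreated control, a
chromatin-damaging treatment (ChrD; histone eviction without DNA breaks) and
a DNA-damaging treatment (DnaD; double-strand breaks) — over a population
that is roughly half p53 wild-type and half p53 knockout. Because the
knockout is produced by bulk ribonucleoprotein editing rather than cloning,
p53 status must be inferred per cell from its transcriptome; all downstream
contrasts are stratified by that call. A second, independent branch computes
promoter-centred coverage statistics (pausing index, metagene profiles,
MNase-seq occupancy change) for gene classes defined by baseline expression.

Coordinates are 0-based half-open everywhere; GTF input is converted at the
boundary. The TSS of a minus-strand gene is `end − 1` (the biological
5′ end). Readers reject malformed input instead of repairing it, and every
writer/reader pair round-trips exactly.

## Cell-level decision rules

All three rules operate on raw UMI counts. QC bounds (UMI 30000–130000,
detected genes 6000–8000, mitochondrial fraction ≤ 7.5%) are inclusive.
Hashtags are thresholded independently at log2(count) > 8, i.e. count > 256
strict — no margin between the top two hashtags is required; negatives and
multiplets are excluded from condition assignment. The genotype rule is:
positive iff TP53 > 0 and log2(MDM2) > 1; negative iff TP53 = 0 and
log2(MDM2) ≤ 1, with log2(0) taken as −∞ so a cell with both markers at
zero is called negative; conflicting combinations are left unassigned and
excluded from stratified contrasts. "Counts" means raw counts for both
markers; a `normalized` switch on `GenotypeRule` rescales to the mean
library size for sensitivity analysis. Whether the MDM2 rule should use
normalized counts is genuinely open; raw is the default because the TP53
half of the rule is explicitly linear in raw counts.

Stage order is fixed — QC, then demultiplexing, then genotyping — and the
pipeline records dropped-record counts per stage in its manifest.

## Differential expression

Size factors are median-of-ratios: factor_s = median over genes positive in
all samples of count_gs / geometric-mean_g. For per-cell matrices no gene is
positive in every cell, so the per-cell mode uses the zero-tolerant variant
(gene-wise geometric means over nonzero counts, per-cell median ratio over
detected genes). This variant, unlike total-count scaling, is robust to
composition shifts: when a few hundred genes are strongly induced the
library grows, and total-count factors would push every null gene's apparent
fold change toward the DEG threshold.

Two tests are provided. The per-cell mode is a two-sided Wilcoxon rank-sum
on normalized counts with mid-ranks and the tie-corrected normal
approximation, Var(R) = n₁n₂/12 · [(N+1) − Σ(t³−t)/(N(N−1))]; fully tied
genes get p = 1. The pseudobulk mode is an NB Wald test: per-gene dispersion
is estimated by method of moments on within-group residual variance, shrunk
50% toward a fitted α ~ a₀ + a₁/μ trend, and the Wald statistic is the
log2 fold change over its delta-method standard error. Exact equivalence to
DESeq2's shrinkage estimators is a non-goal; the pseudobulk test targets
replicate designs and the per-cell test the single-cell contrasts.

Log2 fold changes use normalized group means with a 0.5 pseudocount, which
biases estimates slightly toward zero at low means (≈0.04 log2 units at
mean 20); planted-effect recovery is therefore evaluated as the mean
estimate over planted genes. With a strong one-sided planted program the
size factors shift by a few percent and raw null p-values become mildly
anticonservative; the DEG criteria (|FC| > 1.5 AND BH-adjusted p < 0.05,
BH hand-written and oracle-tested) absorb this, and type-I calibration is
assessed on label-permuted data, where the per-cell test holds the nominal
5% level. The multiple-testing procedure is Benjamini–Hochberg because
"adjusted p-value" in this analysis tradition conventionally means BH.

Over-representation of a DEG list in a gene-set collection is the exact
hypergeometric upper tail P(X ≥ overlap) with BH across sets. Ranked GSEA
with permutation enrichment scores is out of scope.

## Chromatin metrics

The pausing index is mean coverage over the half-open window [TSS, TSS+50)
in transcription direction divided by mean coverage over the whole gene
span. The window is part of the denominator by default (literal "whole
gene"); `body_excludes_window` switches to a body-only denominator. Genes
shorter than `min_gene_length` (default 200 bp) are skipped with a reason;
zero-density bodies yield an undefined (NaN) index, reported not dropped.
The ratio is invariant under scaling the track by any positive constant.

Metagene matrices are reference-point mode at the TSS: row g, bin b is the
mean density over that bin's bases, minus-strand rows reversed so columns
read 5′→3′; bins outside the chromosome are NaN and excluded from column
means. Normalizations: none, per-gene-mean (zero-mean rows dropped and
counted) and CPM. Both the pausing index and the metagene agree with a
per-base brute-force oracle to 1e−9 on 50-gene synthetic genomes.

MNase-seq change: both tracks are scaled to equal total signal (the minimal
defensible depth normalization; the upstream protocol does not dictate
one), then per gene per window the relative change of mean density
(treated − control)/control is computed over strand-aware windows, default
(−300,−150), (−150,0), (0,150), (150,300) bp around the TSS — the window
set is configurable because no canonical set exists. Genes with zero
control density in a window are excluded from that window's summary and
counted. Class comparisons use Welch's two-tailed t-test of the ChrD-induced
class against each other class (the variance assumption of the classical
test is not defensible for ratio data, so the unequal-variance form is
used), and pausing-index distributions are compared with the tie-corrected
Kruskal–Wallis test (classes with fewer than two values are excluded with a
warning; fully tied data give H = 0, p = 1).

Expression classes: ChrD-induced genes are set aside first, zero-expression
genes form their own class, and the remaining genes are split into three
equal-size bins by expression with ties broken by stable input order.

## Synthetic data

The generator's defaults are the study conditions: 500 cells per condition,
three conditions, 50% p53-negative, a 2000-gene universe, NB counts
(gamma–Poisson, dispersion 0.1) around log-normal baseline means
(median 15), 10% lognormal cell-size variation, 5% doublets (same- or
cross-condition with equal probability; cross-condition doublets are what
the multiplet rule must catch), and Beta-distributed mitochondrial fractions
(mean 3%) so a realistic tail fails the 7.5% QC bound.

Planted programs mirror the biology at reduced scale: 400 ChrD-program genes
induced log2FC 1.5 under ChrD in **both** genotypes; 25 p53-target genes
induced log2FC 2 in p53-**positive** cells under both treatments; 50
cell-cycle genes repressed log2FC −1.5 in arrested cells (all ChrD-treated
cells, plus p53-positive DnaD-treated cells — DnaD arrest is p53-dependent,
ChrD arrest is not). At genome scale the published contrast shows ~13×
more ChrD than DnaD DEGs; these sizes reproduce the same structure at ~6×
within a 2000-gene universe. The published detected-gene QC bounds
(6000–8000) presume a genome-scale assay, so end-to-end synthetic runs
rescale only the gene-count bounds (1000–2000) while keeping the published
UMI and mitochondrial thresholds.

Marker channels are structurally separated so that classification error is
attributable to explicit noise parameters: TP53 is exactly zero in knockout
cells (the edited transcript is modeled as absent) and 1 + Poisson in
wild-type cells, zeroed by dropout (default 0.3, reflecting very low TP53
capture); MDM2 is 3 + Poisson in wild-type cells (mean 8 untreated, 16
treated) and Poisson capped at 2 in knockout cells; hashtag signal is a
512-count floor plus NB (mean 3000) for the cell's own condition and
Poisson ambient counts (mean 5) elsewhere. Consequently, with dropout and
ambient both zero the decision rules recover the truth exactly, and at the
default noise levels genotype errors appear as unassigned cells rather than
misassignments. Dropout applies to TP53 by default; MDM2 dropout is a
separate parameter defaulting to 0, because joint marker dropout at 0.3
would make a true-positive cell read (TP53 = 0, MDM2 = 0) — i.e. classify
*negative* — in >10% of cells, which no threshold rule can distinguish
from a real knockout.

Coverage simulations tile fixed-length genes (default 1 kb in tests, 2 kb
elsewhere) with ≥2 kb gaps on one synthetic chromosome so per-gene windows
never collide. Nascent-transcription tracks place uniform density over each
gene body with the first 50 bp downstream of the TSS scaled by a per-class
enrichment factor (defaults chrd_induced 8 > high 3 > moderate 2 > low 1.5),
plus optional per-base Poisson noise; the noise-free pausing index is then
exactly e·L/(L − w + w·e). MNase tracks share phased cosine nucleosome
peaks (spacing 200 bp); the treated track multiplies the (−150, 150) bp
promoter window of depleted classes (default: ChrD-induced ×0.5) and
returns the removed mass as uniform intergenic background at the chromosome
tail, so both tracks have equal total signal and the planted relative
change is exactly the depletion factor minus one in the noise-free case.

What the simulator does **not** model: batch effects, UMI collisions,
ambient RNA contamination of the gene matrix, doublet detection beyond the
hashtag rule, gene-length or GC biases in coverage, and fragment-size
structure in MNase data. Passing recovery tests therefore demonstrates
correctness of the decision rules and estimators under the assumed noise
model, not robustness to every artifact of real data.

## Determinism and problem sizes

All randomness flows from one seed through named `numpy` generators; the
pipeline derives its branch seeds as seed, seed+1, seed+2. Outputs are TSV
with fixed float formatting and a JSON manifest carrying the version, a
hash of the scientific configuration (output paths excluded) and per-stage
record counts; wall-clock information goes only to the stderr log, so two
runs with the same seed and configuration are byte-identical. Test and
acceptance problem sizes — 500 cells/condition, 2000–5000 genes, 200–800
coverage genes — were chosen so the full suite and the acceptance script
each complete in well under a minute while keeping Monte-Carlo error far
inside every asserted margin.
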