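# chromstress

Separating p53-dependent from p53-independent transcriptional responses to
**DNA damage** (double-strand breaks, e.g. from bleomycin) versus **chromatin
damage** (histone eviction without DNA breaks, e.g. from the curaxin
CBL0137) in a single multiplexed single-cell experiment — plus the
coverage-based chromatin metrics that characterise the genes chromatin
damage induces.

The package is aimed at computational biologists analysing cell-hashing
scRNA-seq experiments over mixed knockout/wild-type populations, and at
anyone who needs promoter-centred coverage statistics (pausing index,
metagene profiles, nucleosome-occupancy change) with strict, testable
semantics.

## What it implements

**Cell-level decision rules** on raw UMI counts:

- QC: keep cells with total UMI in [30000, 130000], detected genes in
  [6000, 8000], mitochondrial fraction ≤ 7.5% (all configurable, bounds
  inclusive).
- Hashtag demultiplexing: hashtag *k* is present iff log2(count) > 8
  (count > 256, strict); exactly one present → singlet of that sample,
  none → negative, several → multiplet.
- p53 genotyping: **positive** iff TP53 > 0 and log2(MDM2) > 1;
  **negative** iff TP53 = 0 and log2(MDM2) ≤ 1 (MDM2 = 0 counts as −∞);
  anything else **unassigned**.

**Differential expression.** Median-of-ratios size factors (DESeq2-style;
a zero-tolerant variant for per-cell matrices), a tie-corrected Wilcoxon
rank-sum test on normalized counts (per-cell mode) or an NB Wald test with
trend-shrunk method-of-moments dispersion (pseudobulk mode), hand-written
Benjamini–Hochberg adjustment, DEG counting under FC > 1.5 and adjusted
p < 0.05, and exact hypergeometric over-representation against GMT gene
sets.

**Chromatin metrics.** For genes g with TSS t and strand s:

- pausing index `PI(g) = mean coverage over [t, t+50) / mean coverage over
  the whole gene` (window strand-aware, ratio scale-invariant);
- expression classes: ChrD-induced genes set aside, zero-expression genes
  their own class, remaining genes split into equal low/moderate/high bins;
- TSS-anchored metagene matrices oriented 5′→3′;
- relative MNase-seq density change `(treated − control)/control` in
  windows around the TSS after equal-depth normalization, with Welch
  t-tests of the ChrD-induced class against every other class and a
  Kruskal–Wallis comparison for pausing-index distributions.

**Synthetic data with ground truth.** A negative-binomial simulator of the
three-condition hashtagged design (planted p53-target, chromatin-damage and
cell-cycle programs, marker dropout, ambient hashtag counts, doublets,
mitochondrial fractions) and coverage simulators with configurable TSS
enrichment and promoter nucleosome depletion. Every analysis stage has a
parameter-recovery test against this truth.

## Worked example

```bash
python examples/04_full_pipeline.py
```

prints (seed 0):

```
DEG counts per contrast and genotype:
       contrast genotype  n_cells_ref  n_cells_treated  n_total  n_up  n_down
ChrD_vs_control positive          174              159      475   426      49
ChrD_vs_control negative          262              257      449   400      49
DnaD_vs_control positive          174              184       75    26      49
DnaD_vs_control negative          262              251        0     0       0

ChrD/DnaD DEG ratio (p53-positive): 6.3x
DnaD DEGs without p53: 0 vs 75 with p53
ChrD DEG Jaccard between genotypes: 0.95
```

Read: chromatin damage alters ~6× more genes than DNA damage; removing p53
erases the DNA-damage response (75 → 0 DEGs) but barely touches the
chromatin-damage response (475 vs 449, Jaccard 0.95) — the response to
chromatin damage is broad and p53-independent, the response to DNA damage is
narrow and p53-dependent. The other examples walk through classification
accuracy, DE calibration and the chromatin metrics individually.

There is also a thin CLI mirroring the library
(`chromstress simulate|qc|demux|genotype|de|enrich|pausing|metagene|mnase-change|run-all`);
exit codes are 0 (ok), 2 (config error), 3 (data error).

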