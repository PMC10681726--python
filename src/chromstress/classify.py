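"""Cell-level decision rules: QC filtering, hashtag demultiplexing, p53 genotyping.

The three stages run in this order (QC first, then demultiplexing, then
genotype assignment) and each applies literal thresholds on raw counts:

* QC keeps cells with total UMI in [30000, 130000], detected genes in
  [6000, 8000] and mitochondrial fraction <= 7.5% (bounds inclusive; all
  thresholds configurable).
* A hashtag is called present when log2(count) > 8, i.e. the raw count
  strictly exceeds 256; exactly one present hashtag makes a singlet call,
  none makes a negative, two or more a multiplet.
* A cell is p53-positive when TP53 > 0 and log2(MDM2) > 1 (MDM2 >= 3 for
  integer counts), p53-negative when TP53 = 0 and log2(MDM2) <= 1 (MDM2 of 0
  counts as log2 = -inf and satisfies the bound); every other combination is
  left unassigned and excluded from genotype-stratified contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import CellExperiment, ConfigError, InputError

NEGATIVE_CALL = "negative"
MULTIPLET_CALL = "multiplet"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class QCThresholds:
    umi_min: int = 30_000
    umi_max: int = 130_000
    genes_min: int = 6_000
    genes_max: int = 8_000
    mito_max: float = 0.075

    def __post_init__(self) -> None:
        if self.umi_min >= self.umi_max:
            raise ConfigError("umi_min must be < umi_max")
        if self.genes_min >= self.genes_max:
            raise ConfigError("genes_min must be < genes_max")
        if not 0.0 <= self.mito_max <= 1.0:
            raise ConfigError("mito_max must be in [0, 1]")


@dataclass(frozen=True)
class HashtagRule:
    log2_threshold: float = 8.0

    def __post_init__(self) -> None:
        if self.log2_threshold < 0:
            raise ConfigError("log2_threshold must be >= 0")

    @property
    def count_threshold(self) -> float:
        return 2.0 ** self.log2_threshold


@dataclass(frozen=True)
class GenotypeRule:
    tp53_min_linear: float = 0.0  # positive requires TP53 > this (raw counts)
    mdm2_log2_pos: float = 1.0   # positive requires log2(MDM2) > this
    mdm2_log2_neg: float = 1.0   # negative requires log2(MDM2) <= this
    normalized: bool = False     # optionally scale counts to the mean library size

    def __post_init__(self) -> None:
        if self.mdm2_log2_pos < self.mdm2_log2_neg:
            raise ConfigError("mdm2_log2_pos must be >= mdm2_log2_neg")


def qc_metrics(experiment: CellExperiment) -> pd.DataFrame:
    """Per-cell UMI total, detected-gene count and mitochondrial fraction."""
    counts = experiment.gene_counts
    umi = np.asarray(counts.sum(axis=1)).ravel()
    detected = counts.getnnz(axis=1)
    mito = np.asarray(counts[:, experiment.mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umi > 0, mito / np.maximum(umi, 1), 0.0)
    return pd.DataFrame(
        {"umi": umi, "genes": detected, "mito_frac": mito_frac},
        index=experiment.cell_meta.index,
    )


def apply_qc(experiment: CellExperiment, thresholds: QCThresholds | None = None):
    """Filter cells by UMI / detected-gene / mitochondrial thresholds.

    Returns ``(filtered_experiment, report)`` where the report lists every
    input cell with its metrics, pass flag and failing criteria.
    """
    thresholds = thresholds or QCThresholds()
    report = qc_metrics(experiment)
    reasons = []
    for umi, genes, mito in report.itertuples(index=False):
        why = []
        if umi < thresholds.umi_min:
            why.append("umi_min")
        if umi > thresholds.umi_max:
            why.append("umi_max")
        if genes < thresholds.genes_min:
            why.append("genes_min")
        if genes > thresholds.genes_max:
            why.append("genes_max")
        if mito > thresholds.mito_max:
            why.append("mito_max")
        reasons.append(";".join(why))
    report["fail_reasons"] = reasons
    report["qc_pass"] = report["fail_reasons"] == ""
    if not report["qc_pass"].any():
        warnings.warn("all cells failed QC; returning an empty experiment", stacklevel=2)
    filtered = experiment.subset_cells(report["qc_pass"].to_numpy())
    filtered.cell_meta["qc_pass"] = True
    return filtered, report


def demultiplex_hashtags(experiment: CellExperiment, rule: HashtagRule | None = None) -> pd.Series:
    """Call each cell's hashtag: a hashtag id, ``negative`` or ``multiplet``.

    Each hashtag is thresholded independently (raw count strictly greater
    than ``2**log2_threshold``); no margin between the top two is required.
    """
    rule = rule or HashtagRule()
    passing = experiment.hto_counts > rule.count_threshold
    n_pass = passing.sum(axis=1)
    calls = np.full(experiment.n_cells, NEGATIVE_CALL, dtype=object)
    calls[n_pass >= 2] = MULTIPLET_CALL
    single = np.flatnonzero(n_pass == 1)
    winners = passing[single].argmax(axis=1)
    for row, hid in zip(single, winners):
        calls[row] = experiment.hto_ids[hid]
    return pd.Series(calls, index=experiment.cell_meta.index, name="hashtag_call")


def assign_p53_status(
    experiment: CellExperiment,
    rule: GenotypeRule | None = None,
    tp53_gene: str = "TP53",
    mdm2_gene: str = "MDM2",
) -> pd.Series:
    """Classify each cell as p53 ``positive``, ``negative`` or ``unassigned``."""
    rule = rule or GenotypeRule()
    tp53 = np.asarray(
        experiment.gene_counts[:, experiment.gene_index(tp53_gene)].todense()
    ).ravel().astype(float)
    mdm2 = np.asarray(
        experiment.gene_counts[:, experiment.gene_index(mdm2_gene)].todense()
    ).ravel().astype(float)
    if rule.normalized:
        lib = np.asarray(experiment.gene_counts.sum(axis=1)).ravel().astype(float)
        scale = np.where(lib > 0, lib.mean() / np.maximum(lib, 1), 1.0)
        tp53, mdm2 = tp53 * scale, mdm2 * scale
    with np.errstate(divide="ignore"):
        mdm2_log2 = np.where(mdm2 > 0, np.log2(np.maximum(mdm2, 1e-300)), -np.inf)
    positive = (tp53 > rule.tp53_min_linear) & (mdm2_log2 > rule.mdm2_log2_pos)
    negative = (tp53 == 0) & (mdm2_log2 <= rule.mdm2_log2_neg)
    calls = np.full(experiment.n_cells, UNASSIGNED, dtype=object)
    calls[positive] = "positive"
    calls[negative] = "negative"
    return pd.Series(calls, index=experiment.cell_meta.index, name="genotype_call")
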