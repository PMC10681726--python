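"""Coverage-based chromatin statistics around transcription start sites.

Implements the promoter-proximal RNA Pol II pausing index (mean read density
over the first 50 bp downstream of the TSS divided by mean density over the
whole gene), expression-quartile gene classification, strand-oriented
metagene matrices anchored at the TSS, and the relative change in
nucleosome-occupancy (MNase-seq) read density around the TSS between a
treated and a control track, with the rank-based and t-test group comparisons
used to contrast gene classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import ConfigError, CoverageTrack, GeneModel, InputError

EXPRESSION_CLASSES = ("no_expression", "low", "moderate", "high", "chrd_induced")


@dataclass(frozen=True)
class PausingParams:
    """Pausing-index definition: TSS window size and gene-length floor."""

    tss_window: int = 50
    min_gene_length: int = 200
    body_excludes_window: bool = False  # alternative body-only denominator

    def __post_init__(self) -> None:
        if self.tss_window <= 0:
            raise ConfigError("tss_window must be > 0")
        if self.min_gene_length <= self.tss_window:
            raise ConfigError("min_gene_length must exceed tss_window")


def classify_expression(expression: pd.Series, chrd_genes) -> pd.Series:
    """Split genes into no/low/moderate/high expression plus a ChrD-induced class.

    ChrD-induced genes are set aside first; zero-expression genes form their
    own class; the remaining genes are split into three equal-size bins by
    expression (ties broken by stable input order).
    """
    expression = pd.Series(expression, dtype=float)
    chrd = set(str(g) for g in chrd_genes)
    missing = chrd - set(str(i) for i in expression.index)
    if missing:
        raise InputError(f"ChrD gene(s) absent from expression universe: {sorted(missing)[:5]}")
    labels = pd.Series("no_expression", index=expression.index, dtype=object)
    is_chrd = expression.index.astype(str).isin(chrd)
    labels[is_chrd] = "chrd_induced"
    bin_idx = np.flatnonzero(~is_chrd & (expression.to_numpy() > 0))
    if bin_idx.size:
        order = bin_idx[np.argsort(expression.to_numpy()[bin_idx], kind="stable")]
        for name, part in zip(("low", "moderate", "high"), np.array_split(order, 3)):
            labels.iloc[part] = name
    return labels


def _tss_window_slice(gene: GeneModel, window: int) -> tuple[int, int]:
    """Genomic half-open span of the first ``window`` bases downstream of the TSS."""
    if gene.strand == "+":
        return gene.tss, gene.tss + window
    return gene.tss - window + 1, gene.tss + 1


def pausing_index(track: CoverageTrack, gene: GeneModel, params: PausingParams | None = None) -> float:
    """Pausing index of one gene; NaN when the gene body has zero density.

    The numerator window is the half-open [TSS, TSS + window) in transcription
    direction; the denominator is the whole gene span (including the window by
    default). Invariant under scaling the track by any positive constant.
    """
    params = params or PausingParams()
    if gene.length < params.min_gene_length:
        raise InputError(
            f"gene {gene.gene_id} shorter than min_gene_length ({params.min_gene_length})"
        )
    values = track.values(gene.chrom)
    ws, we = _tss_window_slice(gene, params.tss_window)
    window_mean = values[ws:we].mean()
    if params.body_excludes_window:
        body = np.concatenate([values[gene.start:ws], values[we:gene.end]])
    else:
        body = values[gene.start:gene.end]
    body_mean = body.mean()
    if body_mean == 0:
        return float("nan")
    return float(window_mean / body_mean)


def pausing_indices(track: CoverageTrack, genes, params: PausingParams | None = None) -> pd.DataFrame:
    """Pausing index per gene with a per-gene status (ok / short_gene / zero_body)."""
    params = params or PausingParams()
    rows = []
    for gene in genes:
        if gene.length < params.min_gene_length:
            rows.append({"gene_id": gene.gene_id, "pausing_index": np.nan, "status": "short_gene"})
            continue
        pi = pausing_index(track, gene, params)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "pausing_index": pi,
                "status": "ok" if np.isfinite(pi) else "zero_body",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MetageneMatrix:
    """Genes x position-bins density matrix oriented 5'->3' around the TSS."""

    matrix: np.ndarray
    gene_ids: list[str]
    flank: int
    bin_size: int
    normalization: str = "none"
    n_zero_rows_dropped: int = 0

    @property
    def bin_offsets(self) -> np.ndarray:
        """Transcription-direction offset of each bin's left edge from the TSS."""
        return np.arange(-self.flank, self.flank, self.bin_size)

    @property
    def mean_profile(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.matrix, axis=0)


def metagene(
    track: CoverageTrack,
    genes,
    flank: int = 1000,
    bin_size: int = 50,
    normalization: str = "none",
) -> MetageneMatrix:
    """Reference-point metagene matrix anchored at each gene's TSS.

    Row g, bin b is the mean density over that bin's bases; minus-strand rows
    are reversed so columns read 5'->3'. Bins falling outside the chromosome
    are NaN and excluded from column means. ``normalization`` is ``none``,
    ``per_gene_mean`` (each row divided by its own mean; zero-mean rows set to
    NaN and counted) or ``cpm`` (track scaled to one million total signal).
    """
    if flank % bin_size != 0:
        raise InputError("flank must be a multiple of bin_size")
    if normalization not in ("none", "per_gene_mean", "cpm"):
        raise InputError(f"unknown normalization {normalization!r}")
    n_bins = 2 * flank // bin_size
    scale = 1.0
    if normalization == "cpm":
        total = track.total_signal
        if total <= 0:
            raise InputError("cpm normalization requires positive total signal")
        scale = 1e6 / total
    rows = np.full((len(genes), n_bins), np.nan)
    dropped = 0
    for i, gene in enumerate(genes):
        values = track.values(gene.chrom)
        size = values.size
        if gene.strand == "+":
            lo, hi = gene.tss - flank, gene.tss + flank
        else:
            lo, hi = gene.tss - flank + 1, gene.tss + flank + 1
        window = np.full(2 * flank, np.nan)
        src_lo, src_hi = max(lo, 0), min(hi, size)
        if src_lo < src_hi:
            window[src_lo - lo : src_hi - lo] = values[src_lo:src_hi]
        if gene.strand == "-":
            window = window[::-1]
        row = window.reshape(n_bins, bin_size).mean(axis=1) * scale
        if normalization == "per_gene_mean":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                row_mean = np.nanmean(row)
            if not np.isfinite(row_mean) or row_mean == 0:
                dropped += 1
                row = np.full(n_bins, np.nan)
            else:
                row = row / row_mean
        rows[i] = row
    return MetageneMatrix(
        matrix=rows,
        gene_ids=[g.gene_id for g in genes],
        flank=flank,
        bin_size=bin_size,
        normalization=normalization,
        n_zero_rows_dropped=dropped,
    )


DEFAULT_TSS_WINDOWS = ((-300, -150), (-150, 0), (0, 150), (150, 300))


@dataclass
class TssChangeResult:
    """Per-gene and per-class relative change in TSS-proximal density."""

    per_gene: pd.DataFrame
    per_class: pd.DataFrame
    tests: pd.DataFrame
    n_undefined: int


def mnase_tss_change(
    control: CoverageTrack,
    treated: CoverageTrack,
    genes,
    windows=DEFAULT_TSS_WINDOWS,
    classes: pd.Series | None = None,
    reference_class: str = "chrd_induced",
) -> TssChangeResult:
    """Relative change of mean density around the TSS, treated vs control.

    Both tracks are first scaled to equal total signal (sequencing-depth
    normalization), so uniform depth changes cancel. Windows are half-open
    (from_bp, to_bp] ... [from, to) offsets in transcription direction
    relative to the TSS. Genes with zero control density in a window are
    excluded from that window's class summary and counted. When ``classes``
    is given, per-class means and a two-tailed Welch t-test of the reference
    class against every other class are reported per window.
    """
    if set(control.chroms) != set(treated.chroms):
        raise InputError("control and treated tracks cover different chromosomes")
    depth = control.total_signal / treated.total_signal
    rows = []
    n_undefined = 0
    for gene in genes:
        cvals = control.values(gene.chrom)
        tvals = treated.values(gene.chrom)
        for lo, hi in windows:
            if gene.strand == "+":
                ws, we = gene.tss + lo, gene.tss + hi
            else:
                ws, we = gene.tss - hi + 1, gene.tss - lo + 1
            ws, we = max(ws, 0), min(we, cvals.size)
            c = cvals[ws:we].mean() if we > ws else 0.0
            t = tvals[ws:we].mean() * depth if we > ws else 0.0
            if c == 0:
                change = np.nan
                n_undefined += 1
            else:
                change = (t - c) / c
            rows.append({"gene_id": gene.gene_id, "window": f"{lo}..{hi}", "change": change})
    per_gene = pd.DataFrame(rows)
    per_class = pd.DataFrame()
    tests = pd.DataFrame()
    if classes is not None:
        classes = pd.Series(classes)
        per_gene["class"] = per_gene["gene_id"].map(classes).to_numpy()
        defined = per_gene.dropna(subset=["change"])
        per_class = (
            defined.groupby(["class", "window"], sort=False)["change"]
            .agg(mean="mean", sd="std", n="size")
            .reset_index()
        )
        test_rows = []
        for window in defined["window"].unique():
            sub = defined[defined["window"] == window]
            ref = sub.loc[sub["class"] == reference_class, "change"].to_numpy()
            for other in sub["class"].unique():
                if other == reference_class:
                    continue
                vals = sub.loc[sub["class"] == other, "change"].to_numpy()
                if ref.size < 2 or vals.size < 2:
                    t_stat, p = np.nan, np.nan
                elif np.var(ref) == 0 and np.var(vals) == 0:
                    same = ref.mean() == vals.mean()
                    t_stat, p = (0.0, 1.0) if same else (np.inf, 0.0)
                else:
                    t_stat, p = stats.ttest_ind(ref, vals, equal_var=False)
                test_rows.append(
                    {
                        "window": window,
                        "class_a": reference_class,
                        "class_b": other,
                        "t": float(t_stat),
                        "p": float(p),
                    }
                )
        tests = pd.DataFrame(test_rows)
    return TssChangeResult(per_gene=per_gene, per_class=per_class, tests=tests, n_undefined=n_undefined)


def compare_groups_ranked(values_by_class: dict) -> tuple[float, float]:
    """Kruskal-Wallis rank test across classes; returns (H, p).

    Classes with fewer than 2 values are excluded with a warning; fully tied
    data yield H = 0, p = 1 by convention.
    """
    usable = {}
    for name, values in values_by_class.items():
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < 2:
            warnings.warn(f"class {name!r} has <2 values and is excluded", stacklevel=2)
            continue
        usable[name] = arr
    if len(usable) < 2:
        raise InputError("need at least 2 classes with >=2 values")
    pooled = np.concatenate(list(usable.values()))
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*usable.values())
    return float(h), float(p)
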