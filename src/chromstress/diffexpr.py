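"""Normalization, differential testing, FDR control and over-representation.

Differentially expressed genes (DEGs) are defined by fold change > 1.5 in
either direction and Benjamini-Hochberg adjusted p < 0.05. Two test modes are
provided: a negative-binomial Wald test on median-of-ratios-normalized
pseudobulk counts (method-of-moments dispersion shrunk 50% toward a fitted
mean-dispersion trend), and a tie-corrected Wilcoxon rank-sum test on
library-size-normalized per-cell counts for single-cell contrasts.
Over-representation of DEG lists in supplied gene sets uses the exact
hypergeometric upper tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .models import ConfigError, GeneSetCollection, InputError, NormalizationError

LOG2FC_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class DECriteria:
    fc_min: float = 1.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.fc_min <= 1.0:
            raise ConfigError("fc_min must be > 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")

    @property
    def log2fc_min(self) -> float:
        return float(np.log2(self.fc_min))


def _as_dense(counts) -> np.ndarray:
    if sparse.issparse(counts):
        return np.asarray(counts.todense(), dtype=float)
    return np.asarray(counts, dtype=float)


def size_factors(counts) -> np.ndarray:
    """Median-of-ratios size factors (samples x genes).

    Each sample's factor is the median, over genes positive in every sample,
    of that sample's count divided by the gene's geometric mean. Factors are
    scale-equivariant: multiplying all counts by c multiplies all factors by c.
    """
    x = _as_dense(counts)
    if x.shape[0] < 2:
        raise InputError("size factors require at least 2 samples")
    usable = (x > 0).all(axis=0)
    if not usable.any():
        raise NormalizationError("no gene has positive counts in all samples")
    logs = np.log(x[:, usable])
    log_ratios = logs - logs.mean(axis=0, keepdims=True)
    return np.exp(np.median(log_ratios, axis=1))


def library_size_factors(counts) -> np.ndarray:
    """Total-count factors scaled to geometric mean 1 (sparse scRNA matrices)."""
    x = counts
    totals = np.asarray(x.sum(axis=1)).ravel().astype(float)
    if (totals <= 0).any():
        raise NormalizationError("a cell has zero total counts")
    return totals / np.exp(np.mean(np.log(totals)))


def poscounts_size_factors(counts) -> np.ndarray:
    """Median-of-ratios factors tolerant of zeros (per-cell matrices).

    Gene-wise geometric means are taken over cells with a nonzero count, and
    each cell's factor is the median ratio over its detected genes — the
    sparse-data adaptation of median-of-ratios. Unlike total-count scaling
    this is robust to composition shifts where a large planted program
    inflates library size.
    """
    x = _as_dense(counts)
    if x.shape[0] < 2:
        raise InputError("size factors require at least 2 samples")
    with np.errstate(divide="ignore"):
        logx = np.where(x > 0, np.log(np.maximum(x, 1e-300)), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-zero genes
        geo = np.nanmean(logx, axis=0)
    usable = np.isfinite(geo)
    if not usable.any():
        raise NormalizationError("no gene is detected in any sample")
    ratios = logx[:, usable] - geo[usable]
    factors = np.exp(np.nanmedian(ratios, axis=1))
    if not np.isfinite(factors).all() or (factors <= 0).any():
        raise NormalizationError("a cell has no detected usable gene")
    return factors / np.exp(np.mean(np.log(factors)))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    padj_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, clipped
    at 1 and mapped back to the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _rank_sum_pvalues(normalized: np.ndarray, in_b: np.ndarray) -> np.ndarray:
    """Two-sided tie-corrected Wilcoxon rank-sum p per gene (normal approx)."""
    n = normalized.shape[0]
    n_b = int(in_b.sum())
    n_a = n - n_b
    ranks = stats.rankdata(normalized, axis=0, method="average")
    r_b = ranks[in_b].sum(axis=0)
    expected = n_b * (n + 1) / 2.0
    # tie correction: sum of (t^3 - t) over tied groups, per gene
    tie_term = np.empty(normalized.shape[1])
    for j in range(normalized.shape[1]):
        _, counts = np.unique(normalized[:, j], return_counts=True)
        tie_term[j] = np.sum(counts.astype(float) ** 3 - counts)
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (r_b - expected) / np.maximum(sd, 1e-300), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.minimum(p, 1.0)


def _fit_dispersion_trend(mu: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Fit alpha ~ a0 + a1/mu on genes with usable moment estimates."""
    usable = (mu > 0) & (alpha_mom > 0)
    if usable.sum() < 2:
        return np.full_like(mu, max(float(np.median(alpha_mom[alpha_mom > 0]) if (alpha_mom > 0).any() else 0.01), 1e-8))
    X = np.column_stack([np.ones(usable.sum()), 1.0 / mu[usable]])
    coef, *_ = np.linalg.lstsq(X, alpha_mom[usable], rcond=None)
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.maximum(mu, 1e-8)
    return np.maximum(trend, 1e-8)


def _wald_pvalues(x: np.ndarray, sf: np.ndarray, in_b: np.ndarray) -> np.ndarray:
    """NB Wald test on the group log2 fold change, pseudobulk replicates."""
    norm = x / sf[:, None]
    mu_a = norm[~in_b].mean(axis=0)
    mu_b = norm[in_b].mean(axis=0)
    # method-of-moments dispersion pooled within groups, shrunk 50% to trend
    resid_var = np.zeros(x.shape[1])
    dof = 0
    for grp in (~in_b, in_b):
        if grp.sum() > 1:
            resid_var += norm[grp].var(axis=0, ddof=1) * (grp.sum() - 1)
            dof += grp.sum() - 1
    mu_all = norm.mean(axis=0)
    if dof > 0:
        s2 = resid_var / dof
        with np.errstate(invalid="ignore", divide="ignore"):
            alpha_mom = np.where(mu_all > 0, (s2 - mu_all) / np.maximum(mu_all, 1e-8) ** 2, 0.0)
        alpha_mom = np.maximum(alpha_mom, 0.0)
    else:
        alpha_mom = np.zeros(x.shape[1])
    alpha = 0.5 * alpha_mom + 0.5 * _fit_dispersion_trend(mu_all, alpha_mom)

    inv_sf = 1.0 / sf
    mean_inv_sf_a = inv_sf[~in_b].mean()
    mean_inv_sf_b = inv_sf[in_b].mean()
    n_a, n_b = int((~in_b).sum()), int(in_b.sum())
    var_a = (mu_a * mean_inv_sf_a + alpha * mu_a**2) / n_a
    var_b = (mu_b * mean_inv_sf_b + alpha * mu_b**2) / n_b
    c = LOG2FC_PSEUDOCOUNT
    ln2sq = np.log(2.0) ** 2
    se2 = var_a / ((mu_a + c) ** 2 * ln2sq) + var_b / ((mu_b + c) ** 2 * ln2sq)
    lfc = np.log2(mu_b + c) - np.log2(mu_a + c)
    se = np.sqrt(np.maximum(se2, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, lfc / np.maximum(se, 1e-300), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    both_zero = (mu_a == 0) & (mu_b == 0)
    p[both_zero] = 1.0
    return np.minimum(p, 1.0)


def nb_test(
    counts,
    groups,
    mode: str = "per_cell",
    gene_ids=None,
    levels: tuple[str, str] | None = None,
    criteria: DECriteria | None = None,
) -> pd.DataFrame:
    """Two-group differential expression test.

    ``counts`` is samples/cells x genes; ``groups`` a two-level factor. The
    log2 fold change is level B (``levels[1]``) over level A, computed from
    size-factor-normalized group means with a 0.5 pseudocount. ``mode`` is
    ``"per_cell"`` (Wilcoxon rank-sum on normalized counts) or
    ``"pseudobulk"`` (NB Wald with moderated dispersion). Returns a DataFrame
    with columns log2fc, p, padj, direction, is_deg, mean_a, mean_b, note.
    """
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if levels is None:
        levels = tuple(sorted(uniq))
    if len(uniq) != 2 or set(levels) != set(uniq):
        raise InputError(f"groups must take exactly the two levels {levels}, got {list(uniq)}")
    in_b = groups == levels[1]
    if in_b.all() or not in_b.any():
        raise InputError("both groups must be non-empty")
    criteria = criteria or DECriteria()

    x = _as_dense(counts)
    if x.size and not np.allclose(x, np.round(x)):
        raise InputError("counts must be integral")
    if mode == "per_cell":
        sf = poscounts_size_factors(x)
    elif mode == "pseudobulk":
        sf = size_factors(x)
    else:
        raise InputError(f"unknown mode {mode!r}")
    normalized = x / sf[:, None]
    mu_a = normalized[~in_b].mean(axis=0)
    mu_b = normalized[in_b].mean(axis=0)
    c = LOG2FC_PSEUDOCOUNT
    lfc = np.log2(mu_b + c) - np.log2(mu_a + c)

    if mode == "per_cell":
        p = _rank_sum_pvalues(normalized, in_b)
    else:
        p = _wald_pvalues(x, sf, in_b)

    note = np.where((mu_a == 0) & (mu_b == 0), "zero_in_both_groups", "")
    padj = bh_adjust(p)
    result = pd.DataFrame(
        {
            "gene": list(gene_ids) if gene_ids is not None else np.arange(x.shape[1]),
            "mean_a": mu_a,
            "mean_b": mu_b,
            "log2fc": lfc,
            "p": p,
            "padj": padj,
            "note": note,
        }
    )
    result["direction"] = np.where(result["log2fc"] >= 0, "up", "down")
    result["is_deg"] = (result["padj"] < criteria.alpha) & (
        result["log2fc"].abs() > criteria.log2fc_min
    )
    result.attrs["n_a"] = int((~in_b).sum())
    result.attrs["n_b"] = int(in_b.sum())
    result.attrs["levels"] = levels
    return result


def count_degs(result: pd.DataFrame, criteria: DECriteria | None = None):
    """Count DEGs under the criteria: returns (n_total, n_up, n_down)."""
    criteria = criteria or DECriteria()
    if len(result) == 0:
        return 0, 0, 0
    deg = (result["padj"] < criteria.alpha) & (result["log2fc"].abs() > criteria.log2fc_min)
    up = int((deg & (result["log2fc"] > 0)).sum())
    down = int((deg & (result["log2fc"] < 0)).sum())
    return int(deg.sum()), up, down


def deg_list(result: pd.DataFrame, criteria: DECriteria | None = None) -> list[str]:
    criteria = criteria or DECriteria()
    deg = (result["padj"] < criteria.alpha) & (result["log2fc"].abs() > criteria.log2fc_min)
    return result.loc[deg, "gene"].astype(str).tolist()


def hypergeometric_enrichment(deg_list, universe, sets: GeneSetCollection) -> pd.DataFrame:
    """Over-representation of a DEG list in each gene set (hypergeometric tail).

    For each set, p = P(X >= overlap) with X ~ Hypergeom(N=|universe|,
    K=|set within universe|, n=|list|); BH adjustment across sets.
    """
    universe = list(dict.fromkeys(str(g) for g in universe))
    uni = set(universe)
    degs = list(dict.fromkeys(str(g) for g in deg_list))
    missing = [g for g in degs if g not in uni]
    if missing:
        raise InputError(f"DEG(s) absent from universe: {missing[:5]}")
    rows = []
    for name, members in sets:
        in_uni = [m for m in members if m in uni]
        overlap = len(set(in_uni) & set(degs))
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(in_uni), len(degs)))
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "set_size": len(in_uni),
                "universe_size": len(universe),
                "list_size": len(degs),
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_adjust(out["p"].to_numpy())
    return out
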