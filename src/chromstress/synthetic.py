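"""Synthetic experiments with known ground truth.

Two generators mirror the study design the analysis modules assume:

* :func:`simulate_cell_experiment` builds a hashtag-multiplexed single-cell
  pool of three conditions (untreated control, a chromatin-damage treatment
  and a DNA-damage treatment) over a mixed population of p53-positive and
  p53-knockout cells. Planted transcriptional programs follow the biology the
  pipeline is meant to detect: p53-target induction restricted to p53-positive
  treated cells, a genotype-independent stress program induced only by
  chromatin damage, and cell-cycle repression in arrested cells (all
  chromatin-damage-treated cells, plus p53-positive DNA-damage-treated cells).
* :func:`simulate_paused_coverage` / :func:`simulate_mnase_pair` build
  base-resolution coverage tracks with configurable promoter-proximal read
  enrichment (RNA Pol II pausing) and treatment-dependent promoter nucleosome
  depletion.

Every random draw flows from a single seed through one named generator; runs
are bit-reproducible. The marker channels (TP53, MDM2, hashtag signal) are
modeled with structural floors so that with all noise channels closed
(dropout 0, ambient 0) the downstream classification rules recover the truth
exactly; noise enters only through the explicit dropout and ambient-count
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .models import CellExperiment, ConfigError, CoverageTrack, GeneModel

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class ScSimConfig:
    """Parameters of the simulated single-cell experiment.

    Defaults encode the study conditions: 500 cells per condition, three
    hashtagged conditions, an ~1:1 p53-positive/negative mix, and program
    sizes scaled to a 2000-gene universe.
    """

    n_cells_per_condition: int = 500
    conditions: tuple[str, ...] = ("control", "ChrD", "DnaD")
    frac_p53_negative: float = 0.5
    n_genes: int = 2000
    # planted programs (disjoint; sizes exclude the TP53/MDM2 markers)
    n_p53_targets: int = 25
    p53_target_log2fc: float = 2.0
    n_chrd_program: int = 400
    chrd_log2fc: float = 1.5
    n_cell_cycle: int = 50
    cell_cycle_log2fc: float = -1.5
    # baseline expression and noise
    baseline_mean_log: float = float(np.log(15.0))
    baseline_mean_sigma: float = 1.0
    nb_dispersion: float = 0.1
    cell_size_sigma: float = 0.1
    # marker channel (TP53 / MDM2)
    dropout: float = 0.3  # TP53 capture failure in p53-positive cells
    mdm2_dropout: float = 0.0
    tp53_mean: float = 2.0
    mdm2_neg_mean: float = 0.3
    mdm2_pos_mean: float = 8.0
    mdm2_pos_treated_mean: float = 16.0
    # hashtag channel
    hto_signal_mean: float = 3000.0
    hto_signal_floor: int = 512
    hto_ambient_mean: float = 5.0
    hto_dispersion: float = 0.1
    # doublets and mitochondria
    doublet_rate: float = 0.05
    n_mito_genes: int = 10
    mito_fraction_mean: float = 0.03
    mito_fraction_conc: float = 100.0
    mito_prefix: str = "MT-"
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_p53_negative", "dropout", "mdm2_dropout", "doublet_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.doublet_rate >= 1.0:
            raise ConfigError("doublet_rate must be < 1")
        reserved = 2 + self.n_mito_genes  # TP53, MDM2, mito genes
        n_program = self.n_p53_targets + self.n_chrd_program + self.n_cell_cycle
        if n_program + reserved > self.n_genes:
            raise ConfigError(
                f"programs ({n_program}) plus markers/mito ({reserved}) exceed "
                f"gene universe ({self.n_genes})"
            )
        for name in ("p53_target_log2fc", "chrd_log2fc", "cell_cycle_log2fc"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")
        if not 0 < self.mito_fraction_mean < 1:
            raise ConfigError("mito_fraction_mean must be in (0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth: per-cell origin/genotype and per-gene planted effects."""

    cells: pd.DataFrame = field(default_factory=pd.DataFrame)
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)


def _gene_table(config: ScSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Gene universe with program membership and baseline means."""
    ids, programs = [], []
    ids += ["TP53", "MDM2"]
    programs += ["marker", "marker"]
    for i in range(config.n_mito_genes):
        ids.append(f"{config.mito_prefix}{i + 1}")
        programs.append("mito")
    n_ordinary = config.n_genes - len(ids)
    ordinary = [f"G{i + 1:05d}" for i in range(n_ordinary)]
    ids += ordinary
    labels = (
        ["p53_target"] * config.n_p53_targets
        + ["chrd_program"] * config.n_chrd_program
        + ["cell_cycle"] * config.n_cell_cycle
    )
    labels += ["none"] * (n_ordinary - len(labels))
    programs += labels
    baseline = np.exp(
        rng.normal(config.baseline_mean_log, config.baseline_mean_sigma, size=config.n_genes)
    )
    baseline[:2 + config.n_mito_genes] = 0.0  # markers and mito drawn separately
    genes = pd.DataFrame({"gene_id": ids, "program": programs, "baseline_mean": baseline})

    prog = genes["program"].to_numpy()
    for cond in config.conditions[1:]:
        for geno in (POSITIVE, NEGATIVE):
            lfc = np.zeros(config.n_genes)
            if geno == POSITIVE:
                lfc[prog == "p53_target"] = config.p53_target_log2fc
            if cond == "ChrD":
                lfc[prog == "chrd_program"] = config.chrd_log2fc
                lfc[prog == "cell_cycle"] = config.cell_cycle_log2fc
            elif cond == "DnaD" and geno == POSITIVE:
                lfc[prog == "cell_cycle"] = config.cell_cycle_log2fc
            genes[f"lfc_{cond}_{geno}"] = lfc
    return genes


def _draw_gene_counts(config, genes, conditions, genotypes, rng):
    """NB (gamma-Poisson) counts for a batch of cells, markers/mito excluded."""
    n_cells = len(conditions)
    baseline = genes["baseline_mean"].to_numpy()
    size = np.exp(rng.normal(0.0, config.cell_size_sigma, size=n_cells))
    counts = np.zeros((n_cells, config.n_genes), dtype=np.int64)
    conditions = np.asarray(conditions)
    genotypes = np.asarray(genotypes)
    for cond in np.unique(conditions):
        for geno in (POSITIVE, NEGATIVE):
            rows = np.flatnonzero((conditions == cond) & (genotypes == geno))
            if rows.size == 0:
                continue
            col = f"lfc_{cond}_{geno}"
            lfc = genes[col].to_numpy() if col in genes else np.zeros(config.n_genes)
            mu = size[rows, None] * (baseline * np.exp2(lfc))[None, :]
            d = config.nb_dispersion
            lam = rng.gamma(1.0 / d, d * mu) if d > 0 else mu
            counts[rows] = rng.poisson(lam)
    return counts


def _draw_markers(config, counts, conditions, genotypes, gene_idx, rng):
    """Overwrite TP53/MDM2 columns with the structured marker model."""
    n = len(conditions)
    pos = np.asarray(genotypes) == POSITIVE
    treated = np.asarray(conditions) != config.conditions[0]

    tp53 = np.zeros(n, dtype=np.int64)
    tp53[pos] = 1 + rng.poisson(max(config.tp53_mean - 1.0, 0.0), size=pos.sum())
    tp53[pos & (rng.random(n) < config.dropout)] = 0

    mdm2 = np.minimum(rng.poisson(config.mdm2_neg_mean, size=n), 2)
    mdm2_mean = np.where(treated, config.mdm2_pos_treated_mean, config.mdm2_pos_mean)
    draw = 3 + rng.poisson(np.maximum(mdm2_mean - 3.0, 0.0))
    mdm2[pos] = draw[pos]
    mdm2[pos & (rng.random(n) < config.mdm2_dropout)] = 0

    counts[:, gene_idx["TP53"]] = tp53
    counts[:, gene_idx["MDM2"]] = mdm2


def _draw_mito(config, counts, mito_cols, rng):
    """Add mitochondrial counts so per-cell mito fractions follow a Beta law."""
    n = counts.shape[0]
    a = config.mito_fraction_mean * config.mito_fraction_conc
    b = (1.0 - config.mito_fraction_mean) * config.mito_fraction_conc
    frac = rng.beta(a, b, size=n)
    totals = counts.sum(axis=1)
    mito_total = rng.poisson(totals * frac / (1.0 - frac))
    k = len(mito_cols)
    for i in range(n):
        if mito_total[i] > 0:
            counts[i, mito_cols] = rng.multinomial(mito_total[i], np.full(k, 1.0 / k))


def _draw_hto(config, conditions, rng):
    """Hashtag counts: strong signal for the cell's own condition, ambient elsewhere."""
    n = len(conditions)
    k = len(config.conditions)
    hto = rng.poisson(config.hto_ambient_mean, size=(n, k)).astype(np.int64)
    cond_idx = {c: i for i, c in enumerate(config.conditions)}
    own = np.array([cond_idx[c] for c in conditions])
    extra = config.hto_signal_mean - config.hto_signal_floor
    d = config.hto_dispersion
    lam = rng.gamma(1.0 / d, d * extra, size=n) if d > 0 else np.full(n, extra)
    signal = config.hto_signal_floor + rng.poisson(lam)
    hto[np.arange(n), own] = signal
    return hto


def simulate_cell_experiment(config: ScSimConfig | None = None, *, seed: int | None = None):
    """Simulate a hashtag-multiplexed experiment; returns (experiment, truth).

    Seeded runs are bit-reproducible. ``seed`` overrides ``config.seed``.
    """
    config = config or ScSimConfig()
    config.validate()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)

    genes = _gene_table(config, rng)
    gene_idx = {g: i for i, g in enumerate(genes["gene_id"])}
    mito_cols = np.flatnonzero(genes["program"].to_numpy() == "mito")

    n_singlets = config.n_cells_per_condition * len(config.conditions)
    n_doublets = int(round(config.doublet_rate / (1.0 - config.doublet_rate) * n_singlets))

    sing_cond = np.repeat(config.conditions, config.n_cells_per_condition)
    sing_geno = np.where(rng.random(n_singlets) < config.frac_p53_negative, NEGATIVE, POSITIVE)

    # doublets merge two freshly drawn cells; same- vs cross-condition 50/50
    pa_cond, pb_cond = [], []
    for _ in range(n_doublets):
        c1 = rng.choice(config.conditions)
        if rng.random() < 0.5 or len(config.conditions) == 1:
            c2 = c1
        else:
            c2 = rng.choice([c for c in config.conditions if c != c1])
        pa_cond.append(c1)
        pb_cond.append(c2)
    pa_geno = np.where(rng.random(n_doublets) < config.frac_p53_negative, NEGATIVE, POSITIVE)
    pb_geno = np.where(rng.random(n_doublets) < config.frac_p53_negative, NEGATIVE, POSITIVE)

    def draw_pool(conds, genos):
        counts = _draw_gene_counts(config, genes, conds, genos, rng)
        _draw_markers(config, counts, conds, genos, gene_idx, rng)
        _draw_mito(config, counts, mito_cols, rng)
        hto = _draw_hto(config, conds, rng)
        return counts, hto

    counts_s, hto_s = draw_pool(sing_cond, sing_geno)
    if n_doublets:
        counts_a, hto_a = draw_pool(pa_cond, pa_geno)
        counts_b, hto_b = draw_pool(pb_cond, pb_geno)
        counts = np.vstack([counts_s, counts_a + counts_b])
        hto = np.vstack([hto_s, hto_a + hto_b])
    else:
        counts, hto = counts_s, hto_s

    n_total = counts.shape[0]
    barcodes = [f"BC{i + 1:05d}" for i in range(n_total)]
    cells = pd.DataFrame(
        {
            "barcode": barcodes,
            "condition": list(sing_cond) + list(pa_cond),
            "condition2": [None] * n_singlets + list(pb_cond),
            "genotype": list(sing_geno) + list(pa_geno),
            "is_doublet": [False] * n_singlets + [True] * n_doublets,
        }
    )

    experiment = CellExperiment(
        gene_counts=sparse.csr_matrix(counts),
        hto_counts=hto,
        gene_ids=genes["gene_id"].tolist(),
        hto_ids=list(config.conditions),
        barcode_ids=barcodes,
        mito_mask=genes["gene_id"].str.startswith(config.mito_prefix).to_numpy(),
    )
    return experiment, SyntheticTruth(cells=cells, genes=genes)


# ---------------------------------------------------------------------------
# Coverage simulations
# ---------------------------------------------------------------------------


@dataclass
class CoverageSimConfig:
    """Parameters of the coverage simulations (nascent transcription, MNase)."""

    tss_enrichment: dict[str, float] = field(
        default_factory=lambda: {
            "chrd_induced": 8.0,
            "high": 3.0,
            "moderate": 2.0,
            "low": 1.5,
        }
    )
    reads_per_gene: float = 2000.0
    tss_window: int = 50
    poisson_noise: bool = True
    # MNase model
    mnase_spacing: int = 200
    mnase_amplitude: float = 1.0
    mnase_flank: int = 1000
    promoter_window: tuple[int, int] = (-150, 150)
    depletion: dict[str, float] = field(default_factory=lambda: {"chrd_induced": 0.5})
    compensation_tail: int = 5000
    seed: int = 0

    def validate(self) -> None:
        for name, factors in (("tss_enrichment", self.tss_enrichment), ("depletion", self.depletion)):
            for cls, v in factors.items():
                if v <= 0:
                    raise ConfigError(f"{name}[{cls!r}] must be > 0, got {v}")
        if self.tss_window <= 0 or self.reads_per_gene <= 0:
            raise ConfigError("tss_window and reads_per_gene must be positive")


def make_gene_models(
    n: int,
    length: int = 2000,
    gap: int = 3000,
    chrom: str = "chrS",
    margin: int = 6000,
    alternate_strands: bool = True,
) -> list[GeneModel]:
    """Tile ``n`` non-overlapping genes on one synthetic chromosome.

    Gaps of ``gap`` bp (>= 2 kb by default) keep metagene flanks from
    colliding; ``margin`` bp are left free at both chromosome ends.
    """
    genes = []
    pos = margin
    for i in range(n):
        strand = "-" if (alternate_strands and i % 2) else "+"
        genes.append(
            GeneModel(gene_id=f"SG{i + 1:04d}", chrom=chrom, strand=strand, start=pos, end=pos + length)
        )
        pos += length + gap
    return genes


_TAIL_BUFFER = 2000  # keeps the compensation tail clear of gene flanks


def _chrom_sizes(genes, tail: int) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for g in genes:
        sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.end + _TAIL_BUFFER + tail)
    return sizes


def _assign_classes(genes, class_names):
    """Round-robin class assignment so every class spans the gene tiling."""
    return [class_names[i % len(class_names)] for i in range(len(genes))]


def _tss_window_span(gene: GeneModel, window: int) -> tuple[int, int]:
    """Genomic span of the first ``window`` bases downstream of the TSS."""
    if gene.strand == "+":
        return gene.tss, gene.tss + window
    return gene.tss - window + 1, gene.tss + 1


def simulate_paused_coverage(config: CoverageSimConfig, genes: list[GeneModel]):
    """Nascent-transcription-like coverage with per-class TSS read enrichment.

    Each gene's expected density is uniform over its body except the first
    ``tss_window`` bases downstream of the TSS, which are scaled by its
    class's enrichment factor; per-base Poisson noise is optional.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    classes = _assign_classes(genes, list(config.tss_enrichment))
    sizes = _chrom_sizes(genes, config.compensation_tail)
    chroms = {c: np.zeros(s) for c, s in sizes.items()}
    w = config.tss_window
    for gene, cls in zip(genes, classes):
        e = config.tss_enrichment[cls]
        if gene.length <= w:
            raise ConfigError(f"gene {gene.gene_id} shorter than the TSS window")
        rate = config.reads_per_gene / (gene.length - w + w * e)
        arr = chroms[gene.chrom]
        arr[gene.start : gene.end] += rate
        ws, we = _tss_window_span(gene, w)
        arr[ws:we] += rate * (e - 1.0)
    if config.poisson_noise:
        chroms = {c: rng.poisson(v).astype(float) for c, v in chroms.items()}
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "class": classes,
            "tss_enrichment": [config.tss_enrichment[c] for c in classes],
        }
    )
    return CoverageTrack(chroms), SyntheticTruth(genes=truth)


def simulate_mnase_pair(config: CoverageSimConfig, genes: list[GeneModel]):
    """Control/treated nucleosome-occupancy tracks with promoter depletion.

    Both tracks share phased nucleosome peaks around every gene; in the
    treated track, density inside the promoter window of depleted classes is
    multiplied by the class's depletion factor. The depleted mass is returned
    as uniform intergenic background at each chromosome tail so both tracks
    carry equal total signal (equal sequencing depth), making planted relative
    changes exact in the noise-free case.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    classes = _assign_classes(genes, list(config.tss_enrichment))
    sizes = _chrom_sizes(genes, config.compensation_tail)
    control = {c: np.zeros(s) for c, s in sizes.items()}
    for gene in genes:
        lo = max(gene.start - config.mnase_flank, 0)
        hi = min(gene.end + config.mnase_flank, sizes[gene.chrom])
        x = np.arange(lo, hi)
        control[gene.chrom][lo:hi] += config.mnase_amplitude * (
            1.0 + np.cos(2.0 * np.pi * (x - gene.tss) / config.mnase_spacing)
        )
    treated = {c: v.copy() for c, v in control.items()}
    lo_off, hi_off = config.promoter_window
    for gene, cls in zip(genes, classes):
        f = config.depletion.get(cls, 1.0)
        if f == 1.0:
            continue
        if gene.strand == "+":
            ws, we = gene.tss + lo_off, gene.tss + hi_off
        else:
            ws, we = gene.tss - hi_off + 1, gene.tss - lo_off + 1
        treated[gene.chrom][ws:we] *= f
    # return the depleted mass as intergenic background: equal depth by design
    for chrom in sizes:
        deficit = control[chrom].sum() - treated[chrom].sum()
        if deficit > 0:
            tail = config.compensation_tail
            treated[chrom][-tail:] += deficit / tail
    if config.poisson_noise:
        control = {c: rng.poisson(v).astype(float) for c, v in control.items()}
        treated = {c: rng.poisson(v).astype(float) for c, v in treated.items()}
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "class": classes,
            "depletion": [config.depletion.get(c, 1.0) for c in classes],
        }
    )
    return CoverageTrack(control), CoverageTrack(treated), SyntheticTruth(genes=truth)
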