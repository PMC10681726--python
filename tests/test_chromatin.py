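import numpy as np
import pandas as pd
import pytest

from chromstress import (
    CoverageSimConfig,
    CoverageTrack,
    GeneModel,
    PausingParams,
    classify_expression,
    compare_groups_ranked,
    make_gene_models,
    metagene,
    mnase_tss_change,
    pausing_index,
    pausing_indices,
    simulate_mnase_pair,
    simulate_paused_coverage,
)
from chromstress.models import InputError


def brute_force_pi(track, gene, window=50):
    """Per-base oracle for the pausing index."""
    values = track.values(gene.chrom)
    if gene.strand == "+":
        win = [values[gene.tss + i] for i in range(window)]
    else:
        win = [values[gene.tss - i] for i in range(window)]
    body = [values[i] for i in range(gene.start, gene.end)]
    body_mean = sum(body) / len(body)
    if body_mean == 0:
        return float("nan")
    return (sum(win) / len(win)) / body_mean


def brute_force_metagene_row(track, gene, flank, bin_size):
    """Per-base oracle for one metagene row (transcription-direction offsets)."""
    values = track.values(gene.chrom)
    size = values.size
    row = []
    for b in range(2 * flank // bin_size):
        acc = []
        for k in range(bin_size):
            offset = -flank + b * bin_size + k
            pos = gene.tss + offset if gene.strand == "+" else gene.tss - offset
            acc.append(values[pos] if 0 <= pos < size else np.nan)
        row.append(np.mean(acc))
    return np.array(row)


class TestClassifyExpression:
    def test_four_way_split(self):
        expr = pd.Series([0.0, 1.0, 5.0, 100.0], index=["a", "b", "c", "d"])
        labels = classify_expression(expr, chrd_genes=[])
        assert labels.tolist() == ["no_expression", "low", "moderate", "high"]

    def test_all_zero(self):
        expr = pd.Series([0.0, 0.0], index=["a", "b"])
        assert (classify_expression(expr, []) == "no_expression").all()

    def test_chrd_genes_removed_before_binning(self):
        expr = pd.Series([0.0, 1.0, 5.0, 100.0, 7.0], index=list("abcde"))
        labels = classify_expression(expr, chrd_genes=["d"])
        assert labels["d"] == "chrd_induced"
        # bins recomputed over b, c, e only
        assert labels[["b", "c", "e"]].tolist() == ["low", "moderate", "high"]

    def test_unknown_chrd_gene_rejected(self):
        with pytest.raises(InputError):
            classify_expression(pd.Series([1.0], index=["a"]), ["zzz"])


class TestPausingIndex:
    def test_uniform_coverage_gives_exactly_one(self):
        gene = GeneModel("g", "chr1", "+", 100, 1100)
        track = CoverageTrack({"chr1": np.ones(1200)})
        assert pausing_index(track, gene) == 1.0

    def test_derived_value_on_stepped_profile(self):
        # density 10 over first 50 bp, 1 over remaining 950 -> PI = 10/1.45
        arr = np.zeros(1200)
        arr[100:150] = 10.0
        arr[150:1100] = 1.0
        gene = GeneModel("g", "chr1", "+", 100, 1100)
        track = CoverageTrack({"chr1": arr})
        assert pausing_index(track, gene) == pytest.approx(10 / 1.45, rel=1e-12)

    def test_minus_strand_mirrored_profile_identical(self):
        arr = np.zeros(1200)
        arr[1050:1100] = 10.0  # last 50 bases = first 50 downstream of minus TSS
        arr[100:1050] = 1.0
        gene = GeneModel("g", "chr1", "-", 100, 1100)
        track = CoverageTrack({"chr1": arr})
        assert pausing_index(track, gene) == pytest.approx(10 / 1.45, rel=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        arr = rng.poisson(3, 1500).astype(float)
        gene = GeneModel("g", "chr1", "+", 200, 1200)
        track = CoverageTrack({"chr1": arr})
        assert pausing_index(track.scaled(17.0), gene) == pytest.approx(
            pausing_index(track, gene), rel=1e-12
        )

    def test_short_gene_raises_and_batch_skips(self):
        gene = GeneModel("tiny", "chr1", "+", 0, 100)
        track = CoverageTrack({"chr1": np.ones(200)})
        with pytest.raises(InputError):
            pausing_index(track, gene)
        table = pausing_indices(track, [gene])
        assert table["status"].iloc[0] == "short_gene"

    def test_zero_body_reported_undefined(self):
        gene = GeneModel("g", "chr1", "+", 100, 400)
        track = CoverageTrack({"chr1": np.zeros(600)})
        table = pausing_indices(track, [gene])
        assert table["status"].iloc[0] == "zero_body"
        assert np.isnan(table["pausing_index"].iloc[0])

    def test_agrees_with_brute_force_on_synthetic_genome(self):
        genes = make_gene_models(20, length=1000)
        cfg = CoverageSimConfig(tss_enrichment={"a": 6.0, "b": 2.0}, seed=1)
        track, _ = simulate_paused_coverage(cfg, genes)
        fast = pausing_indices(track, genes)["pausing_index"].to_numpy()
        slow = np.array([brute_force_pi(track, g) for g in genes])
        np.testing.assert_allclose(fast, slow, rtol=1e-9)


class TestMetagene:
    def test_constant_track_flat_profile(self):
        genes = make_gene_models(4, length=1000)
        track = CoverageTrack({"chrS": np.full(30000, 3.5)})
        mg = metagene(track, genes, flank=500, bin_size=50)
        np.testing.assert_allclose(mg.matrix, 3.5)
        np.testing.assert_allclose(mg.mean_profile, 3.5)
        assert mg.matrix.shape == (4, 2 * 500 // 50)

    def test_spike_orientation_contract(self):
        """A spike one bin downstream of the TSS peaks at the same column for
        plus- and minus-strand genes."""
        plus = GeneModel("p", "chr1", "+", 5000, 7000)
        minus = GeneModel("m", "chr1", "-", 10000, 12000)
        arr = np.zeros(20000)
        arr[plus.tss + 60] = 100.0  # bin index flank/bin + 1
        arr[minus.tss - 60] = 100.0
        track = CoverageTrack({"chr1": arr})
        mg = metagene(track, [plus, minus], flank=500, bin_size=50)
        col = 500 // 50 + 1
        assert mg.matrix[0].argmax() == col
        assert mg.matrix[1].argmax() == col

    def test_agrees_with_brute_force_on_50_gene_genome(self):
        genes = make_gene_models(50, length=1000)
        cfg = CoverageSimConfig(tss_enrichment={"a": 5.0, "b": 1.5}, seed=2)
        track, _ = simulate_paused_coverage(cfg, genes)
        mg = metagene(track, genes, flank=400, bin_size=40)
        for i, g in enumerate(genes):
            np.testing.assert_allclose(
                mg.matrix[i], brute_force_metagene_row(track, g, 400, 40), atol=1e-9
            )

    def test_row_permutation_invariance(self):
        genes = make_gene_models(6, length=1000)
        cfg = CoverageSimConfig(tss_enrichment={"a": 3.0}, seed=3)
        track, _ = simulate_paused_coverage(cfg, genes)
        mg = metagene(track, genes, flank=200, bin_size=20)
        perm = [3, 1, 5, 0, 2, 4]
        mg_perm = metagene(track, [genes[i] for i in perm], flank=200, bin_size=20)
        np.testing.assert_allclose(mg_perm.matrix, mg.matrix[perm])
        np.testing.assert_allclose(mg_perm.mean_profile, mg.mean_profile)

    def test_chromosome_edge_padded_with_nan(self):
        gene = GeneModel("edge", "chr1", "+", 10, 500)
        track = CoverageTrack({"chr1": np.ones(600)})
        mg = metagene(track, [gene], flank=100, bin_size=50)
        assert np.isnan(mg.matrix[0, 0])  # bin entirely upstream of position 0
        assert np.isfinite(mg.matrix[0, -1])

    def test_per_gene_mean_drops_zero_rows(self):
        genes = [GeneModel("z", "chr1", "+", 1000, 2000), GeneModel("v", "chr1", "+", 5000, 6000)]
        arr = np.zeros(10000)
        arr[4500:6500] = 2.0
        track = CoverageTrack({"chr1": arr})
        mg = metagene(track, genes, flank=200, bin_size=50, normalization="per_gene_mean")
        assert mg.n_zero_rows_dropped == 1
        assert np.isnan(mg.matrix[0]).all()
        np.testing.assert_allclose(mg.matrix[1], 1.0)


class TestMnaseChange:
    def _classes(self, truth):
        return truth.genes.set_index("gene_id")["class"]

    def test_identical_tracks_zero_change_and_null_test(self):
        genes = make_gene_models(8, length=1000)
        cfg = CoverageSimConfig(
            tss_enrichment={"chrd_induced": 1.0, "high": 1.0}, depletion={}, poisson_noise=False
        )
        control, treated, truth = simulate_mnase_pair(cfg, genes)
        res = mnase_tss_change(control, treated, genes, classes=self._classes(truth))
        defined = res.per_gene["change"].dropna()
        np.testing.assert_allclose(defined, 0.0, atol=1e-12)
        assert (res.tests["p"] == 1.0).all()

    def test_planted_depletion_gives_exact_minus_half(self):
        genes = make_gene_models(10, length=1000)
        cfg = CoverageSimConfig(
            tss_enrichment={"chrd_induced": 1.0, "high": 1.0}, depletion={"chrd_induced": 0.5},
            poisson_noise=False,
        )
        control, treated, truth = simulate_mnase_pair(cfg, genes)
        res = mnase_tss_change(control, treated, genes, classes=self._classes(truth))
        summary = res.per_class.set_index(["class", "window"])["mean"]
        assert summary[("chrd_induced", "-150..0")] == pytest.approx(-0.5, abs=1e-12)
        assert summary[("chrd_induced", "0..150")] == pytest.approx(-0.5, abs=1e-12)
        assert summary[("high", "-150..0")] == pytest.approx(0.0, abs=1e-12)
        assert summary[("chrd_induced", "-300..-150")] == pytest.approx(0.0, abs=1e-12)

    def test_depth_scaling_cancels(self):
        genes = make_gene_models(6, length=1000)
        cfg = CoverageSimConfig(tss_enrichment={"a": 1.0}, depletion={"a": 0.7}, poisson_noise=False)
        control, treated, truth = simulate_mnase_pair(cfg, genes)
        res1 = mnase_tss_change(control, treated, genes, classes=self._classes(truth))
        res2 = mnase_tss_change(control, treated.scaled(2.0), genes, classes=self._classes(truth))
        np.testing.assert_allclose(
            res1.per_gene["change"], res2.per_gene["change"], rtol=1e-12
        )

    def test_mismatched_chromosomes_rejected(self):
        a = CoverageTrack({"chr1": np.ones(10)})
        b = CoverageTrack({"chr2": np.ones(10)})
        with pytest.raises(InputError):
            mnase_tss_change(a, b, [])


class TestCompareGroupsRanked:
    def test_fully_tied_data_convention(self):
        assert compare_groups_ranked({"a": [2.0, 2.0], "b": [2.0, 2.0]}) == (0.0, 1.0)

    def test_hand_ranked_oracle(self):
        # ranks 1..6 -> H = 12/(6*7) * (36/3 + 225/3) - 21 = 27/7
        h, p = compare_groups_ranked({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert h == pytest.approx(27 / 7, rel=1e-12)
        assert 0 < p < 1

    def test_small_class_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            h, p = compare_groups_ranked({"a": [1, 2, 3], "b": [4, 5, 6], "c": [9]})
        assert h == pytest.approx(27 / 7, rel=1e-12)

    def test_too_few_classes_rejected(self):
        with pytest.raises(InputError):
            compare_groups_ranked({"a": [1, 2, 3]})

    def test_detects_planted_pausing_ordering(self):
        genes = make_gene_models(120, length=1000)
        cfg = CoverageSimConfig(seed=4)  # chrd 8 > high 3 > moderate 2 > low 1.5
        track, truth = simulate_paused_coverage(cfg, genes)
        pi = pausing_indices(track, genes).merge(truth.genes, on="gene_id")
        groups = {c: g["pausing_index"].to_numpy() for c, g in pi.groupby("class")}
        h, p = compare_groups_ranked(groups)
        assert p < 0.05
        medians = pi.groupby("class")["pausing_index"].median()
        assert (
            medians["chrd_induced"] > medians["high"] > medians["moderate"] > medians["low"]
        )
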