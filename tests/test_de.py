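"""FPKM, the low-expression filter, BH, and the NB Wald engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hetexpress.data import CountMatrix, SampleSheet, ValidationError
from hetexpress.de import (
    ContrastSpec,
    NBExpressionModel,
    bh_adjust,
    compute_fpkm,
    estimate_dispersions,
    filter_low_expression,
    nb_wald_test,
    run_contrasts,
    size_factors,
)
from hetexpress.evaluation import wald_type1_error
from hetexpress.simulate import SimulationConfig, generate_counts

from conftest import make_counts, two_group_sheet


def nb_matrix(rng, mean, alpha, n_genes, n_samples):
    lam = rng.gamma(1 / alpha, scale=np.asarray(mean) * alpha, size=(n_genes, n_samples))
    return rng.poisson(lam).astype(np.int64)


class TestFPKM:
    def test_zero_count_gives_zero(self):
        cm = make_counts([[0, 10]], lengths=1000)
        fpkm = compute_fpkm(cm, {"s0": 1e6, "s1": 1e6})
        assert fpkm.iloc[0, 0] == 0.0

    def test_worked_example(self):
        cm = make_counts([[10]], lengths=1000)
        fpkm = compute_fpkm(cm, {"s0": 1_000_000})
        assert fpkm.iloc[0, 0] == pytest.approx(10.0)

    def test_joint_scale_invariance(self):
        cm1 = make_counts([[10, 20], [5, 2]], lengths=[1000, 2000])
        cm2 = make_counts([[20, 40], [10, 4]], lengths=[1000, 2000])
        f1 = compute_fpkm(cm1, {"s0": 1e6, "s1": 2e6})
        f2 = compute_fpkm(cm2, {"s0": 2e6, "s1": 4e6})
        assert np.allclose(f1.to_numpy(), f2.to_numpy())

    def test_zero_library_size_rejected(self):
        cm = make_counts([[1]])
        with pytest.raises(ValidationError, match="library size"):
            compute_fpkm(cm, {"s0": 0})


class TestFilter:
    def test_boundary_semantics(self):
        # gene means: 0.99 (removed), 1.00 (retained: only sub-threshold removed)
        fpkm = pd.DataFrame({"s0": [0.99, 1.0], "s1": [0.99, 1.0]}, index=["a", "b"])
        assert filter_low_expression(fpkm, 1.0) == ["b"]

    def test_zero_threshold_retains_all(self):
        fpkm = pd.DataFrame({"s0": [0.0, 5.0]}, index=["a", "b"])
        assert filter_low_expression(fpkm, 0.0) == ["a", "b"]


class TestBH:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_executed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @given(
        ps=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_and_permutation_equivariant(self, ps, seed):
        adj = bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        perm = np.random.default_rng(seed).permutation(len(ps))
        adj_perm = bh_adjust(np.asarray(ps)[perm])
        assert np.allclose(adj_perm, adj[perm])


class TestDispersion:
    def test_constant_counts_hit_floor(self):
        mat = np.full((3, 12), 50, dtype=np.int64)
        cm = make_counts(mat, sample_ids=list(two_group_sheet().groups))
        est = estimate_dispersions(cm, two_group_sheet(), moderation="none")
        assert np.allclose(est.to_numpy(), 1e-8)

    def test_nb_simulation_recovers_alpha(self, rng):
        """At n=50 per group the moment estimator lands near the true 0.1."""
        sheet = two_group_sheet(n_per_group=50)
        mat = nb_matrix(rng, 100.0, 0.1, 200, 100)
        cm = make_counts(mat, sample_ids=list(sheet.groups))
        est = estimate_dispersions(cm, sheet, moderation="none")
        assert 0.05 <= est.median() <= 0.2

    def test_poisson_counts_near_floor(self, rng):
        sheet = two_group_sheet(n_per_group=50)
        mat = rng.poisson(100.0, size=(300, 100)).astype(np.int64)
        cm = make_counts(mat, sample_ids=list(sheet.groups))
        est = estimate_dispersions(cm, sheet, moderation="none")
        # variance ~= mean: half the raw moment estimates fall at the floor
        assert est.median() < 0.01


class TestWald:
    def background(self, rng, n_bg=50, n_samples=12):
        """Identical-count background genes anchoring the size factors at 1."""
        return np.tile(rng.integers(50, 500, size=(n_bg, 1)), (1, n_samples))

    def test_identical_counts_give_null_result(self, rng):
        sheet = two_group_sheet()
        mat = self.background(rng)
        cm = make_counts(mat, sample_ids=list(sheet.groups))
        disp = pd.Series(0.05, index=cm.counts.index)
        res = nb_wald_test(cm, sheet, ContrastSpec("P2_vs_P1", "P2", "P1"), disp)
        assert np.allclose(res.table["log2fc"], 0.0)
        assert np.allclose(res.table["pvalue"], 1.0)

    def test_large_shift_is_extremely_significant(self, rng):
        """Normalized means 800 vs 100 at alpha=0.05, n=6 vs 6: the Wald z is
        ~15, hence p far below 1e-4."""
        sheet = two_group_sheet()
        mat = self.background(rng)
        gene = np.array([[800] * 6 + [100] * 6])
        cm = make_counts(np.vstack([mat, gene]), sample_ids=list(sheet.groups))
        disp = pd.Series(0.05, index=cm.counts.index)
        res = nb_wald_test(cm, sheet, ContrastSpec("P1_vs_P2", "P1", "P2"), disp)
        row = res.table.iloc[-1]
        assert row["log2fc"] == pytest.approx(np.log2(800.5 / 100.5), abs=0.01)
        assert row["pvalue"] < 1e-4

    def test_antisymmetric_under_side_swap(self, rng):
        sheet = two_group_sheet()
        mat = nb_matrix(rng, 100.0, 0.05, 40, 12)
        cm = make_counts(mat, sample_ids=list(sheet.groups))
        disp = estimate_dispersions(cm, sheet)
        fwd = nb_wald_test(cm, sheet, ContrastSpec("a", "P2", "P1"), disp).table
        rev = nb_wald_test(cm, sheet, ContrastSpec("b", "P1", "P2"), disp).table
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["pvalue"], rev["pvalue"])

    def test_type1_error_within_band(self):
        rate = wald_type1_error(n_genes=2000, seed=17)
        assert 0.03 <= rate <= 0.08

    def test_power_monotone_in_effect_size(self, rng):
        """Rejection probability among planted genes grows with |log2FC|.

        Only a tenth of the genes carry the effect so that normalization is
        anchored by the null majority rather than absorbing the shift."""
        sheet = two_group_sheet()
        rates = []
        for log2fc in (0.5, 1.0, 2.0):
            null = nb_matrix(rng, 100.0, 0.05, 450, 12)
            means = np.array([100.0] * 6 + [100.0 * 2**log2fc] * 6)
            planted = nb_matrix(rng, means, 0.05, 50, 12)
            cm = make_counts(np.vstack([null, planted]), sample_ids=list(sheet.groups))
            disp = estimate_dispersions(cm, sheet)
            res = nb_wald_test(cm, sheet, ContrastSpec("c", "P2", "P1"), disp)
            rates.append((res.table["pvalue"].iloc[450:] < 0.05).mean())
        assert rates[0] < rates[1] <= rates[2]

    def test_empty_side_rejected(self, rng):
        sheet = two_group_sheet()
        cm = make_counts(self.background(rng), sample_ids=list(sheet.groups))
        disp = pd.Series(0.05, index=cm.counts.index)
        with pytest.raises(ValidationError, match="F1A"):
            nb_wald_test(cm, sheet, ContrastSpec("x", "F1A", "P1"), disp)


class TestRunContrasts:
    def test_planted_genes_rank_first(self):
        """Two strongly differential genes among 100 conserved ones carry the
        smallest adjusted p-values in the parental contrast."""
        cfg = SimulationConfig(
            seed=21,
            genes_per_mode={"conserved": 100, "additive": 2},
            parent_log2_diff=3.0,
        )
        counts, samples, truth = generate_counts(cfg)
        results = run_contrasts(counts, samples)
        padj = results["P2_vs_P1"].table["padj"]
        planted = set(truth.index[truth["mode"] == "additive"])
        assert set(padj.nsmallest(2).index) == planted

    def test_null_contrast_of_group_with_itself(self):
        cfg = SimulationConfig(seed=22, genes_per_mode={"conserved": 200})
        counts, samples, _ = generate_counts(cfg)
        results = run_contrasts(counts, samples, [ContrastSpec("self", "P1", "P1")])
        table = results["self"].table
        assert np.allclose(table["log2fc"], 0.0)
        assert (table["padj"] >= 0.05).all()

    def test_empty_matrix_warns_and_returns_empty(self, caplog):
        cm = make_counts(np.empty((0, 4), dtype=np.int64),
                         sample_ids=["P1_0", "P1_1", "P2_0", "P2_1"])
        sheet = SampleSheet({"P1_0": "P1", "P1_1": "P1", "P2_0": "P2", "P2_1": "P2"})
        with caplog.at_level("WARNING"):
            results = run_contrasts(cm, sheet, [ContrastSpec("p", "P2", "P1")])
        assert results["p"].table.empty
        assert "no genes" in caplog.text

    def test_midparent_contrast_separates_additive_from_over(self):
        """Additive genes sit at the mid-parent (mid contrast quiet); the
        over-dominant genes sit far above it (mid contrast loud)."""
        cfg = SimulationConfig(
            seed=23, genes_per_mode={"conserved": 200, "additive": 30, "over": 30}
        )
        counts, samples, truth = generate_counts(cfg)
        results = run_contrasts(counts, samples)
        mid = results["F1A_vs_MID"].table
        additive = truth.index[truth["mode"] == "additive"]
        over = truth.index[truth["mode"] == "over"]
        assert (mid.loc[additive, "padj"] < 0.05).mean() < 0.2
        assert (mid.loc[over, "padj"] < 0.05).mean() > 0.9


class TestModelFacade:
    def test_fit_filters_and_summarizes(self):
        cfg = SimulationConfig(seed=24, genes_per_mode={"conserved": 150, "over": 10})
        counts, samples, _ = generate_counts(cfg)
        res = NBExpressionModel(counts, samples).fit()
        assert set(res.contrasts) == {
            "P2_vs_P1", "F1A_vs_P1", "F1A_vs_P2", "F1B_vs_P1", "F1B_vs_P2",
            "F1A_vs_MID", "F1B_vs_MID",
        }
        assert res.n_significant()["F1A_vs_P1"] >= 5
        assert "retained" in res.summary()


def test_size_factors_resist_composition_bias(rng):
    """A block of one-directional DE genes shifts column totals but must not
    shift the median-of-ratios factors of the unaffected samples."""
    n = 200
    base = rng.integers(50, 500, size=(n, 1))
    mat = np.tile(base, (1, 8))
    mat[:20, 4:] *= 16  # 10% of genes strongly up in the second half
    cm = make_counts(mat, sample_ids=[f"s{i}" for i in range(8)])
    mor = size_factors(cm, "median-of-ratios")
    assert np.allclose(mor, mor.iloc[0])  # unaffected majority dominates
    colsum = size_factors(cm, "column-ratio")
    assert colsum.iloc[4] / colsum.iloc[0] > 1.2  # totals are biased
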