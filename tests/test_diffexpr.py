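"""DE engine contracts: filtering, normalization, dispersion, the NB Wald
test (against a Poisson GLM oracle), BH adjustment (against brute force),
and the deregulation-call conventions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aneumir import (
    DesignSpec,
    ExpressionMatrix,
    Karyotype,
    SimulationConfig,
    adjust_bh,
    classify_deregulated,
    de_analysis,
    estimate_dispersions,
    filter_low_expression,
    nb_wald,
    simulate_annotation,
    simulate_counts,
    size_factors,
    summarize_deregulation,
)
from aneumir.simulate import planted_effects

from conftest import make_de_table


def _matrix(counts: np.ndarray, n_parental: int) -> ExpressionMatrix:
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.shape[1]
    conds = ["parental"] * n_parental + ["aneuploid"] * (n - n_parental)
    samples = pd.DataFrame(
        {
            "cell_line": conds,
            "condition": conds,
            "replicate": [f"r{i}" for i in range(n)],
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
    )
    cdf = pd.DataFrame(
        counts, index=[f"f{i}" for i in range(counts.shape[0])], columns=samples.index
    )
    return ExpressionMatrix(cdf, samples)


class TestFilter:
    def test_mean_count_filter_boundaries(self):
        counts = np.array(
            [
                [0, 0, 0, 0, 0, 0],       # removed: all zero
                [12, 9, 10, 11, 10, 8],   # mean 10.0 -> retained (inclusive)
                [9, 9, 9, 9, 9, 9],       # mean 9 -> removed
                [100, 100, 100, 100, 100, 100],
            ]
        )
        mat = _matrix(counts, 3)
        kept = filter_low_expression(mat, min_mean=10)
        assert list(kept.counts.index) == ["f1", "f3"]

    def test_all_removed_warns_and_returns_empty(self):
        mat = _matrix(np.ones((3, 4), dtype=int), 2)
        with pytest.warns(UserWarning):
            kept = filter_low_expression(mat, min_mean=10)
        assert kept.counts.empty


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame(np.tile([[10], [50], [7]], (1, 4)))
        np.testing.assert_allclose(size_factors(counts), 1.0)

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(50, size=(100, 3))
        counts = pd.DataFrame(np.column_stack([base[:, 0], 2 * base[:, 0], base[:, 2]]))
        sf = size_factors(counts)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_hand_computed_median_of_ratios(self):
        counts = pd.DataFrame([[10, 20, 10], [100, 200, 100], [4, 8, 4]])
        sf = size_factors(counts).to_numpy()
        np.testing.assert_allclose(sf / sf[0], [1.0, 2.0, 1.0])

    def test_feature_permutation_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(30, size=(50, 4)))
        perm = rng.permutation(50)
        np.testing.assert_allclose(
            size_factors(counts).to_numpy(), size_factors(counts.iloc[perm]).to_numpy()
        )

    def test_no_universally_expressed_feature_errors(self):
        counts = pd.DataFrame([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="nonzero"):
            size_factors(counts)


class TestDispersions:
    @staticmethod
    def _sim(phi: float, n_features: int, seed: int, mean: float = 100.0):
        rng = np.random.default_rng(seed)
        if phi == 0:
            y = rng.poisson(mean, size=(n_features, 6))
        else:
            r = 1 / phi
            y = rng.negative_binomial(r, r / (r + mean), size=(n_features, 6))
        counts = pd.DataFrame(y)
        sf = pd.Series(1.0, index=counts.columns)
        cond = np.array(["parental"] * 3 + ["aneuploid"] * 3)
        return estimate_dispersions(counts, sf, cond)

    def test_poisson_data_yields_near_zero_dispersion(self):
        phi = self._sim(0.0, 5000, 0)
        assert phi.median() <= 0.01

    def test_nb_data_recovers_dispersion_scale(self):
        phi = self._sim(0.1, 5000, 1)
        assert 0.05 <= phi.median() <= 0.2

    def test_underdispersed_feature_floored(self):
        counts = pd.DataFrame([[100, 100, 101, 100, 100, 101]] * 2 + [[50, 60, 55, 52, 58, 61]] * 20)
        sf = pd.Series(1.0, index=counts.columns)
        cond = np.array(["parental"] * 3 + ["aneuploid"] * 3)
        phi = estimate_dispersions(counts, sf, cond)
        # var << mean: raw estimate hits the floor; trend cannot raise a
        # floored feature above a tiny value
        assert phi.iloc[0] < 1e-3

    def test_single_replicate_errors(self):
        counts = pd.DataFrame([[10, 12, 11]])
        sf = pd.Series(1.0, index=counts.columns)
        with pytest.raises(ValueError, match="replicate"):
            estimate_dispersions(counts, sf, np.array(["parental", "aneuploid", "aneuploid"]))


class TestNbWald:
    def test_null_pvalues_uniform(self):
        """Null comparison (same generating means): Wald p-values should be
        uniform (KS not rejected at alpha=0.01)."""
        cfg = SimulationConfig(n_mrna=5000, n_mirna=10, planted_fraction=0.0, rng_seed=42)
        ann = simulate_annotation(cfg)
        mat = simulate_counts(ann, Karyotype.diploid("ctrl"), cfg)
        tbl = de_analysis(mat.subset_type(ann, "mRNA"), paired=True)
        ks = stats.kstest(tbl["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_poisson_limit_matches_poisson_glm(self):
        """In the phi -> 0 limit the NB Wald statistic equals a Poisson GLM
        fit (statsmodels) on the same data within 1e-3."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n_feat = 60
        y = rng.poisson(
            np.outer(rng.uniform(20, 200, n_feat), np.r_[np.ones(3), 1.3 * np.ones(3)])
        )
        mat = _matrix(y, 3)
        sf = pd.Series(1.0, index=mat.counts.columns)
        phi = pd.Series(1e-12, index=mat.counts.index)
        design = DesignSpec.from_samples(mat.samples, paired=False)
        tbl = nb_wald(mat.counts, sf, phi, design)
        X, _ = design.matrix()
        for i in range(n_feat):
            res = sm.GLM(y[i], X, family=sm.families.Poisson()).fit()
            z_mine = tbl["log2fc"].iloc[i] / tbl["se"].iloc[i]
            z_sm = res.params[1] / res.bse[1]
            assert z_mine == pytest.approx(z_sm, abs=1e-3)
            assert tbl["log2fc"].iloc[i] * np.log(2) == pytest.approx(res.params[1], abs=1e-3)

    def test_recovers_planted_log2fc(self):
        """Planted log2FC=1 at phi=0.05, 3v3, mean ~100: the median estimate
        is within 0.1 of the truth."""
        cfg = SimulationConfig(
            n_mrna=3000, n_mirna=10, planted_fraction=0.1, planted_log2fc=1.0,
            n_causal_pairs=0, baseline_mean=100, baseline_log_sd=0.25, rng_seed=5,
        )
        ann = simulate_annotation(cfg)
        mat = simulate_counts(ann, Karyotype.diploid("ctrl"), cfg)
        tbl = de_analysis(mat.subset_type(ann, "mRNA"), paired=True)
        truth = planted_effects(ann, cfg)
        up = truth.loc[tbl["feature_id"]].to_numpy() > 0
        assert np.median(tbl.loc[up, "log2fc"]) == pytest.approx(1.0, abs=0.1)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Independent step-up oracle: padj_i = min over j with p_j >= p_i of
    min(1, m * p_j / rank_j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    padj_sorted = np.minimum(1.0, m * ranked / np.arange(1, m + 1))
    # enforce step-up monotonicity from the largest p downwards
    for i in range(m - 2, -1, -1):
        padj_sorted[i] = min(padj_sorted[i], padj_sorted[i + 1])
    out = np.empty(m)
    out[order] = padj_sorted
    return out


class TestBH:
    def test_single_pvalue(self):
        np.testing.assert_allclose(adjust_bh([0.04]), [0.04])

    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_brute_force_on_grids(self):
        """Against the independent step-up oracle on 0.01-grid tuples of
        length <= 6 (seeded random sample plus boundary cases)."""
        rng = np.random.default_rng(12)
        grids = [np.array([0.0]), np.array([1.0]), np.array([0.05] * 6)]
        for _ in range(500):
            n = rng.integers(1, 7)
            grids.append(rng.integers(0, 101, size=n) / 100.0)
        for p in grids:
            np.testing.assert_allclose(adjust_bh(p), brute_force_bh(p), atol=1e-12)

    def test_nan_excluded_from_denominator(self):
        p = np.array([0.01, np.nan, 0.02])
        padj = adjust_bh(p)
        assert np.isnan(padj[1])
        np.testing.assert_allclose(padj[[0, 2]], brute_force_bh(np.array([0.01, 0.02])))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    def test_bounded_and_monotone(self):
        rng = np.random.default_rng(7)
        p = rng.random(200)
        padj = adjust_bh(p)
        assert ((padj >= 0) & (padj <= 1)).all()
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-12).all()


class TestCalls:
    @pytest.mark.parametrize(
        "log2fc,padj,expected",
        [
            (0.7, 0.01, "up"),
            (0.59, 0.001, "ns"),
            (-0.8, 0.05, "ns"),   # strict alpha boundary
            (0.6, 0.049, "up"),   # inclusive fold-change boundary
            (-0.6, 0.049, "down"),
        ],
    )
    def test_call_thresholds(self, log2fc, padj, expected):
        tbl = classify_deregulated(make_de_table([log2fc], padj=[padj]))
        assert tbl["call"].iloc[0] == expected

    @pytest.mark.parametrize(
        "n_dereg,n_tested,expected",
        [(74, 249, 29.7), (0, 100, 0.0), (23, 231, 10.0)],
    )
    def test_summary_percentages(self, n_dereg, n_tested, expected):
        calls = ["up"] * n_dereg + ["ns"] * (n_tested - n_dereg)
        tbl = make_de_table(np.zeros(n_tested), call=calls)
        s = summarize_deregulation(tbl)
        assert s == {"n_tested": n_tested, "n_deregulated": n_dereg, "percent": expected}

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            summarize_deregulation(make_de_table([], call=[]))


class TestDesign:
    def test_requires_two_samples_per_condition(self):
        with pytest.raises(ValueError, match="2 samples"):
            DesignSpec(condition=("parental", "aneuploid", "aneuploid"))

    def test_batch_confounded_with_condition_rejected(self):
        spec = DesignSpec(
            condition=("parental", "parental", "aneuploid", "aneuploid"),
            batch=("a", "a", "b", "b"),
        )
        with pytest.raises(ValueError, match="rank"):
            spec.matrix()
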