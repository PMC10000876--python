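import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from odontomorph.dataio import DomainError
from odontomorph.morphospace import (
    OutlinePipelineConfig,
    extreme_outlines,
    outline_pipeline,
    pca,
    rank_transform,
    retain_axes_95,
    wilks_manova,
    wilks_to_f,
)
from odontomorph.simulate import OutlineModelParams, simulate_outline_cohorts


def hotelling_lambda(X: np.ndarray, groups: np.ndarray) -> float:
    """Independent oracle: Lambda = 1 / (1 + T2 / (N - 2)) for two groups."""
    uniq = np.unique(groups)
    a, b = X[groups == uniq[0]], X[groups == uniq[1]]
    na, nb = len(a), len(b)
    diff = a.mean(axis=0) - b.mean(axis=0)
    Sp = ((na - 1) * np.cov(a.T) + (nb - 1) * np.cov(b.T)) / (na + nb - 2)
    Sp = np.atleast_2d(Sp)
    t2 = (na * nb) / (na + nb) * diff @ np.linalg.solve(Sp, diff)
    return float(1.0 / (1.0 + t2 / (na + nb - 2)))


class TestPCA:
    def test_collinear_data_single_component(self):
        t = np.linspace(0, 1, 10)
        X = np.column_stack([t, 2 * t])
        result = pca(X)
        assert result.explained_fraction[0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_eigendecomposition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 6))
        result = pca(X)
        cov = np.cov(X.T, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(
            result.explained_fraction, evals[:6] / evals.sum(), atol=1e-9)
        centered = X - X.mean(axis=0)
        for k in range(6):
            expected = centered @ evecs[:, k]
            got = result.scores[:, k]
            err = min(np.abs(got - expected).max(), np.abs(got + expected).max())
            assert err < 1e-9

    def test_duplicated_specimens_share_scores(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 4))
        X = np.vstack([X, X[0]])
        result = pca(X)
        np.testing.assert_allclose(result.scores[0], result.scores[-1], atol=1e-9)

    def test_reconstruction_and_diagonal_score_covariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 5))
        result = pca(X)
        recon = result.scores @ result.loadings.T
        np.testing.assert_allclose(recon, X - X.mean(axis=0), atol=1e-9)
        cov = np.cov(result.scores.T, ddof=1)
        np.testing.assert_allclose(cov - np.diag(np.diag(cov)), 0.0, atol=1e-9)

    def test_constant_matrix_rejected(self):
        with pytest.raises(DomainError):
            pca(np.ones((5, 3)))


class TestAxisRetention:
    @pytest.mark.parametrize("fractions,expected", [
        ([0.96, 0.04], 1),
        ([0.5, 0.3, 0.1, 0.06, 0.04], 4),
        ([0.05] * 20, 19),
    ])
    def test_examples(self, fractions, expected):
        assert retain_axes_95(fractions) == expected

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=20))
    @settings(max_examples=50, derandomize=True)
    def test_threshold_property(self, raw):
        frac = np.sort(np.asarray(raw))[::-1]
        frac = frac / frac.sum()
        k = retain_axes_95(frac)
        assert np.cumsum(frac)[k - 1] >= 0.95 - 1e-9
        if k > 1:
            assert np.cumsum(frac)[k - 2] < 0.95


class TestRankTransform:
    def test_simple_column(self):
        np.testing.assert_array_equal(
            rank_transform(np.array([3.2, 1.1, 2.5])).ravel(), [3, 1, 2])

    def test_midranks_for_ties(self):
        np.testing.assert_array_equal(
            rank_transform(np.array([2.0, 2.0, 5.0])).ravel(), [1.5, 1.5, 3])

    def test_manova_invariant_to_monotone_distortion(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(24, 3))
        groups = np.array(["a"] * 12 + ["b"] * 12)
        r1 = wilks_manova(rank_transform(X), groups)
        r2 = wilks_manova(rank_transform(np.exp(X)), groups)
        assert r1.wilks_lambda == pytest.approx(r2.wilks_lambda, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)


class TestWilksManova:
    def test_zero_between_group_scatter(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 2))
        X2 = np.vstack([X, X])  # identical group distributions
        groups = np.array(["a"] * 10 + ["b"] * 10)
        res = wilks_manova(X2, groups)
        assert res.wilks_lambda == pytest.approx(1.0, abs=1e-12)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_hotelling_identity(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 3))
        groups = np.array(["a"] * 5 + ["b"] * 7)
        res = wilks_manova(X, groups)
        assert res.wilks_lambda == pytest.approx(hotelling_lambda(X, groups), abs=1e-9)
        assert res.df1 == 3 and res.df2 == 12 - 3 - 1

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.multivariate.manova")
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 4))
        X[15:] += 0.8
        groups = np.array(["a"] * 15 + ["b"] * 15)
        res = wilks_manova(X, groups)
        mv = statsmodels.MANOVA(X, np.column_stack(
            [np.ones(30), (groups == "b").astype(float)]))
        table = mv.mv_test().results["x1"]["stat"]
        assert res.wilks_lambda == pytest.approx(
            float(table.loc["Wilks' lambda", "Value"]), abs=1e-9)
        assert res.p_value == pytest.approx(
            float(table.loc["Wilks' lambda", "Pr > F"]), abs=1e-9)

    def test_invariance_under_linear_transform(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(16, 3))
        groups = np.array(["a"] * 8 + ["b"] * 8)
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        res1 = wilks_manova(X, groups)
        res2 = wilks_manova(X @ A, groups)
        assert res1.wilks_lambda == pytest.approx(res2.wilks_lambda, abs=1e-9)

    def test_too_many_variables_rejected(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(6, 5))
        groups = np.array(["a"] * 3 + ["b"] * 3)
        with pytest.raises(DomainError):
            wilks_manova(X, groups)

    def test_exact_f_transform_values(self):
        # the exact transform applied to printed three-decimal Wilks values
        assert wilks_to_f(0.340, 11, 42) == pytest.approx(7.41, abs=0.05)
        assert wilks_to_f(0.557, 8, 45) == pytest.approx(4.47, abs=0.05)


class TestPipeline:
    def test_injected_shift_detected(self):
        params = OutlineModelParams(delta_theta_c1=0.3)
        outlines = simulate_outline_cohorts(params, 30, 30, seed=42)
        result = outline_pipeline(outlines)
        assert result.manova.p_value < 0.01
        # the most discriminant axis separates the cohorts strongly
        scores = result.pca.scores[:, result.extreme_axis]
        groups = np.asarray(result.matrix.groups)
        a, b = scores[groups == "WT"], scores[groups == "mutant"]
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        assert abs(a.mean() - b.mean()) / pooled > 1

    def test_identical_cohorts_give_lambda_one(self):
        params = OutlineModelParams(noise_sd=0.01)
        base = simulate_outline_cohorts(params, 10, 0, seed=1)
        from odontomorph.dataio import ClosedOutline

        duplicated = []
        for i, o in enumerate(base):
            duplicated.append(ClosedOutline(o.points, label=f"a{i}", cohort="WT"))
            duplicated.append(ClosedOutline(o.points, label=f"b{i}", cohort="mutant"))
        result = outline_pipeline(duplicated)
        assert result.manova.wilks_lambda == pytest.approx(1.0, abs=1e-9)

    def test_extremes_differ_most_near_injected_cusp(self):
        params = OutlineModelParams(delta_theta_c1=0.4, noise_sd=0.005)
        outlines = simulate_outline_cohorts(params, 25, 25, seed=3)
        result = outline_pipeline(outlines)
        neg, pos = result.extremes
        dist = np.linalg.norm(neg.points - pos.points, axis=1)
        angles = np.arctan2(*reversed([neg.points[:, 0], neg.points[:, 1]]))
        peak_angle = angles[np.argmax(dist)]
        cusp1 = params.cusps[0].theta  # the shifted cusp sits near angle 0
        wrapped = np.angle(np.exp(1j * (peak_angle - cusp1)))
        assert abs(wrapped) < 0.6

    def test_invalid_threshold_rejected(self):
        with pytest.raises(DomainError):
            OutlinePipelineConfig(variance_threshold=1.2)


class TestExtremeOutlines:
    def test_zero_multiplier_returns_mean_shape(self):
        outlines = simulate_outline_cohorts(OutlineModelParams(seed=6), 8, 8)
        result = outline_pipeline(outlines)
        neg, pos = extreme_outlines(result.pca, 0, result.mean_coeffs, multiplier=0.0)
        np.testing.assert_allclose(neg.points, pos.points, atol=1e-12)

    def test_axis_sign_symmetry(self):
        outlines = simulate_outline_cohorts(OutlineModelParams(seed=8), 8, 8)
        result = outline_pipeline(outlines)
        neg, pos = extreme_outlines(result.pca, 1, result.mean_coeffs, multiplier=1.0)
        from dataclasses import replace
        flipped = replace(result.pca,
                          loadings=result.pca.loadings * -1,
                          scores=result.pca.scores * -1)
        neg2, pos2 = extreme_outlines(flipped, 1, result.mean_coeffs, multiplier=1.0)
        np.testing.assert_allclose(neg.points, pos2.points, atol=1e-9)
        np.testing.assert_allclose(pos.points, neg2.points, atol=1e-9)
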