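"""Weighted distribution metrics, correlations and the PCA telomere score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from telogel.metrics import (
    METRIC_NAMES,
    TLMetricSet,
    compute_metric_set,
    metric_correlations,
    metrics_table,
    pca_scores,
    standards_cv,
    weighted_mean,
    weighted_moments,
    weighted_quantile,
)
from telogel.simulate import TrueTLSpec
from tests.conftest import make_dist


def replication_oracle(positions, weights, stat):
    """Expand each point by its integer weight, then apply the plain statistic."""
    expanded = np.repeat(positions, weights.astype(int))
    return stat(expanded)


class TestWeightedMean:
    def test_equal_weights_midpoint(self):
        assert weighted_mean(make_dist([5, 10], [1, 1])) == pytest.approx(7.5)

    def test_unequal_weights(self):
        assert weighted_mean(make_dist([5, 10], [3, 1])) == pytest.approx(6.25)

    def test_matches_replication_oracle(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(2, 39, 200)
        w = rng.integers(1, 50, 200).astype(float)
        est = weighted_mean(make_dist(pos, w))
        assert est == pytest.approx(replication_oracle(pos, w, np.mean), abs=1e-12)

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            make_dist([5.0], [0.0])


class TestWeightedMoments:
    def test_symmetric_two_point_mass(self):
        skew, kurt = weighted_moments(make_dist([4, 6], [1, 1]))
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert kurt == pytest.approx(1.0, abs=1e-12)

    def test_single_support_point_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            weighted_moments(make_dist([8, 8], [1, 1]))

    def test_gaussian_grid_recovers_normal_shape(self):
        x = np.linspace(2, 38, 4001)
        w = stats.norm.pdf(x, loc=20, scale=3)
        skew, kurt = weighted_moments(make_dist(x, w))
        assert abs(skew) < 0.05
        assert abs(kurt - 3.0) < 0.05

    def test_matches_replication_oracle(self):
        rng = np.random.default_rng(4)
        pos = rng.uniform(2, 39, 150)
        w = rng.integers(1, 30, 150).astype(float)
        skew, kurt = weighted_moments(make_dist(pos, w))
        assert skew == pytest.approx(
            replication_oracle(pos, w, lambda v: stats.skew(v, bias=True)), abs=1e-10
        )
        assert kurt == pytest.approx(
            replication_oracle(pos, w, lambda v: stats.kurtosis(v, fisher=False, bias=True)),
            abs=1e-10,
        )


class TestWeightedQuantile:
    def test_point_mass(self):
        d = make_dist([8, 8.0000001], [1, 1e-12])
        for q in np.arange(0.1, 0.95, 0.1):
            assert weighted_quantile(d, q) == pytest.approx(8.0, abs=1e-6)

    def test_two_point_median_interpolates(self):
        assert weighted_quantile(make_dist([5, 10], [1, 1]), 0.5) == pytest.approx(7.5)

    def test_within_one_grid_step_of_replication_oracle(self):
        rng = np.random.default_rng(9)
        pos = np.sort(rng.uniform(2, 39, 100))
        w = rng.integers(1, 40, 100).astype(float)
        step = np.diff(pos).max()
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            mine = weighted_quantile(make_dist(pos, w), q)
            oracle = replication_oracle(pos, w, lambda v: np.quantile(v, q))
            assert abs(mine - oracle) <= step

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            weighted_quantile(make_dist([5, 10], [1, 1]), 1.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_in_q(self, seed):
        rng = np.random.default_rng(seed)
        d = make_dist(rng.uniform(2, 39, 30), rng.random(30) + 1e-3)
        qs = np.linspace(0.05, 0.95, 19)
        vals = weighted_quantile(d, qs)
        assert np.all(np.diff(vals) >= -1e-12)


class TestComputeMetricSet:
    def test_symmetric_distribution_mean_equals_median(self):
        x = np.linspace(10, 20, 201)
        w = stats.norm.pdf(x, 15, 1.5)
        m = compute_metric_set(make_dist(x, w))
        assert m.mean_kb == pytest.approx(m.p50, abs=1e-6)

    def test_deciles_monotone(self):
        rng = np.random.default_rng(2)
        m = compute_metric_set(make_dist(rng.uniform(2, 39, 80), rng.random(80) + 0.01))
        assert np.all(np.diff(m.deciles()) >= 0)

    def test_noiseless_mixture_recovers_analytic_truth(self):
        """Metrics of a dense grid weighted by the mixture density match the
        closed-form mixture metrics."""
        spec = TrueTLSpec("a", [(0.6, 9.0, 2.0), (0.4, 13.0, 2.5)])
        x = np.linspace(2.0, 39.0, 6000)
        m = compute_metric_set(make_dist(x, spec.pdf(x)))
        truth = spec.true_metric_set()
        assert m.mean_kb == pytest.approx(truth.mean_kb, rel=0.02)
        for q in range(10, 100, 10):
            assert getattr(m, f"p{q}") == pytest.approx(getattr(truth, f"p{q}"), abs=0.2)
        assert m.skew == pytest.approx(truth.skew, abs=0.05)
        assert m.kurtosis == pytest.approx(truth.kurtosis, abs=0.1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 100), st.floats(-3, 3))
    def test_scale_and_shift_equivariance(self, seed, scale_w, shift_kb):
        """Rescaling weights changes nothing; shifting positions shifts the
        location metrics and leaves the shape metrics alone."""
        rng = np.random.default_rng(seed)
        pos = rng.uniform(5, 30, 40)
        w = rng.random(40) + 0.01
        base = compute_metric_set(make_dist(pos, w, window=(0.0, 100.0)))
        scaled = compute_metric_set(make_dist(pos, w * scale_w, window=(0.0, 100.0)))
        for name in METRIC_NAMES:
            assert getattr(scaled, name) == pytest.approx(getattr(base, name), abs=1e-8)
        shifted = compute_metric_set(make_dist(pos + shift_kb, w, window=(0.0, 100.0)))
        assert shifted.mean_kb == pytest.approx(base.mean_kb + shift_kb, abs=1e-8)
        for q in range(10, 100, 10):
            assert getattr(shifted, f"p{q}") == pytest.approx(
                getattr(base, f"p{q}") + shift_kb, abs=1e-8
            )
        assert shifted.skew == pytest.approx(base.skew, abs=1e-7)
        assert shifted.kurtosis == pytest.approx(base.kurtosis, abs=1e-6)


def random_metric_table(n, seed=0):
    rng = np.random.default_rng(seed)
    latent = rng.normal(size=n)
    rows = []
    for i in range(n):
        x = np.linspace(2, 39, 400)
        w = stats.norm.pdf(x, 12 + 2 * latent[i], 2.0 + 0.2 * rng.random())
        rows.append(compute_metric_set(make_dist(x, w, individual_id=f"i{i}")))
    return metrics_table(rows)


class TestMetricCorrelations:
    def test_duplicated_and_negated_columns(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            rng.normal(size=(20, 12)), columns=list(METRIC_NAMES)
        )
        table["p20"] = table["p10"]
        table["skew"] = -table["mean_kb"]
        r, p = metric_correlations(table)
        assert r.loc["p10", "p20"] == pytest.approx(1.0)
        assert r.loc["mean_kb", "skew"] == pytest.approx(-1.0)
        assert np.allclose(r.values, r.values.T, equal_nan=True)
        assert np.allclose(np.diag(r.values), 1.0)

    def test_matches_textbook_formula_oracle(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.normal(size=(20, 12)), columns=list(METRIC_NAMES))
        r, _ = metric_correlations(table)
        X = table.to_numpy()
        Xc = X - X.mean(axis=0)
        oracle = (Xc.T @ Xc) / np.outer(
            np.sqrt((Xc**2).sum(axis=0)), np.sqrt((Xc**2).sum(axis=0))
        )
        assert np.allclose(r.values, oracle, atol=1e-12)

    def test_constant_column_flagged(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(10, 12)), columns=list(METRIC_NAMES))
        table["kurtosis"] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            r, _ = metric_correlations(table)
        assert np.isnan(r.loc["kurtosis", "mean_kb"])

    def test_simulated_cohort_reproduces_expected_sign_structure(self):
        """Deciles correlate positively with the mean; skew negatively."""
        table = random_metric_table(40, seed=3)
        r, _ = metric_correlations(table)
        for q in range(10, 100, 10):
            assert r.loc["mean_kb", f"p{q}"] > 0.5
        assert r.loc["mean_kb", "skew"] < 0


class TestPCAScores:
    def test_rank_one_table_explained_fully(self):
        rng = np.random.default_rng(0)
        latent = rng.normal(size=30)
        table = pd.DataFrame(
            {name: (i + 1) * latent for i, name in enumerate(METRIC_NAMES)}
        )
        res = pca_scores(table)
        assert res.explained_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_known_two_by_two_covariance(self):
        """Two informative metrics with covariance [[2,1],[1,2]]: leading
        eigenvalue 3 explaining 3/4 of the variance."""
        rng = np.random.default_rng(42)
        z = rng.multivariate_normal([0, 0], [[2, 1], [1, 2]], size=20_000)
        table = pd.DataFrame(0.0, index=range(20_000), columns=list(METRIC_NAMES))
        table["mean_kb"] = z[:, 0]
        table["p50"] = z[:, 1]
        res = pca_scores(table)
        evals = res.explained_fraction * np.trace(np.cov(z, rowvar=False))
        assert evals[0] == pytest.approx(3.0, rel=0.03)
        assert res.explained_fraction[0] == pytest.approx(0.75, abs=0.01)

    def test_matches_eigendecomposition_oracle(self):
        table = random_metric_table(30, seed=7)
        res = pca_scores(table)
        X = table.to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(Xc, rowvar=False))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert np.allclose(
            res.explained_fraction, np.clip(evals, 0, None) / evals.sum(), atol=1e-10
        )
        for j in range(3):
            v = evecs[:, j] if np.dot(evecs[:, j], res.loadings[:, j]) >= 0 else -evecs[:, j]
            assert np.allclose(res.loadings[:, j], v, atol=1e-10)

    def test_sign_convention_high_pc1_is_long_telomeres(self):
        table = random_metric_table(40, seed=9)
        res = pca_scores(table)
        mean_idx = list(METRIC_NAMES).index("mean_kb")
        assert res.loadings[mean_idx, 0] >= 0
        # scores must increase with mean telomere length
        r = np.corrcoef(res.pc1_scores(), table["mean_kb"])[0, 1]
        assert r > 0.9

    def test_score_order_invariant_to_duplicating_individual(self):
        table = random_metric_table(25, seed=11)
        res = pca_scores(table)
        dup = pd.concat([table, table.iloc[[0]].rename(index={"i0": "i0_copy"})])
        res2 = pca_scores(dup, mode="covariance")
        a = res.pc1_scores().rank()
        b = res2.pc1_scores().loc[a.index].rank()
        assert (a.sort_index() == b.sort_index()).all()

    def test_correlation_mode(self):
        table = random_metric_table(30, seed=13)
        res = pca_scores(table, mode="correlation")
        assert res.mode == "correlation"
        assert res.explained_fraction.sum() == pytest.approx(1.0)

    def test_rejects_unknown_mode(self):
        with pytest.raises(ValueError):
            pca_scores(random_metric_table(15), mode="robust")


def test_standards_cv_reports_repeatability():
    table = metrics_table(
        [
            TLMetricSet("std1_gel1", 10.0, 0, 3, *np.linspace(8, 12, 9)),
            TLMetricSet("std1_gel2", 11.0, 0, 3, *np.linspace(8, 12, 9)),
            TLMetricSet("std2_gel1", 9.0, 0, 3, *np.linspace(8, 12, 9)),
        ]
    )
    cv = standards_cv(table, {"std1": ["std1_gel1", "std1_gel2"]})
    assert cv["std1"] == pytest.approx(np.std([10, 11], ddof=1) / 10.5)
    with pytest.raises(ValueError, match=">= 2"):
        standards_cv(table, {"std2": ["std2_gel1"]})
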