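"""EF summary PCA, confound residualization, Q², PLS selection, BCa bootstrap."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from msnkit import (
    CohortConfig,
    bootstrap_weights,
    ef_summary,
    generate_cognition,
    generate_cohort,
    pls1_fit,
    pls_cv_select,
    q_squared,
    residualize_confounds,
)
from msnkit.cognition import bca_interval


class TestEFSummary:
    def test_identical_columns_degenerate_pca(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=200)
        scores = ef_summary(np.column_stack([col, col, col]))
        z = (col - col.mean()) / col.std(ddof=1)
        # scores standardized; equal to the standardized column up to sign
        assert np.allclose(np.abs(np.corrcoef(scores, z)[0, 1]), 1.0)

    def test_compound_symmetric_eigenvalue(self):
        """Loadings sqrt(0.5) on one factor -> rho = 0.5 -> lambda1 = 1 + 2 rho = 2."""
        rng = np.random.default_rng(1)
        n = 5000
        g = rng.normal(size=n)
        lam = np.sqrt(0.5)
        ef = lam * g[:, None] + np.sqrt(1 - lam**2) * rng.normal(size=(n, 3))
        corr = np.corrcoef(ef, rowvar=False)
        lam1 = np.linalg.eigvalsh(corr)[-1]
        assert lam1 == pytest.approx(2.0, abs=0.1)
        scores = ef_summary(ef)
        assert scores.std(ddof=1) == pytest.approx(1.0)

    def test_independent_noise_columns_rejected(self):
        # iid columns: PC1 direction is arbitrary; the common-component rules fail
        rng = np.random.default_rng(0)
        ef = rng.normal(size=(2000, 3))
        with pytest.raises(ValueError):
            ef_summary(ef)

    def test_missing_values_rejected(self):
        ef = np.ones((10, 3)) + np.arange(30).reshape(10, 3)
        ef = ef.astype(float)
        ef[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            ef_summary(ef)


class TestResidualize:
    def test_perfect_confound_fit_zeroes_metric(self):
        rng = np.random.default_rng(2)
        n = 50
        age = rng.uniform(22, 36, n)
        sex = rng.choice(["F", "M"], n)
        metric = np.column_stack([2 * age, -0.5 * age + 3])
        resid = residualize_confounds(metric, age, sex)
        assert np.max(np.abs(resid)) < 1e-10

    def test_null_metric_unaffected_beyond_centering(self):
        rng = np.random.default_rng(3)
        n = 500
        age = rng.uniform(22, 36, n)
        sex = rng.choice(["F", "M"], n)
        metric = rng.normal(size=(n, 20))
        resid = residualize_confounds(metric, age, sex)
        assert np.all(np.abs(resid.mean(axis=0)) < 1e-10)
        r2 = 1 - resid.var(axis=0) / metric.var(axis=0)
        assert np.all(r2 < 0.05)

    def test_single_sex_cohort_rank_deficient(self):
        rng = np.random.default_rng(4)
        n = 30
        age = rng.uniform(22, 36, n)
        sex = np.array(["F"] * n)
        with pytest.raises(ValueError, match="rank"):
            residualize_confounds(rng.normal(size=(n, 5)), age, sex)


class TestQSquared:
    def test_perfect_prediction(self):
        y = np.array([2.0, -1.0, 0.5, 3.0])
        assert q_squared(y, y) == pytest.approx(1.0)

    def test_mean_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert q_squared(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_arithmetic_fixture_can_be_negative(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = np.array([1.0, 2.0, 3.0, 0.0])
        # PRESS = 16, TSS = 5
        assert q_squared(y, yhat) == pytest.approx(1 - 16 / 5)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            q_squared(np.ones(5), np.ones(5))

    def test_shift_invariance_of_mean_model(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=40)
        assert q_squared(y + 100.0, np.full(40, (y + 100.0).mean())) == pytest.approx(0.0)


class TestPLS1:
    def test_predictions_match_sklearn_reference(self):
        """Dual-route check of the NIPALS implementation for every component count."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 15))
        y = X[:, 0] * 2 - X[:, 3] + rng.normal(size=60)
        model = pls1_fit(X, y, 6)
        for c in range(1, 7):
            sk = PLSRegression(n_components=c, scale=True).fit(X, y)
            assert np.allclose(model.predict(X, c), sk.predict(X).ravel(), atol=1e-8)

    def test_component_count_truncated_at_rank(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        model = pls1_fit(X, y, 10)
        assert model.n_components <= 3


@pytest.fixture(scope="module")
def null_data():
    rng = np.random.default_rng(8)
    return rng.normal(size=(90, 30)), rng.normal(size=90)


class TestPLSSelect:
    def test_partition_bookkeeping_n18_k9(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(18, 6))
        y = rng.normal(size=18) + X[:, 0]
        res = pls_cv_select(X, y, c_max=2, n_instances=1, k=9, seed=0)
        assert sum(res.selection_counts.values()) == 1
        # with n=18 and k=9 every fold has exactly 2 subjects; Q² was computable,
        # so every subject was predicted exactly once
        assert np.isfinite(res.q2_curve).all()

    def test_counts_sum_to_instances_and_determinism(self, null_data):
        X, y = null_data
        res1 = pls_cv_select(X, y, c_max=4, n_instances=10, k=9, seed=3)
        res2 = pls_cv_select(X, y, c_max=4, n_instances=10, k=9, seed=3)
        assert sum(res1.selection_counts.values()) == 10
        assert res1.selection_counts == res2.selection_counts
        assert np.allclose(res1.q2_curve, res2.q2_curve)

    def test_null_outcome_selects_zero_components(self, null_data):
        X, y = null_data
        res = pls_cv_select(X, y, c_max=4, n_instances=10, k=9, seed=1)
        assert res.chosen_c == 0

    def test_signal_outcome_selects_components(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(120, 20))
        y = 3 * X[:, 2] - 2 * X[:, 7] + 0.3 * rng.normal(size=120)
        res = pls_cv_select(X, y, c_max=4, n_instances=10, k=9, seed=2)
        assert res.chosen_c >= 1
        assert res.q2_at_chosen > 0.5

    def test_subject_permutation_invariance_of_choice(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 10))
        y = 2 * X[:, 1] + 0.5 * rng.normal(size=60)
        perm = rng.permutation(60)
        res_a = pls_cv_select(X, y, c_max=3, n_instances=10, k=6, seed=4)
        res_b = pls_cv_select(X[perm], y[perm], c_max=3, n_instances=10, k=6, seed=4)
        assert res_a.chosen_c == res_b.chosen_c

    def test_stratified_variant_runs_and_selects_signal(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(80, 12))
        y = 2.5 * X[:, 0] + 0.4 * rng.normal(size=80)
        res = pls_cv_select(X, y, c_max=3, n_instances=8, k=8, seed=5, stratified=True)
        assert res.stratified
        assert res.chosen_c >= 1

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError, match="subjects"):
            pls_cv_select(rng.normal(size=(10, 4)), rng.normal(size=10), k=9)


class TestBootstrap:
    def test_driver_interval_excludes_zero_null_covers(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(150, 10))
        y = 3 * X[:, 0] + 0.5 * rng.normal(size=150)
        w = bootstrap_weights(X, y, chosen_c=1, n_boot=200, seed=0)
        driver = w.iloc[0]
        assert driver.ci_low > 0 or driver.ci_high < 0
        covered = [
            w.iloc[j].ci_low <= 0 <= w.iloc[j].ci_high for j in range(1, 10)
        ]
        assert np.mean(covered) >= 0.8

    def test_disabled_resampling_collapses_intervals(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(40, 5))
        y = X[:, 1] + 0.2 * rng.normal(size=40)
        w = bootstrap_weights(X, y, chosen_c=1, n_boot=20, seed=0, resample=False)
        assert np.allclose(w.ci_low, w.weight)
        assert np.allclose(w.ci_high, w.weight)

    def test_zero_components_rejected(self):
        rng = np.random.default_rng(16)
        with pytest.raises(ValueError, match="no model"):
            bootstrap_weights(rng.normal(size=(20, 4)), rng.normal(size=20), chosen_c=0)

    def test_bca_reduces_to_percentile_when_unbiased_symmetric(self):
        """With z0 = 0 and a = 0 the BCa interval is the percentile interval."""
        boot = np.linspace(-1, 1, 500)  # symmetric about 0, 0 itself excluded
        point = 0.0  # exactly half the replicates below -> z0 = 0
        jackknife = np.linspace(-0.5, 0.5, 11)  # symmetric -> a = 0
        lo, hi = bca_interval(boot, point, jackknife, alpha=0.05)
        assert lo == pytest.approx(np.percentile(boot, 2.5), abs=1e-6)
        assert hi == pytest.approx(np.percentile(boot, 97.5), abs=1e-6)
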