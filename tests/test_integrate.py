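"""Feature fusion, NIPALS PLS-DA, and the association tests."""

import itertools

import numpy as np
import pytest
from scipy import stats

from zfpdx.behavior import summarize_cohort
from zfpdx.integrate import (
    age_band_midpoint,
    build_feature_matrix,
    chisq_yates,
    logistic_fit,
    pls_da_fit,
    predict_outcome,
    variable_weights,
    vip_scores,
    wilcoxon_exact,
)
from zfpdx.lsc_flow import gate_sample


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def cohort_features(small_study):
    from zfpdx.atlas import default_atlas

    atlas = default_atlas()
    gates, behavior = {}, {}
    for sid, (control, test) in small_study.flow.items():
        gates[sid] = gate_sample(control, test)
    rng = np.random.default_rng(1)
    for sid, cohort in small_study.cohorts.items():
        behavior[sid] = summarize_cohort(cohort, atlas, n_boot=200,
                                         seed=int(rng.integers(2**31)))
    return small_study.clinical, gates, behavior


class TestFeatureMatrix:
    def test_unknown_remission_dropped(self, cohort_features):
        clinical, gates, behavior = cohort_features
        fm = build_feature_matrix(clinical, gates, behavior)
        assert len(fm.sample_ids) == 6  # one of seven patients has remission NA
        assert "LPZ10" not in fm.sample_ids
        assert set(fm.y) == {0.0, 1.0}

    def test_columns_standardized(self, cohort_features):
        clinical, gates, behavior = cohort_features
        fm = build_feature_matrix(clinical, gates, behavior)
        assert np.allclose(fm.X.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(fm.X.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_missing_behavior_errors_naming_orphan(self, cohort_features):
        clinical, gates, behavior = cohort_features
        behavior = {k: v for k, v in behavior.items() if k != "LPZ6"}
        with pytest.raises(ValueError, match="LPZ6"):
            build_feature_matrix(clinical, gates, behavior)

    def test_age_band_midpoint(self):
        assert age_band_midpoint("76-80") == 78.0
        assert age_band_midpoint("40-45") == 42.5
        with pytest.raises(ValueError):
            age_band_midpoint("unknown")


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


def _centered_orthonormal(n, p, rng):
    X = rng.normal(size=(n, p))
    X = X - X.mean(axis=0)
    Q, _ = np.linalg.qr(X)
    return Q[:, :p]


class TestPlsDa:
    def test_exact_representation_single_component(self, rng):
        X = _centered_orthonormal(12, 4, rng)
        y = X[:, 0].copy()
        y01 = (y > np.median(y)).astype(float)
        # construct X whose first column IS the centered response
        X[:, 0] = y01 - y01.mean()
        X[:, 0] /= np.linalg.norm(X[:, 0])
        # re-orthogonalize the rest against column 0
        for j in range(1, 4):
            for k in range(j):
                X[:, j] -= (X[:, j] @ X[:, k]) * X[:, k]
            X[:, j] /= np.linalg.norm(X[:, j])
        m = pls_da_fit(X, y01, n_components=1)
        w = np.abs(m.W[:, 0])
        assert w[0] == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(w[1:], 0.0, atol=1e-10)
        assert m.explained_y_variance[0] == pytest.approx(1.0)

    def test_scores_orthogonal(self, rng):
        X = rng.normal(size=(10, 6))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = (rng.random(10) < 0.5).astype(float)
        y[:2] = [0, 1]
        m = pls_da_fit(X, y, n_components=3)
        for i, j in itertools.combinations(range(3), 2):
            assert abs(m.T[:, i] @ m.T[:, j]) < 1e-8

    def test_explained_variance_nondecreasing_and_bounded(self, rng):
        X = rng.normal(size=(12, 5))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = (rng.random(12) < 0.5).astype(float)
        y[:2] = [0, 1]
        m = pls_da_fit(X, y, n_components=4)
        ev = m.explained_y_variance
        assert np.all(np.diff(ev) >= -1e-12)
        assert ev[-1] <= 1.0 + 1e-12

    def test_matches_sklearn_up_to_sign(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(8, 12))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0], dtype=float)
        m = pls_da_fit(X, y, n_components=2)
        sk = PLSRegression(n_components=2, scale=False).fit(X, y - y.mean())
        for k in range(2):
            s = np.sign(m.W[:, k] @ sk.x_weights_[:, k])
            assert np.allclose(m.W[:, k], s * sk.x_weights_[:, k], atol=1e-8)
            assert np.allclose(m.T[:, k], s * sk.x_scores_[:, k], atol=1e-8)

    def test_too_many_components_rejected(self, rng):
        X = rng.normal(size=(4, 8))
        y = np.array([0, 1, 0, 1], dtype=float)
        with pytest.raises(ValueError, match="rank"):
            pls_da_fit(X, y, n_components=5)

    def test_duplicate_columns_get_equal_weights(self, rng):
        x = rng.normal(size=10)
        x = (x - x.mean()) / x.std(ddof=1)
        noise = rng.normal(size=10)
        noise = (noise - noise.mean()) / noise.std(ddof=1)
        X = np.column_stack([x, x, noise])
        y = (x > 0).astype(float)
        m = pls_da_fit(X, y, n_components=1)
        assert abs(abs(m.W[0, 0]) - abs(m.W[1, 0])) < 1e-8


class TestVariableWeights:
    def test_informative_feature_ranked_first(self, rng):
        """A single feature with a 3-SD class effect tops |w1| in >=95%
        of replicates."""
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            y = np.tile([0.0, 1.0], 10)
            X = rng.normal(size=(20, 8))
            X[:, 3] += 3.0 * y
            X = (X - X.mean(0)) / X.std(0, ddof=1)
            m = pls_da_fit(X, y, n_components=2)
            hits += variable_weights(m)["feature"][0] == "x3"
        assert hits / n_rep >= 0.95

    def test_all_noise_vip_rarely_extreme(self, rng):
        """Null X: no feature's VIP exceeds 2 in more than 10% of
        replicates."""
        extreme = 0
        n_rep = 200
        for _ in range(n_rep):
            y = np.tile([0.0, 1.0], 10)
            X = rng.normal(size=(20, 8))
            X = (X - X.mean(0)) / X.std(0, ddof=1)
            m = pls_da_fit(X, y, n_components=2)
            extreme += vip_scores(m).max() > 2.0
        assert extreme / n_rep <= 0.10


class TestPredictOutcome:
    def test_separable_training_data_perfectly_classified(self, rng):
        y = np.tile([0.0, 1.0], 8)
        X = rng.normal(size=(16, 5)) * 0.3
        X[:, 0] += 4.0 * y
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        m = pls_da_fit(X, y, n_components=2)
        assert (predict_outcome(m, X) == y).all()

    def test_midpoint_tie_breaks_to_class_zero(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([0.0, 1.0])
        m = pls_da_fit(X, y, n_components=1)
        mid = np.array([[0.0]])
        assert predict_outcome(m, mid)[0] == 0

    def test_permuted_labels_accuracy_near_chance(self, rng):
        accs = []
        for _ in range(200):
            y = rng.permutation(np.tile([0.0, 1.0], 10))
            X = rng.normal(size=(20, 6))
            X = (X - X.mean(0)) / X.std(0, ddof=1)
            m = pls_da_fit(X, y, n_components=1)
            accs.append((predict_outcome(m, X) == y).mean())
        # resubstitution on pure noise is optimistic but centered well
        # below 1; the mean must sit in a mid band, not near 0 or 1
        assert 0.5 <= np.mean(accs) <= 0.85


# ---------------------------------------------------------------------------
# Association tests
# ---------------------------------------------------------------------------


class TestWilcoxonExact:
    def test_two_below_four_reproduces_reported_p(self):
        p = wilcoxon_exact([10.0, 11.0], [20.0, 25.0, 30.0, 40.0])
        assert p == pytest.approx(2 / 15)
        assert round(p, 4) == 0.1333

    def test_small_shift_enumeration(self):
        assert wilcoxon_exact([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_interleaved_groups_cap_at_one(self):
        assert wilcoxon_exact([1, 4], [2, 3]) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_exact([], [1, 2])

    def test_ties_warn_and_use_midranks(self):
        with pytest.warns(UserWarning, match="midranks"):
            p = wilcoxon_exact([1, 1], [1, 2])
        assert 0 < p <= 1

    def test_matches_scipy_exact_on_random_data(self, rng):
        for _ in range(50):
            na, nb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            a = rng.normal(size=na)
            b = rng.normal(size=nb) + rng.normal()
            p_ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="exact").pvalue
            assert wilcoxon_exact(a, b) == pytest.approx(p_ref, abs=1e-12)


class TestChisqYates:
    def test_dispersion_by_remission_table(self):
        r = chisq_yates([[0, 3], [2, 1]])
        assert r.statistic == pytest.approx(0.75)
        assert round(r.p, 4) == 0.3865

    def test_balanced_table_is_null(self):
        r = chisq_yates([[5, 5], [5, 5]])
        assert r.statistic == 0.0 and r.p == 1.0

    def test_continuity_floor(self):
        # |ad - bc| = 2 < n/2 = 4.5 -> statistic floored at 0
        r = chisq_yates([[2, 2], [2, 3]])
        assert r.statistic == 0.0

    def test_zero_marginal_flagged_undefined(self):
        r = chisq_yates([[0, 0], [3, 4]])
        assert r.undefined and np.isnan(r.statistic)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            chisq_yates([[0.5, 1], [2, 3]])


class TestLogisticFit:
    def test_no_signal_gives_flat_fit(self, rng):
        x = np.concatenate([-np.linspace(0.1, 2, 25), np.linspace(0.1, 2, 25)])
        y = np.tile([0.0, 1.0], 25)
        f = logistic_fit(x, y)
        assert abs(f.slope) < 0.5
        assert f.mcfadden_r2 < 0.05

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(10):
            x = rng.normal(size=50)
            y = (rng.random(50) < 1 / (1 + np.exp(-(0.3 + 1.1 * x)))).astype(float)
            if len(set(y)) < 2:
                continue
            f = logistic_fit(x, y)
            ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            assert np.allclose([f.intercept, f.slope], ref.params, atol=1e-6)
            assert f.mcfadden_r2 == pytest.approx(ref.prsquared, abs=1e-6)

    def test_perfect_separation_flagged(self):
        x = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="separation"):
            f = logistic_fit(x, y)
        assert f.separation

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            logistic_fit([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
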