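"""CSP, log-variance features, paired LOO evaluation, stratification."""

import numpy as np
import pytest
from scipy import linalg

from mises.decoding import (
    CSP,
    CSPDecoder,
    csp_from_covariances,
    csp_features,
    fit_csp,
    loo_accuracy,
    make_fold_plan,
    stratify_performers,
    trial_covariances,
)


def gaussian_trials(rng, cov, n_trials, n_samples=200):
    """Trials drawn from a zero-mean Gaussian with channel covariance cov."""
    chol = np.linalg.cholesky(cov)
    return np.einsum(
        "cd,tds->tcs", chol, rng.standard_normal((n_trials, cov.shape[0], n_samples))
    )


def random_spd(rng, n):
    a = rng.standard_normal((n, n))
    return a @ a.T + n * np.eye(n)


def csp_oracle(c_a, c_b):
    """Direct generalized eigendecomposition: C_a w = lambda (C_a + C_b) w."""
    evals, evecs = linalg.eigh(c_a, c_a + c_b)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


class TestCSPFit:
    def test_closed_form_two_channel(self):
        """diag(10,1) vs diag(1,10): the leading filter isolates channel 1
        and its eigenvalue is 10/11."""
        model = csp_from_covariances(
            np.diag([10.0, 1.0]), np.diag([1.0, 10.0]), n_select=1
        )
        w = model.filters_[0]
        assert abs(w[0]) > 10 * abs(w[1])
        assert model.eigenvalues_[0] == pytest.approx(10 / 11, abs=1e-12)

    def test_identical_covariances_give_half_eigenvalues(self):
        c = random_spd(np.random.default_rng(0), 6)
        model = csp_from_covariances(c, c.copy(), n_select=1)
        np.testing.assert_allclose(model.eigenvalues_, 0.5, atol=1e-10)

    def test_matches_generalized_eig_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(4, 16)
            c_a, c_b = random_spd(rng, n), random_spd(rng, n)
            model = csp_from_covariances(c_a, c_b, n_select=1)
            lam, v = csp_oracle(c_a, c_b)
            np.testing.assert_allclose(model.eigenvalues_, lam, atol=1e-9)
            for j in range(n):
                cos = np.abs(model.filters_[j] @ v[:, j]) / (
                    np.linalg.norm(model.filters_[j]) * np.linalg.norm(v[:, j])
                )
                assert cos > 1 - 1e-6

    def test_eigenvalue_mirror_symmetry(self):
        rng = np.random.default_rng(2)
        c_a, c_b = random_spd(rng, 8), random_spd(rng, 8)
        ab = csp_from_covariances(c_a, c_b).eigenvalues_
        ba = csp_from_covariances(c_b, c_a).eigenvalues_
        np.testing.assert_allclose(ab, 1.0 - ba[::-1], atol=1e-9)

    def test_rank_deficient_covariance_reported(self):
        c = np.zeros((4, 4))
        c[0, 0] = 1.0
        with pytest.raises(np.linalg.LinAlgError, match="rank-deficient"):
            csp_from_covariances(c, c.copy(), n_select=1)

    def test_needs_two_trials_per_class(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((3, 4, 100))
        with pytest.raises(ValueError, match="2 trials"):
            CSP(n_select=1).fit(X, np.array([0, 0, 1]))


class TestFeatures:
    def test_feature_dimension_is_twice_n_select(self):
        rng = np.random.default_rng(4)
        X_a = rng.standard_normal((10, 12, 300))
        X_b = rng.standard_normal((10, 12, 300))
        model = fit_csp(X_a, X_b, n_select=4)
        assert csp_features(X_a, model).shape == (10, 8)

    def test_unit_variance_noise_gives_near_zero_features(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 6, 2000))
        y = np.r_[np.zeros(15), np.ones(15)]
        model = CSP(n_select=3).fit(X, y)
        # filters are normalized so unit-variance white input keeps unit
        # projected variance up to whitening scale; compare classes instead
        feats = model.transform(X)
        assert np.abs(feats[:15].mean(0) - feats[15:].mean(0)).max() < 0.2

    def test_amplitude_doubling_adds_log4(self):
        rng = np.random.default_rng(6)
        X_a = rng.standard_normal((8, 5, 400))
        X_b = rng.standard_normal((8, 5, 400))
        model = fit_csp(X_a, X_b, n_select=2)
        f1 = model.transform(X_a)
        f2 = model.transform(2.0 * X_a)
        np.testing.assert_allclose(f2 - f1, np.log(4.0), atol=1e-9)

    def test_covariance_trace_normalized(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((4, 3, 100))
        covs = trial_covariances(X)
        np.testing.assert_allclose(np.trace(covs, axis1=1, axis2=2), 1.0)


class TestLOO:
    def test_fold_plan_pairs_each_trial_once(self):
        plan = make_fold_plan(40, 40, seed=0)
        assert plan.n_folds == 40
        a_idx = [s[0] for s in plan.sets]
        b_idx = [s[1] for s in plan.sets]
        assert sorted(a_idx) == list(range(40))
        assert sorted(b_idx) == list(range(40))

    def test_forty_sets_for_forty_trials(self):
        rng = np.random.default_rng(8)
        X_a = rng.standard_normal((40, 4, 120))
        X_b = rng.standard_normal((40, 4, 120))
        acc, folds = loo_accuracy(X_a, X_b, n_select=1, seed=0)
        assert len(folds) == 40

    def test_constructed_separability_gives_perfect_accuracy(self):
        rng = np.random.default_rng(9)
        X_a = rng.standard_normal((20, 4, 300))
        X_b = rng.standard_normal((20, 4, 300))
        X_a[:, 0, :] *= np.sqrt(10.0)  # 10x variance ratio on one channel
        acc, _ = loo_accuracy(X_a, X_b, n_select=1, seed=1)
        assert acc == 1.0

    def test_matches_naive_refit_decoder(self):
        """The covariance-cached LOO equals fold-wise refitting of the
        estimator pipeline from raw trials."""
        rng = np.random.default_rng(10)
        X_a = rng.standard_normal((6, 3, 150))
        X_b = 1.3 * rng.standard_normal((6, 3, 150))
        acc, folds = loo_accuracy(X_a, X_b, n_select=1, seed=2)

        plan = make_fold_plan(6, 6, seed=2)
        X = np.concatenate([X_a, X_b])
        y = np.r_[np.zeros(6, int), np.ones(6, int)]
        correct = 0
        for ia, ib in plan.sets:
            test = np.array([ia, 6 + ib])
            train = np.setdiff1d(np.arange(12), test)
            model = CSPDecoder(n_select=1).fit(X[train], y[train])
            correct += int((model.predict(X[test]) == y[test]).sum())
        assert acc == correct / 12

    def test_held_out_pair_never_influences_training(self):
        """The model trained for a fold is byte-identical no matter what the
        held-out trials contain (training uses the training mask only)."""
        rng = np.random.default_rng(11)
        X = rng.standard_normal((12, 3, 150))
        y = np.r_[np.zeros(6, int), np.ones(6, int)]
        train = np.ones(12, bool)
        train[[0, 6]] = False
        m1 = CSP(n_select=1).fit(X[train], y[train])
        X2 = X.copy()
        X2[0] = 100.0 * rng.standard_normal((3, 150))
        X2[6] = -50.0 * rng.standard_normal((3, 150))
        m2 = CSP(n_select=1).fit(X2[train], y[train])
        np.testing.assert_array_equal(m1.filters_, m2.filters_)

    def test_too_few_trials_rejected(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError, match="4 trials"):
            loo_accuracy(
                rng.standard_normal((3, 2, 50)), rng.standard_normal((5, 2, 50))
            )


@pytest.mark.parametrize(
    "accuracy,expected",
    [(0.89, "HIGH"), (0.68, "LOW"), (0.80, "LOW"), (0.801, "HIGH")],
)
def test_stratification_threshold_is_strict(accuracy, expected):
    assert stratify_performers(accuracy) == expected


def test_stratification_rejects_invalid_accuracy():
    with pytest.raises(ValueError):
        stratify_performers(1.2)
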