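"""wPLI estimation, baseline normalization and permutation significance."""

import itertools

import numpy as np
import pytest

from mises.connectivity import (
    BANDS,
    PermutationSpec,
    baseline_wpli_bootstrap,
    normalize_wpli,
    paired_t_permutation,
    permutation_significance,
    wpli,
    wpli_from_imag,
)

from conftest import make_epochs


def lagged_pair_epochs(lag, n_trials=40, snr=10.0, freq=10.0, fs=250.0,
                       seed=0, common=0.0):
    """Two channels carrying one oscillation with a fixed phase lag, plus
    independent noise; optionally a shared zero-lag component."""
    rng = np.random.default_rng(seed)
    n = int(7.5 * fs)
    t = -2.0 + np.arange(n) / fs
    amp = 1.0
    noise_sd = 0.0 if np.isinf(snr) else amp / np.sqrt(2 * snr)
    data = np.empty((n_trials, 2, n))
    for k in range(n_trials):
        phi = rng.uniform(0, 2 * np.pi)
        x = amp * np.sin(2 * np.pi * freq * t + phi)
        y = amp * np.sin(2 * np.pi * freq * t + phi - lag)
        z = common * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
        data[k, 0] = x + z + noise_sd * rng.standard_normal(n)
        data[k, 1] = y + z + noise_sd * rng.standard_normal(n)
    return make_epochs(data, ["F3", "P3"], ["MI"] * n_trials, fs=fs, t0=-2.0)


class TestWpli:
    def test_quarter_cycle_lag_approaches_one(self):
        epochs = lagged_pair_epochs(np.pi / 2, snr=10.0)
        mat = wpli(epochs, BANDS["alpha"], (3.0, 5.0), channels=["F3", "P3"])
        assert mat[0, 1] > 0.95
        assert mat[0, 1] == mat[1, 0]
        assert np.isnan(mat[0, 0])

    def test_zero_lag_is_degenerate_near_zero(self):
        epochs = lagged_pair_epochs(0.0, snr=100.0)
        mat = wpli(epochs, BANDS["alpha"], (3.0, 5.0), channels=["F3", "P3"])
        assert mat[0, 1] < 0.2

    def test_sign_model_matches_enumeration(self):
        """Imaginary parts +-1 with P(+)=p: wPLI = |mean sign|; its
        expectation over sign patterns is enumerable exactly for small n and
        tends to |2p-1|."""
        p = 0.75
        n = 12
        # exact expectation by enumeration over all 2^n sign patterns
        exact = 0.0
        for signs in itertools.product([1.0, -1.0], repeat=n):
            k = sum(s > 0 for s in signs)
            prob = p**k * (1 - p) ** (n - k)
            exact += prob * abs(np.mean(signs))
        rng = np.random.default_rng(0)
        draws = rng.choice([1.0, -1.0], p=[p, 1 - p], size=(20000, n))
        sample = np.array(
            [wpli_from_imag(d[:, None], axis=0)[0] for d in draws]
        ).mean()
        assert sample == pytest.approx(exact, abs=0.01)
        # and the large-n limit is the closed form |2p - 1| = 0.5
        big = rng.choice([1.0, -1.0], p=[p, 1 - p], size=(4000, 1))
        assert wpli_from_imag(big, axis=0)[0] == pytest.approx(0.5, abs=0.03)

    def test_amplitude_rescaling_invariance(self):
        epochs = lagged_pair_epochs(np.pi / 3, snr=3.0, seed=2)
        m1 = wpli(epochs, BANDS["alpha"], (3.0, 5.0), channels=["F3", "P3"])
        scaled = make_epochs(
            epochs.data * np.array([1.0, 17.0])[None, :, None],
            epochs.channels, epochs.conditions, t0=epochs.t0,
        )
        m2 = wpli(scaled, BANDS["alpha"], (3.0, 5.0), channels=["F3", "P3"])
        assert m1[0, 1] == pytest.approx(m2[0, 1], abs=1e-12)

    def test_common_zero_lag_source_does_not_inflate(self):
        """Volume-conduction robustness: adding a shared zero-lag source to
        an uncoupled pair leaves wPLI at its uncoupled level."""
        rng = np.random.default_rng(3)
        base, contaminated = [], []
        for seed in range(10):
            un = lagged_pair_epochs(0.0, snr=0.0001, seed=seed)  # pure noise
            co = lagged_pair_epochs(0.0, snr=0.0001, seed=seed, common=2.0)
            base.append(wpli(un, BANDS["alpha"], (3.0, 5.0), channels=["F3", "P3"])[0, 1])
            contaminated.append(
                wpli(co, BANDS["alpha"], (3.0, 5.0), channels=["F3", "P3"])[0, 1]
            )
        assert np.mean(contaminated) <= np.quantile(base, 0.95) + 0.05

    def test_single_trial_rejected(self):
        epochs = lagged_pair_epochs(np.pi / 2, n_trials=3)
        with pytest.raises(ValueError, match="5 trials"):
            wpli(epochs, BANDS["alpha"], (3.0, 5.0), channels=["F3", "P3"])


class TestNormalization:
    def test_task_equal_to_baseline_mean_is_zero(self):
        baseline = np.array([[0.2], [0.4], [0.3], [0.3]])
        assert normalize_wpli(np.array([0.3]), baseline)[0] == pytest.approx(0.0)

    def test_one_sd_above_is_one(self):
        baseline = np.array([[0.2], [0.4]])
        sd = np.std([0.2, 0.4], ddof=1)
        z = normalize_wpli(np.array([0.3 + sd]), baseline)
        assert z[0] == pytest.approx(1.0)

    def test_pair_constant_shift_invariance(self):
        rng = np.random.default_rng(4)
        baseline = rng.uniform(0.2, 0.4, size=(50, 3))
        task = rng.uniform(0.2, 0.5, size=3)
        z1 = normalize_wpli(task, baseline)
        z2 = normalize_wpli(task + 0.1, baseline + 0.1)
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="zero baseline SD"):
            normalize_wpli(np.array([0.3]), np.array([[0.2], [0.2]]))

    def test_bootstrap_shape_and_determinism(self, low_analysis_epochs):
        b1 = baseline_wpli_bootstrap(
            low_analysis_epochs, BANDS["alpha"], condition="REST",
            channels=["F3", "C3", "P3"], n_boot=20, seed=5,
        )
        b2 = baseline_wpli_bootstrap(
            low_analysis_epochs, BANDS["alpha"], condition="REST",
            channels=["F3", "C3", "P3"], n_boot=20, seed=5,
        )
        assert b1.shape == (20, 3)
        np.testing.assert_array_equal(b1, b2)


class TestPermutation:
    def test_spec_requires_enough_permutations(self):
        with pytest.raises(ValueError, match="permutations"):
            PermutationSpec(n_perm=100, threshold=0.005)

    def test_determinism_under_seed(self, low_analysis_epochs):
        spec = PermutationSpec(n_perm=300, threshold=0.01, seed=7)
        args = (low_analysis_epochs, "MI", "REST", BANDS["alpha"])
        kwargs = dict(channels=["F3", "C3", "P3"], spec=spec)
        p1, _, _ = permutation_significance(*args, **kwargs)
        p2, _, _ = permutation_significance(*args, **kwargs)
        np.testing.assert_array_equal(p1, p2)

    def test_constructed_effect_detected_at_minimum_p(self):
        """Strong quarter-cycle coupling present in A only reaches the
        attainable minimum p = 1/(1+n_perm)."""
        a = lagged_pair_epochs(np.pi / 2, n_trials=30, snr=10.0, seed=8)
        b = lagged_pair_epochs(0.0, n_trials=30, snr=0.001, seed=9)
        data = np.concatenate([a.data, b.data])
        conds = np.array(["MI"] * 30 + ["REST"] * 30)
        epochs = make_epochs(data, ["F3", "P3"], conds, t0=-2.0)
        spec = PermutationSpec(n_perm=400, threshold=0.005, seed=1)
        p, sig, obs = permutation_significance(
            epochs, "MI", "REST", BANDS["alpha"], channels=["F3", "P3"], spec=spec
        )
        assert p[0] == pytest.approx(1.0 / 401.0)
        assert sig[0]
        assert obs[0] > 0.5

    def test_subject_level_paired_t_detects_shift(self):
        rng = np.random.default_rng(10)
        diffs = rng.normal(0.5, 0.1, size=(12, 4))
        diffs[:, 0] = rng.normal(0.0, 0.1, size=12)
        p, sig, t = paired_t_permutation(diffs, PermutationSpec(n_perm=300, threshold=0.01, seed=2))
        assert not sig[0]
        assert sig[1:].all()
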