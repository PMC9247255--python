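"""Weighted phase lag index (wPLI) connectivity and permutation testing.

wPLI of a channel pair is |E[imag(S_xy)]| / E[|imag(S_xy)|], the signed
imaginary cross-spectrum average normalized by its unsigned average; the
expectation runs over observations, here one Hanning-tapered Fourier
cross-spectral estimate per trial per in-band frequency bin.  Zero-lag
(volume-conducted) coupling contributes no imaginary part, so it cannot
inflate the index; when the denominator is numerically zero the pair is
reported as 0 and flagged degenerate.

Task-window wPLI is z-normalized against the baseline window, whose
sampling variability is estimated by bootstrap resampling of trials.
Edge significance uses a permutation test: trial condition labels are
exchanged and the wPLI difference recomputed (the paired t-statistic over
subjects is available for group-level testing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import CONNECTIVITY_CHANNELS
from .preprocess import EpochsSet

_DEGENERACY_TOL = 1e-12

BANDS = {"alpha": (8.0, 13.0), "beta": (14.0, 28.0)}


@dataclass(frozen=True)
class PermutationSpec:
    """Permutation-test configuration for edge significance."""

    n_perm: int = 2000
    threshold: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1.0 / self.threshold:
            raise ValueError(
                f"n_perm={self.n_perm} cannot resolve p < {self.threshold}; "
                f"need at least {int(np.ceil(1 / self.threshold))} permutations"
            )


def _band_cross_terms(
    epochs: EpochsSet,
    trials: np.ndarray,
    band: tuple[float, float],
    time_window: tuple[float, float],
) -> np.ndarray:
    """Imaginary cross-spectrum terms: (n_trials, n_pairs, n_bins).

    One tapered Fourier estimate per trial; pairs are the upper triangle of
    the channel x channel matrix in channel order.
    """
    idx = epochs.time_indices(time_window)
    x = trials[:, :, idx]
    taper = np.hanning(x.shape[2])
    spec = np.fft.rfft(x * taper[None, None, :], axis=2)
    freqs = np.fft.rfftfreq(x.shape[2], d=1.0 / epochs.fs)
    sel = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    z = spec[:, :, sel]
    iu, ju = np.triu_indices(trials.shape[1], k=1)
    return np.imag(z[:, iu, :] * np.conj(z[:, ju, :]))


def wpli_from_imag(imag: np.ndarray, axis: int = 0) -> np.ndarray:
    """wPLI from imaginary cross-spectrum observations along ``axis``;
    degenerate denominators yield 0."""
    num = np.abs(np.mean(imag, axis=axis))
    den = np.mean(np.abs(imag), axis=axis)
    out = np.zeros_like(den)
    ok = den > _DEGENERACY_TOL
    out[ok] = num[ok] / den[ok]
    return out


def _pairs_to_matrix(values: np.ndarray, n_ch: int) -> np.ndarray:
    mat = np.full((n_ch, n_ch), np.nan)
    iu, ju = np.triu_indices(n_ch, k=1)
    mat[iu, ju] = values
    mat[ju, iu] = values
    return mat


def wpli(
    epochs: EpochsSet,
    band: tuple[float, float],
    time_window: tuple[float, float] = (3.0, 5.0),
    condition: str | None = None,
    channels: list[str] | None = None,
    return_matrix: bool = True,
):
    """Pairwise wPLI over trials x in-band frequency bins.

    Returns a symmetric (n_channels, n_channels) matrix with NaN diagonal,
    or the upper-triangle vector when ``return_matrix`` is False.  Needs at
    least 5 trials for a stable asymmetry estimate.
    """
    chans = channels or [c for c in CONNECTIVITY_CHANNELS if c in epochs.channels]
    sub = epochs.data[:, [epochs.channel_index(c) for c in chans], :]
    mask = (epochs.conditions == condition) if condition else np.ones(len(sub), bool)
    mask = mask & epochs.kept_mask
    trials = sub[mask]
    if len(trials) < 5:
        raise ValueError("need at least 5 trials to estimate wPLI")
    imag = _band_cross_terms(epochs, trials, band, time_window)
    obs = imag.transpose(0, 2, 1).reshape(-1, imag.shape[1])  # (trials*bins, pairs)
    vals = wpli_from_imag(obs, axis=0)
    if return_matrix:
        return _pairs_to_matrix(vals, len(chans))
    return vals


def baseline_wpli_bootstrap(
    epochs: EpochsSet,
    band: tuple[float, float],
    baseline_window: tuple[float, float] = (-1.0, -0.2),
    condition: str | None = None,
    channels: list[str] | None = None,
    n_boot: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Bootstrap distribution (n_boot, n_pairs) of baseline-window wPLI.

    A single baseline window yields one wPLI number per pair; resampling
    trials with replacement provides the spread needed for z-normalization.
    """
    chans = channels or [c for c in CONNECTIVITY_CHANNELS if c in epochs.channels]
    sub = epochs.data[:, [epochs.channel_index(c) for c in chans], :]
    mask = (epochs.conditions == condition) if condition else np.ones(len(sub), bool)
    mask = mask & epochs.kept_mask
    trials = sub[mask]
    if len(trials) < 5:
        raise ValueError("need at least 5 trials to estimate wPLI")
    imag = _band_cross_terms(epochs, trials, band, baseline_window)
    rng = np.random.default_rng(seed)
    n = len(trials)
    out = np.empty((n_boot, imag.shape[1]))
    s_t = imag.sum(axis=2)  # per-trial signed sums
    a_t = np.abs(imag).sum(axis=2)
    for b in range(n_boot):
        pick = rng.integers(0, n, size=n)
        num = np.abs(s_t[pick].sum(axis=0))
        den = a_t[pick].sum(axis=0)
        ok = den > _DEGENERACY_TOL
        row = np.zeros(imag.shape[1])
        row[ok] = num[ok] / den[ok]
        out[b] = row
    return out


def normalize_wpli(task_values: np.ndarray, baseline_values: np.ndarray) -> np.ndarray:
    """z = (task - mean(baseline)) / sd(baseline), per pair."""
    baseline_values = np.atleast_2d(baseline_values)
    if baseline_values.shape[0] < 2:
        raise ValueError("need >= 2 baseline estimates per pair")
    mu = baseline_values.mean(axis=0)
    sd = baseline_values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero baseline SD; cannot z-normalize")
    return (task_values - mu) / sd


def permutation_significance(
    epochs: EpochsSet,
    condition_a: str,
    condition_b: str,
    band: tuple[float, float],
    time_window: tuple[float, float] = (3.0, 5.0),
    channels: list[str] | None = None,
    spec: PermutationSpec = PermutationSpec(),
):
    """Trial-label permutation test of the per-pair wPLI difference.

    The observed statistic is wPLI(A) - wPLI(B) computed from trial-wise
    cross-spectra; the null distribution exchanges trial condition labels
    ``spec.n_perm`` times.  Two-sided p-values use the add-one estimator
    p = (1 + #{|d_perm| >= |d_obs|}) / (1 + n_perm).

    Returns ``(p_values, sig_mask, observed_diff)`` over channel pairs
    (upper triangle in channel order).
    """
    chans = channels or [c for c in CONNECTIVITY_CHANNELS if c in epochs.channels]
    sub = epochs.data[:, [epochs.channel_index(c) for c in chans], :]
    mask_a = (epochs.conditions == condition_a) & epochs.kept_mask
    mask_b = (epochs.conditions == condition_b) & epochs.kept_mask
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a < 5 or n_b < 5:
        raise ValueError("need at least 5 trials per condition")
    trials = np.concatenate([sub[mask_a], sub[mask_b]], axis=0)
    imag = _band_cross_terms(epochs, trials, band, time_window)
    s_t = imag.sum(axis=2)  # (n_trials, n_pairs)
    a_t = np.abs(imag).sum(axis=2)

    def diff(sel_a: np.ndarray) -> np.ndarray:
        sel_a = sel_a.astype(float)
        sel_b = 1.0 - sel_a
        num_a, den_a = np.abs(sel_a @ s_t), sel_a @ a_t
        num_b, den_b = np.abs(sel_b @ s_t), sel_b @ a_t
        w_a = np.where(den_a > _DEGENERACY_TOL, num_a / np.maximum(den_a, _DEGENERACY_TOL), 0.0)
        w_b = np.where(den_b > _DEGENERACY_TOL, num_b / np.maximum(den_b, _DEGENERACY_TOL), 0.0)
        return w_a - w_b

    n_tot = n_a + n_b
    obs_sel = np.zeros(n_tot)
    obs_sel[:n_a] = 1.0
    observed = diff(obs_sel[None, :])[0]

    rng = np.random.default_rng(spec.seed)
    perm_sel = np.zeros((spec.n_perm, n_tot))
    for i in range(spec.n_perm):
        perm_sel[i, rng.permutation(n_tot)[:n_a]] = 1.0
    null = diff(perm_sel)
    exceed = (np.abs(null) >= np.abs(observed)[None, :] - 1e-15).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + spec.n_perm)
    return p, p < spec.threshold, observed


def paired_t_permutation(
    diffs: np.ndarray, spec: PermutationSpec = PermutationSpec(n_perm=2000)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group-level sign-flip permutation test on per-subject wPLI
    differences (n_subjects, n_pairs), using the paired t-statistic."""
    diffs = np.atleast_2d(diffs)
    n_subj = diffs.shape[0]

    def tstat(d: np.ndarray) -> np.ndarray:
        mu = d.mean(axis=0)
        se = d.std(axis=0, ddof=1) / np.sqrt(n_subj)
        return np.where(se > 0, mu / np.maximum(se, 1e-300), 0.0)

    observed = tstat(diffs)
    rng = np.random.default_rng(spec.seed)
    exceed = np.zeros(diffs.shape[1])
    for _ in range(spec.n_perm):
        flips = rng.choice([-1.0, 1.0], size=n_subj)
        exceed += np.abs(tstat(diffs * flips[:, None])) >= np.abs(observed) - 1e-15
    p = (1.0 + exceed) / (1.0 + spec.n_perm)
    return p, p < spec.threshold, observed


def significant_edge_count(
    epochs: EpochsSet,
    condition: str,
    band: tuple[float, float],
    reference_condition: str = "REST",
    time_window: tuple[float, float] = (3.0, 5.0),
    channels: list[str] | None = None,
    spec: PermutationSpec = PermutationSpec(n_perm=400, threshold=0.005),
) -> int:
    """Number of channel pairs whose task-window wPLI differs significantly
    between a condition and the resting reference."""
    _, sig, _ = permutation_significance(
        epochs, condition, reference_condition, band, time_window, channels, spec
    )
    return int(sig.sum())
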