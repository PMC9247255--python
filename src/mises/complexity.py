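"""Sample entropy (SampEn) and its task/baseline relative form.

SampEn(x, m, r) = -ln(B_{m+1}(r) / B_m(r)): the negative log conditional
probability that two sequences matching for m points (Chebyshev distance
<= r) still match for m+1 points.  Template pairs are counted over
i != j with both template start indices in 1..N-m (the Richman-Moorman
convention, self-matches excluded).  The printed per-template
normalizations 1/(N-m) and 1/(N-m-1) cancel in the ratio, so the estimator
is computed directly from the raw pair counts.

The relative SampEn of a trial is (task - baseline) / baseline, with both
window entropies computed on the band-limited series and the tolerance
r = g * SD taken per analysis window.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .preprocess import EpochsSet


def _template_count(x: np.ndarray, m: int, r_abs: float) -> int:
    """Number of ordered-pair-free (i < j) template matches at length m,
    both indices in 0..N-m-1."""
    n = x.size
    n_templates = n - m
    # running Chebyshev distance between all template pairs
    d = np.zeros((n_templates, n_templates))
    for k in range(m):
        seg = x[k : k + n_templates]
        d = np.maximum(d, np.abs(seg[:, None] - seg[None, :]))
    match = d <= r_abs
    return int((match.sum() - n_templates) // 2)  # remove self-matches, i<j


def sampen_counts(x: np.ndarray, m: int = 2, r_abs: float | None = None) -> tuple[int, int]:
    """Raw template-match pair counts (B_m, B_{m+1}).

    Both counts use start indices 0..N-m-1 so the length-(m+1) templates
    exist for every counted index.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < m + 2:
        raise ValueError(f"series too short (N={x.size}) for m={m}")
    if r_abs is None or r_abs <= 0:
        raise ValueError("r_abs must be positive")
    n_templates = x.size - m
    b_m = 0
    b_m1 = 0
    d = np.zeros((n_templates, n_templates))
    for k in range(m + 1):
        seg = x[k : k + n_templates]
        d = np.maximum(d, np.abs(seg[:, None] - seg[None, :]))
        if k == m - 1:
            b_m = int((np.count_nonzero(d <= r_abs) - n_templates) // 2)
    b_m1 = int((np.count_nonzero(d <= r_abs) - n_templates) // 2)
    return b_m, b_m1


def sampen(x: np.ndarray, m: int = 2, r_abs: float | None = None) -> float:
    """Sample entropy with an absolute tolerance.

    Returns ``+inf`` (with a warning) when no template pair matches at
    length m+1; raises when none matches even at length m, since the
    conditional probability is then undefined.
    """
    b_m, b_m1 = sampen_counts(x, m, r_abs)
    if b_m == 0:
        raise ValueError("degenerate series: no length-m template matches")
    if b_m1 == 0:
        warnings.warn("no length-(m+1) template matches; SampEn is infinite")
        return float("inf")
    return float(-np.log(b_m1 / b_m))


def sampen_sd_tolerance(x: np.ndarray, m: int = 2, g: float = 0.1) -> float:
    """SampEn with tolerance r = g * SD of the analysed series itself."""
    x = np.asarray(x, dtype=float).ravel()
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate series: zero standard deviation")
    return sampen(x, m, g * sd)


def relative_sampen(
    epochs: EpochsSet,
    condition: str,
    channel: str = "C3",
    band: tuple[float, float] = (8.0, 28.0),
    m: int = 2,
    g: float = 0.1,
    task_window: tuple[float, float] = (3.0, 5.0),
    baseline_window: tuple[float, float] = (-1.0, -0.2),
) -> tuple[np.ndarray, float]:
    """Per-trial relative SampEn at one channel, and the condition mean.

    Each trial's channel series is band-limited (zero-phase Butterworth)
    over the whole epoch, the two analysis windows are cut out, and
    SampEn is computed per window with tolerance g * SD of that window.
    Relative SampEn = (task - baseline) / baseline.  Trials with an
    infinite window entropy are dropped from the mean (with a warning
    already emitted by :func:`sampen`).
    """
    ci = epochs.channel_index(channel)
    data = epochs.select(condition)[:, ci, :]
    sos = signal.butter(4, band, btype="bandpass", fs=epochs.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, data, axis=1)
    it = epochs.time_indices(task_window)
    ib = epochs.time_indices(baseline_window)

    values = []
    for trial in filtered:
        se_task = sampen_sd_tolerance(trial[it], m, g)
        se_base = sampen_sd_tolerance(trial[ib], m, g)
        if se_base == 0:
            raise ValueError("baseline SampEn is zero; relative form undefined")
        values.append((se_task - se_base) / se_base)
    values = np.asarray(values)
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("no finite relative SampEn values")
    return values, float(values[finite].mean())
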