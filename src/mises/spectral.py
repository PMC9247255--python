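"""Event-related spectral perturbation (ERSP) and r^2 discriminability maps.

ERSP is the trial-averaged short-time Fourier power (Hanning taper, window
256 samples), converted to dB and baseline-corrected by subtracting the
mean dB power in a pre-cue window per frequency.  r^2 is the squared
point-biserial correlation between trial class labels and single-trial
spectral power, averaged over a frequency band and time window to give one
discriminability value per channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import EpochsSet

ALPHA_BAND = (8.0, 13.0)
BETA_BAND = (14.0, 28.0)


@dataclass
class TFMap:
    """Per-channel time-frequency map in dB relative to baseline.

    ``valid`` flags time bins whose full analysis window lies inside the
    epoch; edge bins are computed on zero-padded data and excluded from band
    averages.
    """

    values: np.ndarray  # (n_channels, n_freqs, n_times), dB
    freqs: np.ndarray
    times: np.ndarray  # seconds relative to the preparation cue
    valid: np.ndarray  # (n_times,) bool
    channels: list[str]
    baseline_window: tuple[float, float]
    window_len: int

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel!r} not in map") from None


def _stft_power(
    x: np.ndarray, fs: float, window_len: int, hop: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Single-channel trials -> (power (n_trials, n_f, n_t), freqs,
    center indices, valid mask).  Frames crossing the epoch edge are
    zero-padded and flagged invalid."""
    n_trials, n_samp = x.shape
    half = window_len // 2
    centers = np.arange(0, n_samp, hop)
    valid = (centers - half >= 0) & (centers + half <= n_samp)
    taper = np.hanning(window_len)
    pad = np.zeros((n_trials, n_samp + window_len))
    pad[:, half : half + n_samp] = x
    starts = centers  # centers - half + half
    frames = np.stack([pad[:, s : s + window_len] for s in starts], axis=1)
    spec = np.fft.rfft(frames * taper[None, None, :], axis=2)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(window_len, d=1.0 / fs)
    return np.moveaxis(power, 1, 2), freqs, centers, valid


def ersp(
    epochs: EpochsSet,
    condition: str | None = None,
    channels: list[str] | None = None,
    window_len: int = 256,
    hop: int = 25,
    baseline: tuple[float, float] = (-1.0, -0.2),
) -> TFMap:
    """Trial-averaged ERSP map (dB relative to the pre-cue baseline).

    Power spectra of all trials are averaged per (frequency, time) bin,
    converted to dB, and the mean baseline-window dB value per frequency is
    subtracted.  The baseline window must contain at least one valid bin.
    """
    if window_len > epochs.data.shape[2]:
        raise ValueError("window_len exceeds epoch length")
    data = epochs.select(condition) if condition is not None else epochs.data[epochs.kept_mask]
    chans = channels if channels is not None else list(epochs.channels)
    idx = [epochs.channel_index(c) for c in chans]

    maps = []
    freqs = centers = valid = None
    for ci in idx:
        power, freqs, centers, valid = _stft_power(
            data[:, ci, :], epochs.fs, window_len, hop
        )
        mean_power = power.mean(axis=0)  # average over trials
        maps.append(10.0 * np.log10(np.maximum(mean_power, 1e-300)))
    values = np.stack(maps, axis=0)
    times = epochs.t0 + centers / epochs.fs

    in_base = (times >= baseline[0] - 1e-9) & (times <= baseline[1] + 1e-9) & valid
    if not in_base.any():
        raise ValueError(f"baseline window {baseline} has no valid time bins")
    base = values[:, :, in_base].mean(axis=2, keepdims=True)
    values = values - base
    return TFMap(
        values=values,
        freqs=freqs,
        times=times,
        valid=valid,
        channels=list(chans),
        baseline_window=baseline,
        window_len=window_len,
    )


def band_average(
    tfmap: TFMap,
    band: tuple[float, float],
    time_window: tuple[float, float],
    channel: str,
) -> float:
    """Mean dB over a frequency band x time window box (valid bins only)."""
    ci = tfmap.channel_index(channel)
    fsel = (tfmap.freqs >= band[0] - 1e-9) & (tfmap.freqs <= band[1] + 1e-9)
    tsel = (
        (tfmap.times >= time_window[0] - 1e-9)
        & (tfmap.times <= time_window[1] + 1e-9)
        & tfmap.valid
    )
    if not fsel.any() or not tsel.any():
        raise ValueError("empty band/time selection")
    return float(tfmap.values[ci][np.ix_(fsel, tsel)].mean())


def _pointbiserial_r2(power: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared correlation between labels and power, per column."""
    y = y.astype(float)
    yc = y - y.mean()
    pc = power - power.mean(axis=0, keepdims=True)
    denom = np.sqrt((yc**2).sum() * (pc**2).sum(axis=0))
    if np.any(denom == 0):
        raise ValueError("zero-variance power across trials")
    r = (yc @ pc) / denom
    return r**2


def r2_map(
    epochs_a: EpochsSet | np.ndarray,
    epochs_b: EpochsSet | np.ndarray,
    band: tuple[float, float] = (8.0, 28.0),
    time_window: tuple[float, float] = (3.0, 5.0),
    condition_a: str | None = None,
    condition_b: str | None = None,
    window_len: int = 256,
    hop: int = 25,
):
    """Per-channel r^2 discriminability between two trial classes.

    For every (frequency, time) bin inside ``band`` x ``time_window`` the
    squared point-biserial correlation between class labels and single-trial
    STFT power is computed, then averaged over the box.  Returns
    ``(values, channels)`` with values in [0, 1].

    The two inputs must be EpochsSets sharing fs, t0 and channels; pass
    ``condition_a``/``condition_b`` to select conditions from the same set.
    """
    a = epochs_a.select(condition_a) if condition_a else epochs_a.data[epochs_a.kept_mask]
    b = epochs_b.select(condition_b) if condition_b else epochs_b.data[epochs_b.kept_mask]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 trials per class")
    ref = epochs_a
    y = np.r_[np.zeros(len(a)), np.ones(len(b))]
    x = np.concatenate([a, b], axis=0)

    values = np.empty(len(ref.channels))
    for ci in range(len(ref.channels)):
        power, freqs, centers, valid = _stft_power(x[:, ci, :], ref.fs, window_len, hop)
        times = ref.t0 + centers / ref.fs
        fsel = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
        tsel = (times >= time_window[0] - 1e-9) & (times <= time_window[1] + 1e-9) & valid
        if not fsel.any() or not tsel.any():
            raise ValueError("empty band/time selection")
        box = power[:, fsel, :][:, :, tsel].reshape(len(x), -1)
        values[ci] = _pointbiserial_r2(box, y).mean()
    return values, list(ref.channels)
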