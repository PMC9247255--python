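"""Synthetic EEG generator for the four-condition motor-imagery paradigm.

The generator emulates a cue-paced brain-switch experiment with four trial
types -- motor imagery (MI), sensory-threshold somatosensory electrical
stimulation alone (SES), the combination (MI_SES), and rest (REST) -- and
injects the statistical structure the downstream analyses measure:

* lateralized alpha/beta event-related desynchronization (ERD) at C3 during
  MI-type trials, as a multiplicative amplitude envelope on narrowband
  rhythm sources added to spatially mixed pink background noise;
* an additional ERD component switching on two seconds into the task in
  conditions with stimulation (full strength in MI_SES, a smaller
  "attention" component in SES), ramped over 100 ms;
* a phase-lagged fronto-parietal coupled source pair whose strength is
  condition dependent, giving the wPLI analysis something to detect;
* distinct "high performer" and "low performer" effect profiles, the low
  profile having weaker, less consistent ERD and a large stimulation gain.

Rhythm sources are constant-amplitude phase-diffusion sinusoids under a slow
log-normal amplitude modulation.  Because the modulation is approximately
constant within one trial, the task/baseline power ratio of a trial equals
the squared ERD amplitude factor almost exactly, which gives closed-form
expected ERSP values; the slow modulation still spreads single-trial band
power across trials so that decoding is imperfect, as in real subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import (
    CONNECTIVITY_CHANNELS,
    DEFAULT_MONTAGE,
    channel_positions,
    mixing_matrix,
    source_projection,
)

CONDITIONS: tuple[str, ...] = ("MI", "SES", "MI_SES", "REST")

#: Conditions in which the subject performs motor imagery.
_MI_CONDITIONS = frozenset({"MI", "MI_SES"})
#: Conditions in which the stimulator is switched on mid-task.
_SES_CONDITIONS = frozenset({"SES", "MI_SES"})


@dataclass(frozen=True)
class ParadigmSpec:
    """Trial timing and condition structure of the experiment.

    Defaults follow the study paradigm: a 1 s preparation cue, a 4 s task
    period, stimulation onset 2 s into the task, inter-trial intervals
    drawn uniformly from 3-5 s, and 40 trials per condition (4 runs of 10,
    randomized within run).
    """

    prep_dur: float = 1.0
    task_dur: float = 4.0
    iti_range: tuple[float, float] = (3.0, 5.0)
    ses_onset: float = 2.0
    n_trials_per_condition: int = 40
    conditions: tuple[str, ...] = CONDITIONS
    n_runs: int = 4

    def __post_init__(self) -> None:
        if not self.prep_dur > 0:
            raise ValueError("prep_dur must be positive")
        if not (self.task_dur > self.ses_onset >= 0):
            raise ValueError("require task_dur > ses_onset >= 0")
        if self.iti_range[0] > self.iti_range[1]:
            raise ValueError("iti_range must be (low, high) with low <= high")
        if self.n_trials_per_condition < 2:
            raise ValueError("need at least 2 trials per condition")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition label(s): {sorted(unknown)}")


@dataclass(frozen=True)
class PerformerProfile:
    """Effect-size profile of one synthetic subject.

    ``erd_alpha_mi``/``erd_beta_mi`` are fractional amplitude reductions in
    [0, 1) of the C3 rhythm during motor imagery; ``ses_erd_gain`` is the
    extra fractional reduction switched on at stimulation onset in MI_SES;
    ``ses_attention_erd`` is the smaller "attention" reduction appearing
    from stimulation onset in SES alone (its magnitude is a free profile
    parameter).  ``erd_consistency`` is the log-normal sigma of the
    per-trial multiplicative jitter on these fractions -- large values
    model subjects who cannot hold a stable ERD.

    The coupled fronto-parietal source pair has constant total power
    ``coupling_strength`` (uV amplitude) but a condition-dependent
    phase-coherent fraction ``coupling_condition_coherence`` during task
    windows: the coherent component arrives at the parietal channel with
    phase lag ``coupling_lag`` (radians), the remainder is pair-independent
    rhythm at the same frequency.  Variance-based decoding therefore cannot
    see the coupling manipulation, while phase-lag connectivity can.
    """

    label: str = "HIGH"
    erd_alpha_mi: float = 0.65
    erd_beta_mi: float = 0.45
    erd_consistency: float = 0.15
    ses_erd_gain: float = 0.0
    ses_attention_erd: float = 0.35
    coupling_lag: float = np.pi / 2
    coupling_strength: float = 3.0
    coupling_band: str = "beta"
    coupling_condition_coherence: dict[str, float] = field(
        default_factory=lambda: {"MI": 0.9, "MI_SES": 0.5, "SES": 0.3, "REST": 0.2}
    )

    def __post_init__(self) -> None:
        if self.label not in ("HIGH", "LOW"):
            raise ValueError("label must be HIGH or LOW")
        for name in ("erd_alpha_mi", "erd_beta_mi", "ses_erd_gain", "ses_attention_erd"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.erd_consistency < 0 or self.coupling_strength < 0:
            raise ValueError("erd_consistency and coupling_strength must be >= 0")
        if self.coupling_band not in ("alpha", "beta"):
            raise ValueError("coupling_band must be 'alpha' or 'beta'")
        if any(not 0.0 <= c <= 1.0 for c in self.coupling_condition_coherence.values()):
            raise ValueError("coherent fractions must lie in [0, 1]")


def high_performer_profile() -> PerformerProfile:
    """Default high-performer profile: strong, consistent MI ERD, no
    stimulation gain, beta-band coupling strongest during plain MI."""
    return PerformerProfile()


def low_performer_profile() -> PerformerProfile:
    """Default low-performer profile: weak, inconsistent MI ERD, a large
    stimulation ERD gain, alpha-band coupling strongest under MI_SES."""
    return PerformerProfile(
        label="LOW",
        erd_alpha_mi=0.32,
        erd_beta_mi=0.18,
        erd_consistency=0.45,
        ses_erd_gain=0.50,
        ses_attention_erd=0.15,
        coupling_band="alpha",
        coupling_condition_coherence={"MI": 0.5, "MI_SES": 0.9, "SES": 0.3, "REST": 0.2},
    )


@dataclass(frozen=True)
class NoiseModel:
    """Background-activity model.

    Pink (1/f^pink_exponent) sources under every electrode, mixed across the
    scalp with a distance-based row-normalized kernel, plus white sensor
    noise.  Rhythm carriers default to 10 Hz (alpha) and 20 Hz (beta),
    inside the study's 8-13 / 14-28 Hz band definitions.  Amplitudes are in
    microvolts.
    """

    pink_exponent: float = 1.0
    channel_noise_sd: float = 1.5
    background_sd: float = 9.0
    mixing_sigma: float = 0.04
    osc_freq_alpha: float = 10.0
    osc_freq_beta: float = 20.0
    osc_amp_alpha: float = 7.0
    osc_amp_beta: float = 3.5
    am_sigma: float = 0.15
    am_cutoff_hz: float = 0.05
    phase_jitter: float = 2.5

    def __post_init__(self) -> None:
        if not (0.5 <= self.pink_exponent <= 2.0):
            raise ValueError("pink_exponent must lie in [0.5, 2]")
        if self.channel_noise_sd <= 0:
            raise ValueError("channel_noise_sd must be positive")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")


@dataclass
class ContinuousRecord:
    """A continuous multichannel EEG recording in microvolts."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    channels: list[str]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _pink_noise(rng: np.random.Generator, n_src: int, n: int, exponent: float) -> np.ndarray:
    """(n_src, n) unit-variance 1/f^exponent noise via spectral shaping."""
    from scipy import fft as sfft

    nfft = sfft.next_fast_len(n, real=True)
    white = rng.standard_normal((n_src, nfft))
    spec = sfft.rfft(white, axis=1)
    freqs = sfft.rfftfreq(nfft)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    shaped = sfft.irfft(spec * shape[None, :], n=nfft, axis=1)[:, :n]
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _slow_am(rng: np.random.Generator, n: int, fs: float, cutoff: float, sigma: float) -> np.ndarray:
    """exp(sigma * u(t)) with u low-pass filtered unit-variance noise."""
    from scipy import fft as sfft

    if sigma == 0:
        return np.ones(n)
    nfft = sfft.next_fast_len(n, real=True)
    white = rng.standard_normal(nfft)
    spec = sfft.rfft(white)
    freqs = sfft.rfftfreq(nfft, d=1.0 / fs)
    spec[freqs > cutoff] = 0.0
    u = sfft.irfft(spec, n=nfft)[:n]
    sd = u.std()
    if sd > 0:
        u = u / sd
    return np.exp(sigma * u - 0.5 * sigma**2)


def _phase_walk(rng: np.random.Generator, n: int, fs: float, diffusion: float) -> np.ndarray:
    """Wiener phase process with diffusion rate ``diffusion`` rad^2/s."""
    steps = rng.standard_normal(n) * np.sqrt(diffusion / fs)
    return np.cumsum(steps)


def _build_timeline(
    paradigm: ParadigmSpec, fs: float, rng: np.random.Generator, pad: float = 3.0
) -> tuple[pd.DataFrame, int]:
    """Randomized trial order (per run) and cue-onset samples."""
    labels: list[str] = []
    per_run = paradigm.n_trials_per_condition // paradigm.n_runs
    rem = paradigm.n_trials_per_condition - per_run * paradigm.n_runs
    for run in range(paradigm.n_runs):
        extra = 1 if run < rem else 0
        block = [c for c in paradigm.conditions for _ in range(per_run + extra)]
        order = rng.permutation(len(block))
        labels.extend(block[i] for i in order)

    onsets = []
    t = pad
    for _ in labels:
        onsets.append(int(round(t * fs)))
        iti = rng.uniform(*paradigm.iti_range)
        t += paradigm.prep_dur + paradigm.task_dur + iti
    n_samples = int(round((t + pad) * fs))
    events = pd.DataFrame({"onset_sample": onsets, "condition": labels})
    return events, n_samples


def _erd_envelope(
    events: pd.DataFrame,
    paradigm: ParadigmSpec,
    fs: float,
    n: int,
    erd_mi: float,
    ses_gain: float,
    attention_erd: float,
    jitter_sigma: float,
    rng: np.random.Generator,
    ramp: float = 0.1,
) -> np.ndarray:
    """Multiplicative amplitude envelope encoding MI ERD and the st-SES gain.

    The envelope is 1 outside tasks; drops to (1 - erd_k) over a 100 ms ramp
    at task onset in MI-type trials; and multiplies in (1 - gain_k) from
    stimulation onset in stimulated trials.  Per-trial fractions are jittered
    with a mean-one log-normal of sigma ``jitter_sigma``, clipped to [0, 0.98].
    """
    env = np.ones(n)
    n_ramp = max(int(round(ramp * fs)), 1)
    for onset, cond in zip(events["onset_sample"], events["condition"]):
        task0 = onset + int(round(paradigm.prep_dur * fs))
        task1 = task0 + int(round(paradigm.task_dur * fs))
        # draw jitters unconditionally so the random stream does not depend
        # on which effects are enabled
        j_mi, j_ses = np.exp(
            jitter_sigma * rng.standard_normal(2) - 0.5 * jitter_sigma**2
        )
        if cond in _MI_CONDITIONS and erd_mi > 0:
            f = 1.0 - np.clip(erd_mi * j_mi, 0.0, 0.98)
            _apply_drop(env, task0, task1, f, n_ramp)
        if cond in _SES_CONDITIONS:
            g = ses_gain if cond == "MI_SES" else attention_erd
            if g > 0:
                f = 1.0 - np.clip(g * j_ses, 0.0, 0.98)
                ses0 = task0 + int(round(paradigm.ses_onset * fs))
                _apply_drop(env, ses0, task1, f, n_ramp)
    return env


def _apply_drop(env: np.ndarray, start: int, stop: int, factor: float, n_ramp: int) -> None:
    stop = min(stop, env.size)
    start = max(start, 0)
    if start >= stop:
        return
    ramp_end = min(start + n_ramp, stop)
    env[start:ramp_end] *= np.linspace(1.0, factor, ramp_end - start)
    env[ramp_end:stop] *= factor


def _condition_envelope(
    events: pd.DataFrame,
    paradigm: ParadigmSpec,
    fs: float,
    n: int,
    gains: dict[str, float],
    base: float = 0.2,
    ramp: float = 0.1,
) -> np.ndarray:
    """Coupling-strength envelope: ``base`` between trials, the condition's
    gain during each task window."""
    env = np.full(n, base)
    n_ramp = max(int(round(ramp * fs)), 1)
    for onset, cond in zip(events["onset_sample"], events["condition"]):
        task0 = onset + int(round(paradigm.prep_dur * fs))
        task1 = min(task0 + int(round(paradigm.task_dur * fs)), n)
        g = gains.get(cond, base)
        ramp_end = min(task0 + n_ramp, task1)
        env[task0:ramp_end] = np.linspace(base, g, ramp_end - task0)
        env[ramp_end:task1] = g
    return env


def simulate_subject(
    profile: PerformerProfile,
    paradigm: ParadigmSpec | None = None,
    noise: NoiseModel | None = None,
    fs: float = 1000.0,
    montage: tuple[str, ...] | list[str] = DEFAULT_MONTAGE,
    seed: int = 0,
    coupling_pair: tuple[str, str] = ("F3", "P3"),
) -> tuple[ContinuousRecord, pd.DataFrame]:
    """Simulate one subject's continuous EEG and its event table.

    Returns a :class:`ContinuousRecord` (microvolts) and a DataFrame with
    columns ``onset_sample`` (preparation-cue onset) and ``condition``.
    Bit-for-bit reproducible for identical arguments and seed.

    Raises
    ------
    ValueError
        If ``fs`` is not a positive multiple of 250 Hz, or the montage lacks
        the sensorimotor/connectivity channels the analyses address.
    KeyError
        For channel labels outside the standard 10-05 set.
    """
    paradigm = paradigm or ParadigmSpec()
    noise = noise or NoiseModel()
    if fs <= 0 or abs(fs / 250.0 - round(fs / 250.0)) > 1e-9 or round(fs / 250.0) < 1:
        raise ValueError(f"fs must be a positive multiple of 250 Hz, got {fs}")
    montage = tuple(montage)
    required = set(CONNECTIVITY_CHANNELS) | {"C3", "C4", "Cz"}
    missing = sorted(required - set(montage))
    if missing:
        raise ValueError(f"montage must include sensorimotor/connectivity channels; missing {missing}")
    channel_positions(montage)  # raises KeyError on unknown labels

    rng = np.random.default_rng(seed)
    events, n = _build_timeline(paradigm, fs, rng)
    n_ch = len(montage)

    # background: mixed pink sources + white sensor noise
    data = np.zeros((n_ch, n))
    if noise.background_sd > 0:
        sources = _pink_noise(rng, n_ch, n, noise.pink_exponent)
        mix = mixing_matrix(montage, noise.mixing_sigma)
        # normalize so each channel's background has sd == background_sd
        mixed = mix @ sources
        mixed /= mixed.std(axis=1, keepdims=True)
        data += noise.background_sd * mixed
        del sources, mixed
    data += noise.channel_noise_sd * rng.standard_normal((n_ch, n))

    t = np.arange(n) / fs
    proj_c3 = source_projection(montage, "C3")
    proj_c4 = source_projection(montage, "C4")

    env_alpha = _erd_envelope(
        events, paradigm, fs, n, profile.erd_alpha_mi, profile.ses_erd_gain,
        profile.ses_attention_erd, profile.erd_consistency, rng,
    )
    env_beta = _erd_envelope(
        events, paradigm, fs, n, profile.erd_beta_mi, profile.ses_erd_gain,
        profile.ses_attention_erd, profile.erd_consistency, rng,
    )

    for f0, amp, env_task in (
        (noise.osc_freq_alpha, noise.osc_amp_alpha, env_alpha),
        (noise.osc_freq_beta, noise.osc_amp_beta, env_beta),
    ):
        # contralateral (C3) rhythm carries the task modulation; the
        # ipsilateral (C4) rhythm is an unmodulated independent control
        for proj, env in ((proj_c3, env_task), (proj_c4, None)):
            theta = _phase_walk(rng, n, fs, noise.phase_jitter)
            am = _slow_am(rng, n, fs, noise.am_cutoff_hz, noise.am_sigma)
            wave = amp * am * np.sin(2 * np.pi * f0 * t + theta)
            if env is not None:
                wave = wave * env
            data += proj[:, None] * wave[None, :]

    # phase-lagged fronto-parietal coupled pair: constant total power, the
    # phase-coherent fraction of it is condition dependent in task windows
    if profile.coupling_strength > 0:
        f_c = noise.osc_freq_alpha if profile.coupling_band == "alpha" else noise.osc_freq_beta
        phases = [
            2 * np.pi * f_c * t + _phase_walk(rng, n, fs, noise.phase_jitter)
            for _ in range(3)  # shared, src-private, dst-private carriers
        ]
        frac = _condition_envelope(
            events, paradigm, fs, n, profile.coupling_condition_coherence
        )
        a_coh = profile.coupling_strength * np.sqrt(frac)
        a_ind = profile.coupling_strength * np.sqrt(1.0 - frac)
        i_src = montage.index(coupling_pair[0])
        i_dst = montage.index(coupling_pair[1])
        data[i_src] += a_coh * np.sin(phases[0]) + a_ind * np.sin(phases[1])
        data[i_dst] += (
            a_coh * np.sin(phases[0] - profile.coupling_lag)
            + a_ind * np.sin(phases[2])
        )

    record = ContinuousRecord(data=data, fs=fs, channels=list(montage))
    return record, events


def cohort_profiles(
    n_high: int, n_low: int, base_seed: int
) -> list[PerformerProfile]:
    """Draw per-subject profiles around the HIGH/LOW defaults.

    ERD fractions get additive Gaussian jitter (sd 0.05, clipped to [0, 0.9]);
    the stimulation gain of LOW subjects likewise (sd 0.05, clipped >= 0.1).
    """
    if n_high < 0 or n_low < 0:
        raise ValueError("cohort sizes must be >= 0")
    rng = np.random.default_rng(base_seed)
    profiles = []
    for i in range(n_high + n_low):
        base = high_performer_profile() if i < n_high else low_performer_profile()
        jit = rng.normal(0.0, 0.05, size=3)
        kwargs = dict(
            erd_alpha_mi=float(np.clip(base.erd_alpha_mi + jit[0], 0.0, 0.9)),
            erd_beta_mi=float(np.clip(base.erd_beta_mi + jit[1], 0.0, 0.9)),
        )
        if base.ses_erd_gain > 0:
            kwargs["ses_erd_gain"] = float(np.clip(base.ses_erd_gain + jit[2], 0.1, 0.9))
        profiles.append(replace(base, **kwargs))
    return profiles


def simulate_cohort(
    n_high: int,
    n_low: int,
    base_seed: int = 0,
    paradigm: ParadigmSpec | None = None,
    noise: NoiseModel | None = None,
    fs: float = 1000.0,
    montage: tuple[str, ...] | list[str] = DEFAULT_MONTAGE,
):
    """Yield ``(subject_id, profile, record, events)`` for a cohort.

    Per-subject seeds derive deterministically from ``base_seed`` via
    ``numpy.random.SeedSequence`` spawning, so cohorts are reproducible and
    subjects mutually independent.
    """
    profiles = cohort_profiles(n_high, n_low, base_seed)
    seeds = np.random.SeedSequence(base_seed).generate_state(len(profiles)) % (2**31)
    for i, (profile, seed) in enumerate(zip(profiles, seeds)):
        record, events = simulate_subject(
            profile, paradigm, noise, fs=fs, montage=montage, seed=int(seed)
        )
        yield f"S{i + 1:02d}", profile, record, events
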