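"""Shared fixtures: one simulated subject per profile, reused across tests.

Simulation is at 250 Hz (the analysis rate) to keep the suite fast; the
paradigm structure (4 conditions x 40 trials, 1 s preparation + 4 s task)
is the study's.
"""

from __future__ import annotations

import numpy as np
import pytest

from mises.preprocess import EpochsSet, preprocess_analysis, preprocess_decoding
from mises.simulate import (
    NoiseModel,
    ParadigmSpec,
    PerformerProfile,
    low_performer_profile,
    simulate_subject,
)


@pytest.fixture(scope="session")
def low_subject():
    record, events = simulate_subject(low_performer_profile(), fs=250.0, seed=42)
    return record, events


@pytest.fixture(scope="session")
def low_decoding_epochs(low_subject):
    record, events = low_subject
    return preprocess_decoding(record, events)


@pytest.fixture(scope="session")
def low_analysis_epochs(low_subject):
    record, events = low_subject
    return preprocess_analysis(record, events)


@pytest.fixture(scope="session")
def noiseless_erd_subject():
    """An ERD amplitude factor of exactly 0.5 on the alpha rhythm, with the
    stochastic background switched (almost) off: closed-form expectations
    apply (power ratio 0.25, band ERSP 10*log10(0.25) dB)."""
    profile = PerformerProfile(
        erd_alpha_mi=0.5, erd_beta_mi=0.0, erd_consistency=0.0,
        ses_erd_gain=0.0, ses_attention_erd=0.0, coupling_strength=0.0,
    )
    noise = NoiseModel(
        background_sd=0.0, channel_noise_sd=1e-6, am_sigma=0.0, osc_amp_beta=0.0
    )
    return simulate_subject(profile, noise=noise, fs=250.0, seed=7)


def make_epochs(data: np.ndarray, channels, conditions, fs=250.0, t0=-1.0) -> EpochsSet:
    return EpochsSet(
        data=np.asarray(data, dtype=float),
        fs=fs,
        t0=t0,
        channels=list(channels),
        conditions=np.asarray(conditions),
    )
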