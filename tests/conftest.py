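"""Shared fixtures: small montages and simulated sessions kept cheap.

Scheme-level fixtures run at 200 Hz with a 9-channel fronto-central montage;
the [100, 500) ms analysis window and the 50 Hz feature rate are unchanged,
so every pipeline contract is exercised at full fidelity.
"""

import numpy as np
import pytest

from errp import (ErpTemplateParams, VariabilityProfile, make_session_schedule,
                  preprocess_session, synthesize_recording)

SMALL_MONTAGE = ["Fz", "F1", "F2", "FCz", "FC1", "FC2", "Cz", "C1", "C2"]
FS = 200.0


def clean_profile(**overrides) -> VariabilityProfile:
    """No nuisance structure at all; add back what a test needs."""
    base = dict(participant_amp_scale=0.0, day_amp_scale=0.0, latency_jitter_ms=0.0,
                day_latency_shift_ms=0.0, noise_rms_uV=0.0, alpha_rms_uV=0.0,
                artifact_epoch_rate=0.0, bad_channel_rate=0.0)
    base.update(overrides)
    return VariabilityProfile(**base)


@pytest.fixture(scope="session")
def small_montage():
    return list(SMALL_MONTAGE)


@pytest.fixture(scope="session")
def noisy_session():
    """One 100-trial session with background noise but no other nuisances."""
    schedule = make_session_schedule(25, 0.70, seed=2)
    profile = clean_profile(noise_rms_uV=6.0, alpha_rms_uV=1.0)
    return synthesize_recording(schedule, ErpTemplateParams(), profile,
                                SMALL_MONTAGE, FS, seed=5)


@pytest.fixture(scope="session")
def noisy_epochs(noisy_session):
    epochs, _ = preprocess_session(noisy_session, seed=1)
    return epochs


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free session: every epoch is exactly template x spatial weight."""
    schedule = make_session_schedule(5, 0.5, seed=3)
    return synthesize_recording(schedule, ErpTemplateParams(), clean_profile(),
                                SMALL_MONTAGE, FS, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
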