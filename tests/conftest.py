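import numpy as np
import pytest

import preshot as ps

SMALL_CHANNELS = ["Fpz", "Fz", "Cz", "Pz", "C3", "C4", "O1", "O2"]

#: Amplitude gains by performance type used throughout the recovery tests;
#: expected indices are 100·(1 − g²) = 0, +36, +64, −56.25.
TYPE_GAINS = {1: 1.0, 2: 0.8, 3: 0.6, 4: 1.25}


def small_config(**overrides) -> ps.SimulationConfig:
    """Down-scaled session: 256 Hz, 8 channels, 12-s shot spacing."""
    kwargs = dict(
        n_subjects=2,
        n_trials_per_subject=40,
        fs=256.0,
        channel_labels=list(SMALL_CHANNELS),
        isi_mean=12.0,
        isi_jitter=1.0,
        artifact_rate=0.0,
        gains=ps.GainTable.from_type_gains(TYPE_GAINS),
    )
    kwargs.update(overrides)
    return ps.SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def clean_session():
    """Two artifact-free subjects with type-coupled gains (seed 42)."""
    cfg = small_config()
    return cfg, ps.simulate_session(cfg, seed=42)


@pytest.fixture(scope="session")
def recovery_session():
    """One subject, 320 trials: ≥70 retained epochs per quadrant for the
    gain-recovery checks (uniform quadrant mixture)."""
    cfg = small_config(n_subjects=1, n_trials_per_subject=320,
                       quadrant_mix=(0.25, 0.25, 0.25, 0.25),
                       channel_labels=["Fpz", "Cz", "C3", "O2"])
    recs, events, behavior, truth = ps.simulate_session(cfg, seed=7)
    rec = ps.bandpass_broad(recs[0])
    epochs, _ = ps.epoch_extract(rec, events)
    epochs = ps.artifact_detect(epochs)
    return cfg, epochs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
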