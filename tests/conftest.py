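import dataclasses

import numpy as np
import pytest

from striatim.population import build_population
from striatim.session_io import SessionMeta
from striatim.synth import SynthConfig, simulate_session
from striatim.trials import segment_trials


@pytest.fixture(scope="session")
def small_session():
    """A 120-trial session with a compact mixed population (no accel)."""
    meta = SessionMeta(subject_id="fix1")
    cfg0 = SynthConfig(meta=meta, n_trials=120)
    counts = {
        "entry": 2, "exit": 2, "both": 2, "inside_port": 2, "cue": 2,
        "lick": 2, "reward_resp": 2, "noreward_resp": 2,
        "expected_noreward_resp": 2, "nonresponsive": 2,
    }
    specs = build_population(counts, cfg0)
    cfg = dataclasses.replace(cfg0, unit_specs=specs)
    session, truth = simulate_session(cfg, 20250101, with_accel=False)
    return cfg, session, truth


@pytest.fixture(scope="session")
def small_table(small_session):
    _, session, _ = small_session
    return segment_trials(session)


@pytest.fixture(scope="session")
def accel_session():
    """A 150-trial session with an accelerometer trace and no units."""
    meta = SessionMeta(subject_id="fix2", accel_sampling_hz=125.0)
    cfg = SynthConfig(meta=meta, n_trials=150)
    session, truth = simulate_session(cfg, 20250202)
    return cfg, session, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
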