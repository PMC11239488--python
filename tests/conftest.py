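import numpy as np
import pandas as pd
import pytest

from optophys.synth import (
    AgentModel,
    FidelityGenParams,
    PhotomGenParams,
    SessionSpec,
    gen_evoked_spikes,
    gen_photometry_session,
    gen_pulse_train,
    gen_session_log,
)


@pytest.fixture(scope="session")
def train20():
    return gen_pulse_train(20.0, 1.0)


@pytest.fixture(scope="session")
def train50():
    return gen_pulse_train(50.0, 1.0)


@pytest.fixture(scope="session")
def perfect_follower(train20):
    """Deterministic spike trials: one spike 5 ms after every pulse."""
    params = FidelityGenParams(frequency=20.0, p0=1.0, decay=1.0,
                               latency_mean=0.005, latency_sd=0.0,
                               background_rate=0.0, n_trials=3, seed=0)
    return gen_evoked_spikes(train20, params)


@pytest.fixture(scope="session")
def small_session():
    """Small three-event-type photometry session with modest noise."""
    params = PhotomGenParams(
        seed=11, session_length=1500.0, iti_mean=100.0,
        event_counts={"stim_20hz": 4, "stim_50hz": 4, "food": 4},
    )
    return gen_photometry_session(params)


@pytest.fixture(scope="session")
def noise_free_session():
    """Single food transient, no noise or motion: exact-recovery fixture."""
    params = PhotomGenParams(
        seed=5, session_length=800.0, iti_mean=300.0,
        event_counts={"food": 1}, motion_sd=0.0,
        noise_sd_control=0.0, noise_sd_signal=0.0,
    )
    return gen_photometry_session(params)


@pytest.fixture()
def pit_log():
    spec = SessionSpec(phase="pit_test", seed=5)
    agent = AgentModel(
        base_press_rate={"L": 4.0, "R": 4.0},
        cue_press_multiplier={("clicker", "L"): 3.0, ("noise", "R"): 3.0},
        port_entry_rate=2.0,
    )
    return gen_session_log(spec, agent)
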