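import numpy as np
import pytest

from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

import avmod


@pytest.fixture(scope="session")
def small_af_dataset():
    """Small but analyzable mixed-class population (cached per session)."""
    cfg = avmod.SimConfig(n_neurons=6, n_stimuli=4, n_reps=10, seed=11)
    return avmod.simulate_population(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_trial(spike_times, modality="V", movie_duration=1.5, trial_id=0,
               neuron_id="n0", stimulus_id="stim00"):
    return avmod.TrialRecord(
        neuron_id=neuron_id, session_id="s01", trial_id=trial_id,
        stimulus_id=stimulus_id, modality=modality, movie_onset=0.5,
        movie_duration=movie_duration, spike_times=np.asarray(spike_times))
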