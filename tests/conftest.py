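import numpy as np
import pytest

from oscispeech import preprocess, synthgen, tfr
from oscispeech.core import EpochTimeline, biosemi32_montage


@pytest.fixture(scope="session")
def montage():
    return biosemi32_montage()


@pytest.fixture(scope="session")
def timeline():
    return EpochTimeline()


@pytest.fixture(scope="session")
def default_table():
    """Full-design behavior table: 6 subjects x 175 trials x 2 conditions."""
    return synthgen.simulate_behavior(synthgen.SynthParams(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic EEG cohort (2 subjects x 10 trials x 2 conditions)
    shared across preprocessing and time-frequency tests."""
    params = synthgen.SynthParams(n_subjects=2, n_trials_per_condition=10, seed=1234)
    table = synthgen.simulate_behavior(params)
    epochs, truth = synthgen.synthesize_cohort(params, table)
    return params, epochs, truth


@pytest.fixture(scope="session")
def small_cohort_clean(small_cohort):
    params, epochs, truth = small_cohort
    segments = [c for c in truth["blink_components"] if c.any()]
    clean, _ = preprocess.preprocess_epochs(epochs, artifact_segments=segments)
    return params, clean, truth


@pytest.fixture(scope="session")
def small_band_power(small_cohort_clean):
    params, clean, _ = small_cohort_clean
    table, specs = tfr.extract_band_power_table(
        clean, freqs=np.arange(5.0, 33.0), return_spectrograms=True
    )
    return params, table, specs, clean
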