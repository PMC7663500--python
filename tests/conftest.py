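import pytest

from dyndse.cost_models import load_profiles
from dyndse.synthetic_emg import GeneratorParams, generate_participant


@pytest.fixture(scope="session")
def profiles():
    return load_profiles()


@pytest.fixture(scope="session")
def arm(profiles):
    return profiles.microcontrollers["arm_cortex_m3"]


@pytest.fixture(scope="session")
def short_streams():
    """Three half-hour participants with a few eating events each."""
    return [
        generate_participant(GeneratorParams(
            duration=1800.0, n_events=3, event_duration_range=(120.0, 300.0),
            seed=seed))
        for seed in range(3)
    ]
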