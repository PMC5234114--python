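import numpy as np
import pytest
from hypothesis import settings

from osasev import AudioSignal, SyntheticSubjectSpec, synth_subject

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def severe_subject():
    """One synthetic severe-OSA subject (10 min, seed frozen) shared by tests."""
    spec = SyntheticSubjectSpec(target_ahi=30, duration_min=10.0, seed=42)
    signal, intervals, events, ahi = synth_subject(spec)
    return {"signal": signal, "intervals": intervals, "events": events, "ahi": ahi}


@pytest.fixture()
def white_noise_signal():
    rng = np.random.default_rng(7)
    return AudioSignal(0.05 * rng.standard_normal(8000 * 60), 8000)
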