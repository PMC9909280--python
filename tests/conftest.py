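import numpy as np
import pytest
from hypothesis import settings

from lfianet import synthdata as sd

# property tests must behave identically on every machine
settings.register_profile("deterministic", derandomize=True, deadline=None,
                          max_examples=40)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully representative dataset (all four classes)."""
    cfg = sd.SynthConfig(counts=(40, 40, 40, 60), seed=7)
    return sd.generate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_two_peak_trace():
    """Noiseless double-peak trace on a flat zero baseline."""
    specs = [
        sd.PeakSpec(center=120, amplitude=5000, sigma=12, zone="C"),
        sd.PeakSpec(center=350, amplitude=2000, sigma=10, zone="T"),
    ]
    baseline = sd.BaselineSpec()
    values = sd.render_trace(specs, baseline, np.random.default_rng(0))
    return values, specs


@pytest.fixture
def float64_engine():
    """Run the NN engine in float64 for exact gradient checks."""
    from lfianet import _nn

    old = _nn.DTYPE
    _nn.DTYPE = np.float64
    yield
    _nn.DTYPE = old
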