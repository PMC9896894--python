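import numpy as np
import pytest

from paleodecay import AnalyteSeries
from paleodecay.simulate import SimulationSpec, AnalyteSpec, simulate_profile


@pytest.fixture
def exact_power_series():
    """Noiseless Y = 100 * t**-1 at t = 1, 10, 100."""
    t = np.array([1.0, 10.0, 100.0])
    return AnalyteSeries("exact", t, 100.0 / t, "diatom", "DNA")


@pytest.fixture
def noisy_series_factory():
    """Seeded noisy power-law series with configurable parameters."""

    def make(seed, a=100.0, b=-1.5, sigma=0.2, n=20, t_min=1.0, t_max=200.0):
        spec = SimulationSpec(age_grid=list(np.geomspace(t_min, t_max, n)),
                              community=None)
        an = AnalyteSpec("noisy", a, b, sigma)
        return simulate_profile(spec, an, np.random.default_rng(seed))

    return make
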