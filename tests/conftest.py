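import numpy as np
import pytest

from precluster import DLSInstrument
from precluster.fcs import eval_fcs_model
from precluster.synthetic import FcsSimSpec, gen_fcs_curve


@pytest.fixture
def instrument() -> DLSInstrument:
    return DLSInstrument()


def make_two_component_fcs(seed: int, noise_frac: float = 0.01):
    """Two-component FCS curve (0.2 / 2.0 ms, fractions 0.7 / 0.3) with
    noise SD equal to ``noise_frac`` of the local correlation amplitude."""
    base = FcsSimSpec(components=[(0.7, 0.2), (0.3, 2.0)], n_particles=2.0, seed=0)
    clean = eval_fcs_model(base.lag_grid_ms, base.model_params()).values
    lags = base.lag_grid_ms

    def noise(l):
        return noise_frac * np.interp(l, lags, clean)

    spec = FcsSimSpec(
        components=[(0.7, 0.2), (0.3, 2.0)], n_particles=2.0, noise_sd=noise, seed=seed
    )
    return gen_fcs_curve(spec), spec


@pytest.fixture
def two_component_curve():
    return make_two_component_fcs(seed=42)[0]
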