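import numpy as np
import pytest

from nanocascade.kinetics import HillKinetics, MMKinetics, RatePoint, hill_rate, mm_rate

GLUCOSE_GRID = np.array([1.0, 2.5, 5.0, 10.0, 20.0, 30.0])      # mM
H2O2_GRID = np.array([100.0, 200.0, 400.0, 600.0, 1000.0])       # mM


@pytest.fixture
def mm_params():
    return MMKinetics(v_max=10.0, k_m=2.9)


@pytest.fixture
def hill_params():
    return HillKinetics(v_max=5.0, k_half=155.1, hill_h=2.0)


def noisy_rate_points(params, grid, noise_frac, seed):
    """Rate-law samples with relative Gaussian noise, as RatePoints."""
    rng = np.random.default_rng(seed)
    rate = mm_rate if isinstance(params, MMKinetics) else hill_rate
    v = rate(params, grid) * (1.0 + noise_frac * rng.standard_normal(len(grid)))
    return [RatePoint(substrate_conc=s, initial_rate=r) for s, r in zip(grid, v)]
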