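import numpy as np
import pytest

from leaffit.models import CellProfileParams, GrowthParams


@pytest.fixture
def control_params() -> GrowthParams:
    """Group-mean parameters of a wild-type-like maize 4th leaf."""
    return GrowthParams(Lm=535.0, t0=0.0, tm=167.0, te=231.0)


@pytest.fixture
def transgenic_params() -> GrowthParams:
    return GrowthParams(Lm=743.0, t0=0.0, tm=180.0, te=246.0)


@pytest.fixture
def control_profile() -> CellProfileParams:
    """Group-mean cell-profile parameters of the wild-type-like leaf."""
    return CellProfileParams(Lb=10.9, Lm=118.5, Pm=21.3, Pe=43.4)


def random_growth_params(rng: np.random.Generator, fix_t0: bool = True) -> GrowthParams:
    """A random valid parameter set spanning realistic grass leaves."""
    lm = rng.uniform(50, 1500)
    t0 = 0.0 if fix_t0 else rng.uniform(0, 40)
    te = t0 + rng.uniform(100, 400)
    tm = t0 + rng.uniform(0.3, 0.85) * (te - t0)
    return GrowthParams(Lm=lm, t0=t0, tm=tm, te=te)
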