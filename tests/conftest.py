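import numpy as np
import pytest

from standdist.diameter_classes import StandRecord
from standdist.distributions import RDistParams, Weibull3Params, r_cdf, r_quantile

#: canonical suite seed — every fixture and test that needs one uses this.
SEED = 0

#: mid-range R-distribution parameters (scale/location at the empirical means
#: of fitted plantation stands, moderate shape).
MID_R = RDistParams(p=1.26, q=9.40, r=-2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture
def mid_r_params():
    return MID_R


def sample_rdist(params: RDistParams, n: int, rng, floor: float = 1.0) -> np.ndarray:
    """Inverse-CDF sample truncated below the measurement floor."""
    u = rng.uniform(float(r_cdf(floor, params)), 1.0 - 1e-12, size=n)
    return np.asarray(r_quantile(u, params))


def make_stand(diameters, stand_id="S0", age=12.0, planting_density=3333.0,
               stand_density=3100.0, site_index=14.5, mean_height=9.5,
               dominant_height=11.0, thinned=False) -> StandRecord:
    return StandRecord(
        stand_id=stand_id, diameters=np.asarray(diameters, dtype=float),
        age=age, planting_density=planting_density, stand_density=stand_density,
        site_index=site_index, mean_height=mean_height,
        dominant_height=dominant_height, thinned=thinned,
    )


def random_r_params(rng) -> RDistParams:
    """Draw parameters uniformly over the empirical plantation ranges."""
    return RDistParams(
        p=rng.uniform(0.52, 2.57),
        q=rng.uniform(3.39, 18.32),
        r=-rng.uniform(0.30, 6.83),
    )


def random_weibull_params(rng, c_min: float = 0.5) -> Weibull3Params:
    return Weibull3Params(
        a=rng.uniform(0.0, 3.0),
        b=rng.uniform(2.0, 8.0),
        c=rng.uniform(c_min, 6.0),
    )
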