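import numpy as np
import pytest
from shapely.geometry import box

from cosstack import (
    BlockSupport,
    ExposureData,
    GeometryCache,
    KernelParams,
    PointSupport,
    PriorConfig,
    TimeInterval,
)
from cosstack.basis import build_basis, monthly_indicator_spec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_supports():
    """Nine point supports: three sites observed over three months."""
    sites = [(0.2, 0.3), (0.7, 0.6), (0.4, 0.9)]
    return [
        PointSupport(site=s, interval=TimeInterval(float(v), float(v + 1)))
        for s in sites
        for v in range(3)
    ]


@pytest.fixture(scope="session")
def small_blocks():
    """Four square blocks tiling the unit square over one quarter."""
    interval = TimeInterval(0.0, 3.0)
    return [
        BlockSupport(polygon=box(x, y, x + 0.5, y + 0.5), interval=interval)
        for x in (0.0, 0.5)
        for y in (0.0, 0.5)
    ]


@pytest.fixture(scope="session")
def kp():
    return KernelParams(phi1=4.0, nu=0.5, phi2=0.6, delta2=0.5)


@pytest.fixture()
def small_exposure(small_supports, rng):
    spec = monthly_indicator_spec(3)
    basis = build_basis(spec, small_supports)
    x = 5.0 + rng.standard_normal(len(small_supports))
    return ExposureData(supports=small_supports, x=x, basis=basis)


@pytest.fixture()
def default_priors():
    return PriorConfig.default(r=3, p=1)
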