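import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from modfluct.grid import TorusGrid, wrapped_gaussian
from modfluct.kernels import MollifierSpec, RieszSpec, build_kernel_tables

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid32() -> TorusGrid:
    return TorusGrid(L=10.0, n=32, d=3)


@pytest.fixture(scope="session")
def spec() -> RieszSpec:
    return RieszSpec(d=3, lam=0.5)


@pytest.fixture(scope="session")
def tables(spec, grid32):
    """Mollified kernel tables at a representative moderate radius."""
    return build_kernel_tables(spec, MollifierSpec(eta=0.75, d=3), grid32)


@pytest.fixture(scope="session")
def u0_field(grid32):
    return wrapped_gaussian(grid32, 0.0, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
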