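import numpy as np
import pytest

from mepflux import FluxParams, PoolSizes


@pytest.fixture
def pools_1234() -> PoolSizes:
    return PoolSizes(1.0, 2.0, 3.0, 4.0)


@pytest.fixture
def params_j1_m1() -> FluxParams:
    return FluxParams(flux_j=1.0, plateau_m=1.0)


@pytest.fixture
def grid_0_20() -> np.ndarray:
    return np.arange(0.0, 21.0, 1.0)


def random_pool_sets(n: int, seed: int) -> list[tuple[PoolSizes, FluxParams]]:
    """Log-uniform pools in [0.1, 100], J in [0.01, 10], m uniform in (0.2, 1]."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        pools = 10.0 ** rng.uniform(-1, 2, size=4)
        p = PoolSizes(*pools)
        if p.is_degenerate(1e-6):  # keep the closed form well conditioned
            continue
        j = 10.0 ** rng.uniform(-2, 1)
        m = rng.uniform(0.2, 1.0)
        out.append((p, FluxParams(flux_j=j, plateau_m=m)))
    return out
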