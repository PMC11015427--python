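import numpy as np
import pytest

from mitoniche.raster import ClimateStack, GridTransform
from mitoniche.simulate import make_template_genome, simulate_climate_stack


@pytest.fixture(scope="session")
def stack():
    """Shared 100x100, 6-variable synthetic climate stack."""
    return simulate_climate_stack(seed=1)


@pytest.fixture(scope="session")
def template_genome():
    return make_template_genome(seed=3)


@pytest.fixture(scope="session")
def recovery_run(stack):
    """One fitted model-recovery run shared across evaluation tests."""
    from mitoniche.workflow import sdm_recovery

    return sdm_recovery(seed=11, stack=stack)


@pytest.fixture
def tiny_stack():
    """Deterministic 10x10 single-variable-per-band stack for exact checks."""
    rng = np.random.default_rng(0)
    grids = np.stack([
        np.linspace(0, 1, 100).reshape(10, 10),
        rng.normal(size=(10, 10)),
    ])
    mask = np.ones((10, 10), dtype=bool)
    return ClimateStack(["v1", "v2"], grids, GridTransform(0.0, 0.0, 1.0), mask)
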