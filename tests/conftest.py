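import numpy as np
import pytest

from phylospan import SilerParams


@pytest.fixture(scope="session")
def ref_params() -> SilerParams:
    """Reference bathtub parameter set used across tests."""
    return SilerParams(a0=-1.0, a1=1.0, c=0.02, b0=-6.0, b1=0.15)


@pytest.fixture(scope="session")
def constant_hazard_params() -> SilerParams:
    """Near-constant hazard: juvenile and senescent terms suppressed so the
    hazard is c = 0.1 over the relevant age range."""
    return SilerParams(a0=-30.0, a1=1.0, c=0.1, b0=-30.0, b1=0.15)


@pytest.fixture(scope="session")
def param_grid() -> list[SilerParams]:
    """Deterministic grid of valid parameter sets spanning realistic
    juvenile, adult and senescent mortality regimes."""
    rng = np.random.default_rng(20260928)
    grid = []
    for _ in range(100):
        grid.append(SilerParams(
            a0=rng.uniform(-3.0, 1.0),
            a1=rng.uniform(0.3, 3.0),
            c=rng.uniform(0.005, 0.2),
            b0=rng.uniform(-8.0, -3.0),
            b1=rng.uniform(0.05, 0.4),
        ))
    return grid
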