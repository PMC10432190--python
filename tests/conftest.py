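import numpy as np
import pytest

from cardiolyso.model import CellParameters


@pytest.fixture
def params() -> CellParameters:
    return CellParameters()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_physiological_state(rng: np.random.Generator) -> np.ndarray:
    """A random state within physiological ranges (gates in [0,1], conc > 0)."""
    from cardiolyso import model as M

    y = np.empty(M.NSTATE)
    y[M.iV] = rng.uniform(-85.0, 30.0)
    for i in M.GATE_INDICES:
        y[i] = rng.uniform(0.0, 1.0)
    r, o, iry = rng.dirichlet([8.0, 1.0, 1.0])[:3] * rng.uniform(0.5, 1.0)
    y[M.iRYR_R], y[M.iRYR_O], y[M.iRYR_I] = r, o, iry
    y[M.iCJ] = rng.uniform(1e-4, 0.2)
    y[M.iCSL] = rng.uniform(5e-5, 0.01)
    y[M.iCI] = rng.uniform(3e-5, 1e-3)
    y[M.iCSR] = rng.uniform(0.05, 0.6)
    y[M.iCLS] = rng.uniform(1e-4, 0.5)
    return y
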