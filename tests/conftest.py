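import numpy as np
import pytest

from climprior.config import PipelineConfig
from climprior.grid import rasterize_domain
from climprior import pipeline as pl


@pytest.fixture
def domain3x3():
    return rasterize_domain(3, 3, 0.1, (-55.0, -30.0))


@pytest.fixture
def domain5x5():
    return rasterize_domain(5, 5, 0.1, (0.0, 0.0))


def tiny_config(seed: int = 11) -> PipelineConfig:
    """Desk-scale pipeline configuration for fast integration tests."""
    return PipelineConfig.from_dict({
        "seed": seed,
        "grid": {"n_rows": 16, "n_cols": 16},
        "species": {"n_species": 8},
        "enm": {"n_reps": 8},
    })


@pytest.fixture(scope="session")
def tiny_run():
    """One fully-executed in-memory pipeline on the tiny configuration."""
    state = pl.stage_simulate(tiny_config())
    pl.stage_enm(state)
    pl.stage_ensemble(state)
    pl.stage_dispersal(state)
    pl.stage_prioritize(state)
    return state


@pytest.fixture
def rng():
    return np.random.default_rng(123)
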