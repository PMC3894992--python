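import numpy as np
import pytest

from answers.grid import build_grid, build_spatial_prior
from answers.retest import RetestModel
from answers.synthetic import GeneratorConfig, gen_cohort


@pytest.fixture(scope="session")
def grid():
    return build_grid()


@pytest.fixture(scope="session")
def prior(grid):
    return build_spatial_prior(grid)


@pytest.fixture(scope="session")
def retest_model():
    """Packaged retest model, fitted to the default synthetic retest study."""
    import importlib.resources

    ref = importlib.resources.files("answers.data").joinpath(
        "retest_model_synthetic.json"
    )
    return RetestModel.from_json(str(ref))


@pytest.fixture(scope="session")
def small_cohort(grid):
    """Ten series, three progressing, with ground truth."""
    cfg = GeneratorConfig(seed=11, n_eyes=10, frac_progressing=0.3,
                          progression_slope=-1.5, n_tests=7)
    return gen_cohort(cfg, grid)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
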