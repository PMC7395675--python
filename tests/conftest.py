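import warnings

import numpy as np
import pytest

from oct2vf.synthetic_cohort import (
    GeneratorConfig,
    derive_normative_tables,
    simulate_cohort,
)
from oct2vf.vf_geometry import assign_gh_sectors, build_grid_24_2
from oct2vf.workflows import run_structure_function_study


@pytest.fixture(scope="session")
def grid():
    return build_grid_24_2("right")


@pytest.fixture(scope="session")
def sectors(grid):
    return assign_gh_sectors(grid)


@pytest.fixture(scope="session")
def gen_cfg():
    return GeneratorConfig(n_patients=120, seed=7)


@pytest.fixture(scope="session")
def small_cohort(gen_cfg):
    return simulate_cohort(gen_cfg)


@pytest.fixture(scope="session")
def normative_small(small_cohort, gen_cfg):
    healthy = [e for e in small_cohort if not e.is_glaucoma]
    glauc = [e for e in small_cohort if e.is_glaucoma]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return derive_normative_tables(healthy, glauc, gen_cfg)


@pytest.fixture(scope="session")
def study():
    """The full synthetic study at benchmark scale (~5,000 pairs, 30 epochs).

    Session-scoped: trained once and shared by the experiment-level tests.
    """
    return run_structure_function_study(seed=1, n_patients=1500, epochs=30)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
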