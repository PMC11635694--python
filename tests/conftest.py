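import numpy as np
import pytest

from capdyn import synthetic_data as sd


@pytest.fixture(scope="session")
def centroids8():
    return sd.make_centroids(8, 129, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """6 subjects, 3 conditions, 48 striatal voxels — planted study effects."""
    cfg = sd.study_config(n_subjects=6, seed=5, n_striatal_voxels=48)
    cohort, truth = sd.simulate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
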