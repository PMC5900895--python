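"""Shared fixtures: small grids and seeded synthetic cohorts.

The default-resolution cohort and its cross-validated evaluation are
session-scoped because several tests interrogate different properties of
the same study conditions.
"""

import numpy as np
import pytest

from b0shim.evaluation import EvalConfig, loocv_evaluate
from b0shim.grids import VoxelGrid
from b0shim.synthetic import CohortConfig, sample_cohort, template_anatomy

# coarse grid for unit tests: same head, quarter the voxels
SMALL_GRID_KW = dict(shape=(36, 36, 36), voxel_size_mm=4.0)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_subjects=8, seed=11, **SMALL_GRID_KW)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return sample_cohort(small_config)


@pytest.fixture(scope="session")
def small_anatomy(small_config):
    return template_anatomy(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-resolution cohort at the generator's default study conditions."""
    cfg = CohortConfig(n_subjects=20, seed=1)
    return cfg, template_anatomy(cfg), sample_cohort(cfg)


@pytest.fixture(scope="session")
def default_loocv(default_cohort):
    cfg, anatomy, cohort = default_cohort
    return loocv_evaluate(cohort, EvalConfig(seed=2, n_random=100),
                          anatomy=anatomy)


@pytest.fixture
def grid16():
    return VoxelGrid.centered(16, 8.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
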