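"""Shared fixtures: the default head phantom and standard-condition PBPK curves.

Session-scoped because phantom generation and ODE integration are the slow
steps; all consumers treat them as read-only.
"""

import numpy as np
import pytest

from myelinpet import pbpk
from myelinpet.config import RunConfig
from myelinpet.study import cached_head_phantom


@pytest.fixture(scope="session")
def head_phantom():
    return cached_head_phantom((256, 256, 128), 1.1)


@pytest.fixture(scope="session")
def study_agent():
    return pbpk.AgentProperties()


@pytest.fixture(scope="session")
def study_curve(study_agent):
    """Biodistribution at the reference imaging condition: Kd 1e-6 M, 100-fold
    lesion demyelination, logP 4."""
    phys = pbpk.default_physiology(lesion_demyelination_fold=100.0)
    return pbpk.simulate_biodistribution(phys, study_agent)


@pytest.fixture(scope="session")
def small_cfg():
    """Coarse study configuration for fast end-to-end runs."""
    return RunConfig(grid_shape=(128, 128, 64), voxel_size_mm=2.2, n_angles=90)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
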