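import numpy as np
import pytest

from tevgsim.anatomy import AnatomyConfig, generate_aorta
from tevgsim.fixtures import (narrowed_cylinder, small_study_case,
                              straight_cylinder, two_cylinder_assembly)


@pytest.fixture(scope="session")
def cylinder():
    """Straight tube, r = 10 mm, L = 100 mm, fine circumference."""
    return straight_cylinder()


@pytest.fixture(scope="session")
def branched_aorta():
    """Two-branch arched aorta at moderate resolution."""
    cfg = AnatomyConfig(radius_profile=(8.0, 6.0), branch_count=2,
                        n_circumferential=16, n_axial=48)
    return generate_aorta(cfg)


@pytest.fixture(scope="session")
def one_branch_aorta():
    cfg = AnatomyConfig(radius_profile=(8.0, 6.0), branch_count=1,
                        n_circumferential=16, n_axial=48)
    return generate_aorta(cfg)


@pytest.fixture(scope="session")
def gap_assembly():
    """Two-cylinder 2-mm-gap anastomosis fixture."""
    return two_cylinder_assembly()


@pytest.fixture(scope="session")
def study_case():
    """Small branched implantation case shared by pipeline tests."""
    return small_study_case()


@pytest.fixture(scope="session")
def narrowed_tube():
    return narrowed_cylinder()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
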