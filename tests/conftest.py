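import numpy as np
import pytest

from subaxis import CohortConfig, generate_cohort, generate_phantom_mask
from subaxis.synthetic_cohort import PhantomSpec, random_phantom_spec


@pytest.fixture(scope="session")
def curved_phantom():
    """A mildly curved tube phantom with its stored ground truth."""
    return generate_phantom_mask(random_phantom_spec(7))


@pytest.fixture(scope="session")
def straight_tube():
    """Axis-aligned straight tube, 100 mm long, radius 2 mm, 1 mm voxels."""
    spec = PhantomSpec(
        control_points=np.array([[0.0, 0.0, 0.0], [0.0, 100.0, 0.0]]),
        radius_mm=2.0,
    )
    return generate_phantom_mask(spec)


@pytest.fixture(scope="session")
def calibration_cohort():
    """Calibration-mode cohort of n=656, seed 1."""
    return generate_cohort(CohortConfig(mode="calibration", n=656, seed=1))


@pytest.fixture(scope="session")
def study_cohort():
    """Study-like cohort with the reported group sizes (302/183/171)."""
    return generate_cohort(CohortConfig(mode="study_like", seed=3))
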