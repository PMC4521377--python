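import numpy as np
import pytest

from skars.model import SensorModelParams
from skars.synth import CohortSpec, FrameSpec, generate_cohort, render_frames, spec_with


@pytest.fixture(scope="session")
def params() -> SensorModelParams:
    return SensorModelParams()


@pytest.fixture(scope="session")
def small_cohort():
    """20-cell default-noise cohort with fixed seed."""
    spec = spec_with(CohortSpec(), n_cells=20, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def rendered_movie(params):
    """Small rendered movie (10 cells, 5 frames) with default imaging noise."""
    spec = spec_with(CohortSpec(), n_cells=10, seed=5)
    truth = generate_cohort(spec)
    times = np.asarray(spec.times[:5])
    stack = render_frames(truth, FrameSpec(shape=(256, 256)), params, times=times)
    return truth, stack
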