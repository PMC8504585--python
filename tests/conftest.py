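import numpy as np
import pytest

from geldose import (
    CalibrationCurve,
    DoseGrid,
    GridGeometry,
    default_beams,
    default_phantom,
    simulate_box_dose,
)

# Figure-of-merit calibration used throughout: R2 = 2.21 + 0.75 D (s^-1, Gy)
FIG5_INTERCEPT = 2.21
FIG5_SLOPE = 0.75


@pytest.fixture(scope="session")
def gel_curve() -> CalibrationCurve:
    return CalibrationCurve(
        intercept=FIG5_INTERCEPT, slope=FIG5_SLOPE, dose_range=(0.0, 3.0)
    )


@pytest.fixture(scope="session")
def box_dose() -> DoseGrid:
    """Desk-scale four-field box plan, 2 Gy at the isocenter, no implants."""
    return simulate_box_dose(default_phantom(), default_beams(), prescription=2.0)


@pytest.fixture()
def small_geometry() -> GridGeometry:
    return GridGeometry((8, 8, 4), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))


def random_grid_pair(rng: np.random.Generator, shape=(8, 8, 4), spacing=(2.0, 2.0, 2.0)):
    """A normalized reference grid and a mildly perturbed evaluated grid."""
    geom = GridGeometry(shape, spacing, (0.0, 0.0, 0.0))
    base = 0.4 + 0.8 * rng.random(shape)
    pert = np.clip(base * (1.0 + rng.normal(0.0, 0.03, shape)), 0.0, None)
    ref = DoseGrid(geom, base, normalized=True, normalization_value=2.0)
    ev = DoseGrid(geom, pert, normalized=True, normalization_value=2.0)
    return ref, ev
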