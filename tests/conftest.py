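import numpy as np
import pytest

from cardio5d.phantom import (
    MotionModel,
    PhantomSpec,
    Sphere,
    Tube,
    render_phase_grid,
)
from cardio5d.structures import StructureMask


@pytest.fixture
def unit_grid():
    """Factory for small masks on a 1 mm isotropic grid."""

    def make(shape=(20, 20, 20), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
        return StructureMask(np.zeros(shape, dtype=bool), spacing, origin)

    return make


def random_blob(rng, shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0)) -> StructureMask:
    """Random connected-ish blob: thresholded smoothed noise, never empty."""
    from scipy.ndimage import gaussian_filter

    field = gaussian_filter(rng.standard_normal(shape), sigma=rng.uniform(2.0, 4.0))
    thresh = np.quantile(field, rng.uniform(0.85, 0.97))
    data = field >= thresh
    if not data.any():  # pragma: no cover - quantile guarantees non-empty
        data[tuple(np.unravel_index(np.argmax(field), shape))] = True
    return StructureMask(data, spacing)


@pytest.fixture
def blob_factory():
    return random_blob


@pytest.fixture(scope="session")
def small_phase_grid():
    """Two-substructure phantom phase grid on a fast 48^3 desk grid."""
    spec = PhantomSpec(
        substructures={
            "RCA": Tube(points=((55.0, 37.0, 20.0), (55.0, 40.0, 55.0)), radius=4.0),
            "LV": Sphere(center=(28.0, 37.0, 37.0), radius=12.0),
        },
        grid_shape=(48, 48, 48),
        spacing=(1.56, 1.56, 1.56),
    )
    model = MotionModel(
        cardiac_amp=(-5.5, 3.8, -3.6),
        resp_amp=(0.0, 1.0, -4.0),
        hysteresis_mm=4.0,
    )
    grid, truth = render_phase_grid(spec, model)
    return spec, model, grid, truth
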