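import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from limbictex.image_io import ROISample
from limbictex.synthetic import CohortSpec, simulate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*convergence.*")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def make_sample():
    """Factory: ROISample from a 3D intensity array and optional mask."""

    def _make(data, mask=None, voxel_size=(1.0, 1.0, 1.0), name="test-roi"):
        data = np.asarray(data, dtype=float)
        if mask is None:
            mask = np.ones(data.shape, dtype=bool)
        coords = np.argwhere(mask)
        return ROISample(data[mask], coords, name, voxel_size)

    return _make


SMALL_ROIS = (
    "Left-Hippocampus",
    "Right-Hippocampus",
    "Left-Amygdala",
    "Right-Amygdala",
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small in-memory image cohort shared across pipeline tests."""
    spec = CohortSpec(
        n_ect=10, n_med=9, n_hc=12, rois=SMALL_ROIS, grid_shape=(40, 40, 40),
        texture_effect=0.45, seed=77,
    )
    return spec, simulate_cohort(spec)


@pytest.fixture(scope="session")
def cohort_on_disk(tmp_path_factory):
    """The same small cohort written as NIfTI + manifest + registry."""
    out = tmp_path_factory.mktemp("cohort")
    spec = CohortSpec(
        n_ect=8, n_med=7, n_hc=10, rois=SMALL_ROIS, grid_shape=(40, 40, 40),
        texture_effect=0.45, seed=101,
    )
    cohort = simulate_cohort(spec, out_dir=str(out))
    return spec, cohort, out
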