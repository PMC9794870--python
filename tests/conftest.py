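import numpy as np
import pytest

from brainage_bag.synthetic import generate_cohort, make_roi_atlas
from brainage_bag.types import Volume3D


@pytest.fixture(scope="session")
def cohort_and_gt():
    """A small cohort with its generating ground truth (shared, read-only)."""
    return generate_cohort(80, seed=7)


@pytest.fixture(scope="session")
def atlas48():
    return make_roi_atlas(48)


def make_cylinder(radius: float, length: int = 30, grid: int = 48,
                  axis: int = 2, intensity: float = 10.0,
                  spacing=(1.0, 1.0, 1.0)) -> tuple[Volume3D, np.ndarray]:
    """Axis-aligned cylinder phantom: tube of the given in-plane radius
    (voxels) centred in the grid, plus the axis voxel coordinates."""
    data = np.zeros((grid, grid, grid))
    c = grid // 2
    lo, hi = c - length // 2, c + length // 2
    ii = np.arange(grid)
    plane = np.add.outer((ii - c) ** 2, (ii - c) ** 2) <= radius ** 2
    sl = [slice(None)] * 3
    sl[axis] = slice(lo, hi)
    if axis == 2:
        data[:, :, lo:hi] = plane[:, :, None] * intensity
    elif axis == 0:
        data[lo:hi, :, :] = plane[None, :, :] * intensity
    else:
        data[:, lo:hi, :] = plane[:, None, :] * intensity
    axis_coords = np.zeros((hi - lo, 3), dtype=int)
    axis_coords[:, :] = c
    axis_coords[:, axis] = np.arange(lo, hi)
    return Volume3D(data, spacing, "tof-like"), axis_coords
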