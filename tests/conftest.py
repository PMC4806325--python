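"""Shared fixtures: digital geometry factories and small quantized ROIs."""

import numpy as np
import pytest

from radiomics_repro.roi import QuantizedROI
from radiomics_repro.volume_io import SegmentationMask, VoxelGrid

ISO = (0.625, 0.625, 0.625)


def make_ball(radius_mm, spacing=ISO, margin_vox=3, center_offset=(0.0, 0.0, 0.0)):
    """Digital ball mask: voxel centres within radius_mm of the centre."""
    dz, dy, dx = spacing
    nz = int(2 * radius_mm / dz) + 2 * margin_vox + 1
    ny = int(2 * radius_mm / dy) + 2 * margin_vox + 1
    nx = int(2 * radius_mm / dx) + 2 * margin_vox + 1
    z = (np.arange(nz) - (nz - 1) / 2) * dz - center_offset[0]
    y = (np.arange(ny) - (ny - 1) / 2) * dy - center_offset[1]
    x = (np.arange(nx) - (nx - 1) / 2) * dx - center_offset[2]
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij", sparse=True)
    mask = (zz ** 2 + yy ** 2 + xx ** 2 <= radius_mm ** 2).astype(np.uint8)
    return SegmentationMask(mask, spacing)


def grid_like(mask, fill=0.0, data=None):
    if data is None:
        data = np.full(mask.shape, fill, dtype=np.float64)
    return VoxelGrid(data, mask.spacing, mask.origin)


def quantized_from_slices(level_slices, n_levels):
    """Wrap a list of 2D integer level arrays into a QuantizedROI."""
    levels = np.stack([np.asarray(s, dtype=np.int32) for s in level_slices])
    return QuantizedROI(levels=levels, n_levels=n_levels,
                        edges=np.linspace(0, 1, n_levels + 1), spacing=ISO)


@pytest.fixture
def ball_r10():
    return make_ball(10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
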