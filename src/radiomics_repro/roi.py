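"""ROI preparation shared by all feature classes.

Consensus masking (2-of-3 reader vote), representative 2D slice selection,
boundary bands with signed physical distances, and gray-level quantization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .volume_io import SegmentationMask, VoxelGrid


class ROIError(ValueError):
    pass


@dataclass
class QuantizedROI:
    """Equal-width gray-level quantization of the in-mask intensities.

    ``levels`` holds integers 1..G inside the mask and 0 outside; ``edges``
    are the G+1 bin edges in HU spanning the in-mask min-max.
    """

    levels: np.ndarray
    n_levels: int
    edges: np.ndarray
    spacing: Tuple[float, float, float]


def consensus_mask(masks) -> SegmentationMask:
    """2-of-3 majority vote over three reader masks, largest component kept.

    Mirrors consensus segmentation practice: a voxel is tumor iff at least two
    of the three readers marked it; stray agreed voxels disconnected from the
    main tumor are discarded.
    """
    if len(masks) != 3:
        raise ROIError(f"need exactly 3 masks, got {len(masks)}")
    ref = masks[0]
    for m in masks[1:]:
        if m.shape != ref.shape or not np.allclose(m.spacing, ref.spacing):
            raise ROIError("masks differ in shape or spacing")
    votes = sum(m.data.astype(np.int16) for m in masks)
    agreed = (votes >= 2)
    if not agreed.any():
        raise ROIError("empty consensus: no voxel agreed by 2 of 3 readers")
    structure = ndimage.generate_binary_structure(3, 3)
    labels, n = ndimage.label(agreed, structure=structure)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        agreed = labels == counts.argmax()
    return SegmentationMask(agreed.astype(np.uint8), ref.spacing, ref.origin)


def largest_slice(mask: SegmentationMask) -> int:
    """Index of the axial slice with the most in-mask pixels (ties: smallest z)."""
    counts = mask.data.sum(axis=(1, 2))
    if counts.sum() == 0:
        raise ROIError("empty mask")
    return int(counts.argmax())


def signed_distance(mask: SegmentationMask) -> np.ndarray:
    """Signed Euclidean distance (mm) to the mask surface, negative inside.

    The surface is taken midway between adjacent foreground/background voxel
    centres: the voxel-centre distance transform is shifted toward the
    interface by half the smallest spacing step, so first shells on either
    side sit at roughly +/- half a voxel.
    """
    fg = mask.data.astype(bool)
    if not fg.any():
        raise ROIError("empty mask")
    sampling = mask.spacing
    d_in = ndimage.distance_transform_edt(fg, sampling=sampling)
    d_out = ndimage.distance_transform_edt(~fg, sampling=sampling)
    sd = d_out - d_in
    half = 0.5 * min(sampling)
    return sd - half * np.sign(sd)


def boundary_band(mask: SegmentationMask, width_mm: float) -> Tuple[np.ndarray, np.ndarray]:
    """Voxels within ``width_mm`` of the mask surface, with signed distances.

    Returns ``(band, sd)``: a boolean array marking the band and the full
    signed-distance array (mm, negative inside).
    """
    if width_mm <= 0:
        raise ROIError("width must be > 0")
    sd = signed_distance(mask)
    band = np.abs(sd) <= width_mm
    return band, sd


def quantize(grid: VoxelGrid, mask: SegmentationMask, n_levels: int = 64) -> QuantizedROI:
    """Equal-width binning of in-mask HU into ``n_levels`` gray levels.

    Levels span the in-mask min-max; the maximum maps to level G.  A flat ROI
    (zero intensity range) quantizes entirely to level 1.  The level image is
    invariant under positive affine rescaling of the intensities.
    """
    if n_levels < 2:
        raise ROIError("need at least 2 gray levels")
    mask.check_alignment(grid)
    fg = mask.data.astype(bool)
    if not fg.any():
        raise ROIError("empty mask")
    vals = grid.data[fg]
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(grid.shape, dtype=np.int32)
    if vmax > vmin:
        scaled = (grid.data[fg] - vmin) / (vmax - vmin) * n_levels
        levels[fg] = np.clip(np.floor(scaled).astype(np.int32) + 1, 1, n_levels)
    else:
        levels[fg] = 1
    edges = np.linspace(vmin, vmax, n_levels + 1)
    return QuantizedROI(levels=levels, n_levels=n_levels, edges=edges, spacing=grid.spacing)
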