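"""The 89-feature CT radiomics engine (15 feature classes).

:func:`compute_all` evaluates every registered feature for one
(volume, mask) pair; degenerate ROIs yield NaN ("Not Available") with a
logged reason rather than an exception.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Optional

import numpy as np

from ..roi import ROIError, quantize
from ..volume_io import SegmentationMask, VoxelGrid
from .filters import gabor_features, log_features, wavelet_features
from .intensity import (fit_sigmoid, first_order_features, sigmoid_margin_features,
                        sigmoid_model)
from .registry import (FeatureRegistry, FeatureVector, MATRIX_TEXTURE_CLASSES,
                       REGISTRY_VERSION, load_registry)
from .shape import (fractal_dimension, shape_features, shape_index_histogram,
                    size_features)
from .texture import (edge_frequency_features, glcm_features, gtdm_features,
                      laws_features, runlength_features,
                      spatial_correlation_features)

__all__ = [
    "compute_all", "load_registry", "FeatureRegistry", "FeatureVector",
    "REGISTRY_VERSION", "MATRIX_TEXTURE_CLASSES",
    "size_features", "shape_features", "shape_index_histogram",
    "sigmoid_margin_features", "fit_sigmoid", "sigmoid_model",
    "first_order_features", "glcm_features", "gtdm_features",
    "runlength_features", "laws_features", "edge_frequency_features",
    "gabor_features", "wavelet_features", "log_features",
    "fractal_dimension", "spatial_correlation_features",
]

logger = logging.getLogger(__name__)

NA = float("nan")

#: Gray-level count for the matrix texture features (GLCM/GTDM/run length).
DEFAULT_N_LEVELS = 64


def compute_all(grid: VoxelGrid, mask: SegmentationMask,
                registry: Optional[FeatureRegistry] = None,
                n_levels: int = DEFAULT_N_LEVELS,
                sigmoid_band_mm: float = 4.0) -> FeatureVector:
    """Compute the full 89-feature vector for one (volume, mask) pair.

    Deterministic: identical inputs give identical vectors.  Each feature
    class that cannot be evaluated on a degenerate ROI (too few surface
    voxels, too small a bounding box, ...) contributes NaN values with the
    reason recorded on the returned vector.
    """
    registry = registry or load_registry()
    mask.check_alignment(grid)
    if mask.voxel_count == 0:
        raise ROIError("empty mask")

    values: Dict[str, float] = {}
    reasons: Dict[str, str] = {}

    def run(fn, *args, **kwargs) -> Dict[str, float]:
        try:
            return fn(*args, **kwargs)
        except ROIError as exc:
            logger.info("%s unavailable: %s", fn.__name__, exc)
            return {}

    values.update(run(size_features, grid, mask))
    values.update(run(shape_features, grid, mask))
    values.update(run(shape_index_histogram, grid, mask))
    sig = run(sigmoid_margin_features, grid, mask, band_width_mm=sigmoid_band_mm)
    values.update({k: v for k, v in sig.items() if k != "Sigmoid_Baseline"})
    values.update(run(first_order_features, grid, mask))

    try:
        q = quantize(grid, mask, n_levels=n_levels)
    except ROIError:
        q = None
    if q is not None:
        values.update(run(glcm_features, q))
        values.update(run(gtdm_features, q))
        values.update(run(runlength_features, q))

    values.update(run(laws_features, grid, mask))
    values.update(run(edge_frequency_features, grid, mask))
    values.update(run(spatial_correlation_features, grid, mask))
    values.update(run(gabor_features, grid, mask))
    values.update(run(wavelet_features, grid, mask))
    values.update(run(log_features, grid, mask))
    values["FractalDimension_3D"] = fractal_dimension(grid, mask)

    for name in registry.names:
        if name not in values:
            values[name] = NA
        v = values[name]
        if isinstance(v, float) and math.isnan(v):
            reasons.setdefault(name, "degenerate ROI below the operator's minimum size")

    extra = set(values) - set(registry.names)
    for name in extra:
        values.pop(name)

    return FeatureVector(registry=registry, values=values, na_reasons=reasons)
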