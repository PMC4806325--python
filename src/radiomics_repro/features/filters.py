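"""Multi-scale filter features: Gabor energy, Haar wavelet subband energy, LoG."""

from __future__ import annotations

import math
from typing import Dict, Optional, Tuple

import numpy as np
import pywt
from scipy import ndimage
from skimage.filters import gabor_kernel

from ..roi import ROIError, largest_slice
from ..volume_io import SegmentationMask, VoxelGrid

NA = float("nan")


# --------------------------------------------------------------------------
# Gabor energy
# --------------------------------------------------------------------------

GABOR_WAVELENGTH_PX = 4.0
GABOR_SIGMA_PX = 2.0


def _gabor_kernels():
    kernels = {}
    for name, theta in (("Gabor_Energy_0", 0.0), ("Gabor_Energy_90", math.pi / 2)):
        k = gabor_kernel(frequency=1.0 / GABOR_WAVELENGTH_PX, theta=theta,
                         sigma_x=GABOR_SIGMA_PX, sigma_y=GABOR_SIGMA_PX)
        kr = np.real(k)
        kr = kr - kr.mean()  # remove DC leakage so constants map to zero
        kernels[name] = (kr, np.imag(k))
    return kernels


def gabor_features(grid: VoxelGrid, mask: SegmentationMask,
                   min_bbox: int = 13) -> Dict[str, float]:
    """Mean squared Gabor response magnitude over in-mask pixels.

    Quadrature filters at wavelength 4 px, sigma 2 px, orientations 0 and 90
    degrees (0 responds to intensity variation along x).  The real kernel is
    made zero-mean, so a constant image has exactly zero energy.  Slices whose
    in-mask bounding box is below the filter support are skipped.
    """
    mask.check_alignment(grid)
    kernels = _gabor_kernels()
    sums = {n: 0.0 for n in kernels}
    count = 0
    for z in range(mask.shape[0]):
        m2d = mask.data[z].astype(bool)
        if not m2d.any():
            continue
        ys, xs = np.nonzero(m2d)
        if (ys.max() - ys.min() + 1) < min_bbox or (xs.max() - xs.min() + 1) < min_bbox:
            continue
        img = grid.data[z].astype(np.float64)
        count += int(m2d.sum())
        for name, (kr, ki) in kernels.items():
            rr = ndimage.convolve(img, kr, mode="reflect")
            ri = ndimage.convolve(img, ki, mode="reflect")
            mag2 = rr ** 2 + ri ** 2
            sums[name] += float(mag2[m2d].sum())
    if count == 0:
        return {n: NA for n in kernels}
    return {n: sums[n] / count for n in kernels}


# --------------------------------------------------------------------------
# Haar wavelet subband energies
# --------------------------------------------------------------------------

WAVELET_NAMES = tuple(f"Wavelet_L{lv}_{sb}" for lv in (1, 2) for sb in ("LL", "LH", "HL", "HH"))


def _pad_even(arr: np.ndarray, value_arr: Optional[np.ndarray] = None) -> np.ndarray:
    """Pad to even dimensions by edge replication."""
    py = arr.shape[0] % 2
    px = arr.shape[1] % 2
    if py or px:
        arr = np.pad(arr, ((0, py), (0, px)), mode="edge")
    return arr


def wavelet_features(grid: VoxelGrid, mask: SegmentationMask) -> Dict[str, float]:
    """Per-pixel Haar subband energies at decomposition levels 1 and 2.

    Each eligible slice's in-mask bounding box is cropped, out-of-mask pixels
    are filled with the in-mask mean, and a 2-level orthonormal 2D Haar
    transform (periodization mode) is taken.  The feature is the mask-weighted
    mean squared coefficient divided by the subband's pixels-per-coefficient
    (4 at level 1, 16 at level 2), so level-1 energies of a full-mask square
    satisfy Parseval against the image's mean square.  Level-2 features need
    an in-mask bounding box of at least 4x4 pixels.
    """
    mask.check_alignment(grid)
    num = {n: 0.0 for n in WAVELET_NAMES}
    den = {n: 0.0 for n in WAVELET_NAMES}
    for z in range(mask.shape[0]):
        m2d = mask.data[z].astype(bool)
        if m2d.sum() < 2:
            continue
        ys, xs = np.nonzero(m2d)
        sl = (slice(ys.min(), ys.max() + 1), slice(xs.min(), xs.max() + 1))
        crop = grid.data[z][sl].astype(np.float64)
        mcrop = m2d[sl].astype(np.float64)
        if min(crop.shape) < 2:
            continue
        fill = crop[mcrop > 0].mean()
        crop = np.where(mcrop > 0, crop, fill)
        crop = _pad_even(crop)
        mcrop = _pad_even(mcrop)

        cA1, (cH1, cV1, cD1) = pywt.dwt2(crop, "haar", mode="periodization")
        w1 = mcrop.reshape(cA1.shape[0], 2, cA1.shape[1], 2).mean(axis=(1, 3))
        for sb, c in (("LL", cA1), ("LH", cH1), ("HL", cV1), ("HH", cD1)):
            name = f"Wavelet_L1_{sb}"
            num[name] += float((w1 * c ** 2).sum()) / 4.0
            den[name] += float(w1.sum())

        if min(crop.shape) >= 4:
            a1 = _pad_even(cA1)
            w1p = _pad_even(w1)
            cA2, (cH2, cV2, cD2) = pywt.dwt2(a1, "haar", mode="periodization")
            w2 = w1p.reshape(cA2.shape[0], 2, cA2.shape[1], 2).mean(axis=(1, 3))
            for sb, c in (("LL", cA2), ("LH", cH2), ("HL", cV2), ("HH", cD2)):
                name = f"Wavelet_L2_{sb}"
                num[name] += float((w2 * c ** 2).sum()) / 16.0
                den[name] += float(w2.sum())

    out: Dict[str, float] = {}
    for name in WAVELET_NAMES:
        out[name] = num[name] / den[name] if den[name] > 0 else NA
    return out


# --------------------------------------------------------------------------
# Laplacian-of-Gaussian multiscale features
# --------------------------------------------------------------------------

#: Scale index -> in-plane Gaussian sigma (px); linear from 0 (no
#: preprocessing) at s=1 to 2.5 at s=4.
LOG_SIGMAS_PX = {1: 0.0, 2: 2.5 / 3, 3: 5.0 / 3, 4: 2.5}

LOG_N_BINS = 64


def _uniformity(vals: np.ndarray, bin_width: float) -> float:
    """Sum of squared histogram fractions with a fixed bin width."""
    if bin_width <= 0 or vals.max() == vals.min():
        return 1.0
    lo = math.floor(vals.min() / bin_width) * bin_width
    n_bins = int(math.ceil((vals.max() - lo) / bin_width)) + 1
    hist, _ = np.histogram(vals, bins=n_bins, range=(lo, lo + n_bins * bin_width))
    p = hist / hist.sum()
    return float((p ** 2).sum())


def log_features(grid: VoxelGrid, mask: SegmentationMask) -> Dict[str, float]:
    """Mean and histogram uniformity of the multiscale LoG response.

    s = 1 uses the raw intensities (no preprocessing; its Mean equals the
    first-order 3D mean); s = 2..4 apply an in-plane Laplacian-of-Gaussian of
    increasing sigma per axial slice.  Uniformity is the sum of squared
    histogram fractions using a fixed bin width of (raw in-mask range)/64 at
    every scale, so stronger smoothing concentrates the histogram and raises
    uniformity; a constant response gives 1.
    """
    mask.check_alignment(grid)
    fg = mask.data.astype(bool)
    if not fg.any():
        raise ROIError("empty mask")
    raw = grid.data[fg].astype(np.float64)
    bin_width = float(np.ptp(raw)) / LOG_N_BINS

    out: Dict[str, float] = {}
    for s, sigma in LOG_SIGMAS_PX.items():
        if s == 1:
            vals = raw
        else:
            resp = np.empty(grid.shape, dtype=np.float64)
            for z in range(grid.shape[0]):
                resp[z] = ndimage.gaussian_laplace(grid.data[z].astype(np.float64),
                                                   sigma=sigma, mode="nearest")
            vals = resp[fg]
        out[f"LoG_Mean_s{s}"] = float(vals.mean())
        out[f"LoG_Uniformity_s{s}"] = _uniformity(vals, bin_width)
    return out
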