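"""Matrix- and filter-free texture features.

All texture operators work with in-plane (2D) offsets accumulated over axial
slices, because CT voxels are strongly anisotropic at 2.5/5 mm slice
thickness.  Matrix features (GLCM, GTDM, run length) consume a
:class:`~radiomics_repro.roi.QuantizedROI`, which makes them invariant under
positive affine rescaling of the intensities; Laws, edge-frequency and
spatial-correlation features use raw HU.
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage

from ..roi import QuantizedROI
from ..volume_io import SegmentationMask, VoxelGrid

NA = float("nan")
EPS = 1e-12

#: In-plane offsets for 0, 45, 90, 135 degrees at distance 1 (dy, dx).
GLCM_OFFSETS: Tuple[Tuple[int, int], ...] = ((0, 1), (1, 1), (1, 0), (1, -1))


def _log2(p: np.ndarray) -> np.ndarray:
    """log2 with the 0*log(0) = 0 convention."""
    out = np.zeros_like(p, dtype=np.float64)
    nz = p > 0
    out[nz] = np.log2(p[nz])
    return out


def _offset_pairs(arr: np.ndarray, dy: int, dx: int) -> Tuple[np.ndarray, np.ndarray]:
    """Pairs (a, b) with b displaced by (dy, dx) from a; dy >= 0, dx any sign."""
    H, W = arr.shape
    ys = slice(0, H - dy)
    yt = slice(dy, H)
    if dx >= 0:
        xs, xt = slice(0, W - dx), slice(dx, W)
    else:
        xs, xt = slice(-dx, W), slice(0, W + dx)
    return arr[ys, xs], arr[yt, xt]


# --------------------------------------------------------------------------
# GLCM
# --------------------------------------------------------------------------

def glcm_matrix(q: QuantizedROI, min_pixels: int = 16) -> np.ndarray:
    """Symmetric co-occurrence matrix summed over 4 directions and all slices.

    Slices with fewer than ``min_pixels`` in-mask pixels are skipped; the sum
    is normalised once at the end.  Returns a (G, G) probability matrix, or a
    zero matrix if no slice is eligible.
    """
    G = q.n_levels
    counts = np.zeros((G, G), dtype=np.float64)
    for z in range(q.levels.shape[0]):
        L = q.levels[z]
        if int((L > 0).sum()) < min_pixels:
            continue
        for dy, dx in GLCM_OFFSETS:
            a, b = _offset_pairs(L, dy, dx)
            valid = (a > 0) & (b > 0)
            if not valid.any():
                continue
            idx = (a[valid] - 1) * G + (b[valid] - 1)
            binc = np.bincount(idx, minlength=G * G).reshape(G, G)
            counts += binc
            counts += binc.T  # symmetric
    total = counts.sum()
    return counts / total if total > 0 else counts


def glcm_features_from_matrix(P: np.ndarray) -> Dict[str, float]:
    """The 17 Haralick-style features of a normalised symmetric GLCM.

    Logs are base 2; degenerate single-cell matrices give Correlation = 1 and
    IMC1 = 0 by convention.
    """
    if P.sum() == 0:
        return {n: NA for n in GLCM_FEATURE_NAMES}
    G = P.shape[0]
    i = np.arange(1, G + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())

    p_sum = np.bincount((ii + jj).ravel(), weights=P.ravel(), minlength=2 * G + 1)[2:]
    p_diff = np.bincount(np.abs(ii - jj).ravel(), weights=P.ravel(), minlength=G)

    k_sum = np.arange(2, 2 * G + 1)
    k_diff = np.arange(0, G)

    energy = float((P ** 2).sum())
    entropy = float(-(P * _log2(P)).sum())
    contrast = float((P * (ii - jj) ** 2).sum())
    dissimilarity = float((P * np.abs(ii - jj)).sum())
    homogeneity = float((P / (1.0 + (ii - jj) ** 2)).sum())
    autocorr = float((P * ii * jj).sum())
    if var_x > 0 and var_y > 0:
        correlation = float((autocorr - mu_x * mu_y) / math.sqrt(var_x * var_y))
    else:
        correlation = 1.0
    variance = float((P * (ii - mu_x) ** 2).sum())
    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = float(-(p_sum * _log2(p_sum)).sum())
    diff_average = float((k_diff * p_diff).sum())
    diff_variance = float(((k_diff - diff_average) ** 2 * p_diff).sum())
    diff_entropy = float(-(p_diff * _log2(p_diff)).sum())

    hx = float(-(px * _log2(px)).sum())
    hy = float(-(py * _log2(py)).sum())
    pxy = np.outer(px, py)
    hxy = entropy
    hxy1 = float(-(P * _log2(pxy)).sum())
    hxy2 = float(-(pxy * _log2(pxy)).sum())
    denom = max(hx, hy)
    imc1 = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))))

    cluster = ii + jj - mu_x - mu_y
    cluster_shade = float((P * cluster ** 3).sum())
    cluster_prominence = float((P * cluster ** 4).sum())

    return {
        "GLCM_Energy": energy,
        "GLCM_Entropy": entropy,
        "GLCM_Contrast": contrast,
        "GLCM_Dissimilarity": dissimilarity,
        "GLCM_Homogeneity": homogeneity,
        "GLCM_Correlation": correlation,
        "GLCM_Variance": variance,
        "GLCM_SumAverage": sum_average,
        "GLCM_SumVariance": sum_variance,
        "GLCM_SumEntropy": sum_entropy,
        "GLCM_DifferenceVariance": diff_variance,
        "GLCM_DifferenceEntropy": diff_entropy,
        "GLCM_IMC1": imc1,
        "GLCM_IMC2": imc2,
        "GLCM_Autocorrelation": autocorr,
        "GLCM_ClusterShade": cluster_shade,
        "GLCM_ClusterProminence": cluster_prominence,
    }


GLCM_FEATURE_NAMES = (
    "GLCM_Energy", "GLCM_Entropy", "GLCM_Contrast", "GLCM_Dissimilarity",
    "GLCM_Homogeneity", "GLCM_Correlation", "GLCM_Variance", "GLCM_SumAverage",
    "GLCM_SumVariance", "GLCM_SumEntropy", "GLCM_DifferenceVariance",
    "GLCM_DifferenceEntropy", "GLCM_IMC1", "GLCM_IMC2", "GLCM_Autocorrelation",
    "GLCM_ClusterShade", "GLCM_ClusterProminence",
)


def glcm_features(q: QuantizedROI, min_pixels: int = 16) -> Dict[str, float]:
    return glcm_features_from_matrix(glcm_matrix(q, min_pixels=min_pixels))


# --------------------------------------------------------------------------
# GTDM (neighborhood gray-tone difference, Amadasun & King)
# --------------------------------------------------------------------------

GTDM_FEATURE_NAMES = ("GTDM_Coarseness", "GTDM_Contrast", "GTDM_Busyness",
                      "GTDM_Complexity", "GTDM_Strength")


def gtdm_features(q: QuantizedROI) -> Dict[str, float]:
    """Coarseness/Contrast/Busyness/Complexity/Strength from gray-tone differences.

    For every interior pixel (in-plane 3x3 neighborhood fully in mask) the
    absolute difference between its level and the mean of its 8 neighbours is
    accumulated per level, slicewise.  Denominators are guarded with 1e-12;
    a constant ROI caps Coarseness at 1e12.
    """
    G = q.n_levels
    s = np.zeros(G, dtype=np.float64)
    n = np.zeros(G, dtype=np.float64)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    for z in range(q.levels.shape[0]):
        L = q.levels[z].astype(np.float64)
        inmask = L > 0
        if inmask.sum() < 9:
            continue
        interior = ndimage.binary_erosion(inmask, structure=np.ones((3, 3)), border_value=0)
        if not interior.any():
            continue
        neigh_sum = ndimage.convolve(L, kernel, mode="constant", cval=0.0)
        mean_neigh = neigh_sum / 8.0
        diff = np.abs(L - mean_neigh)
        levels = q.levels[z][interior]
        diffs = diff[interior]
        s += np.bincount(levels - 1, weights=diffs, minlength=G)
        n += np.bincount(levels - 1, minlength=G)

    N = n.sum()
    if N == 0:
        return {name: NA for name in GTDM_FEATURE_NAMES}
    p = n / N
    present = p > 0
    i = np.arange(1, G + 1, dtype=np.float64)
    Ngp = int(present.sum())

    coarseness = 1.0 / (EPS + float((p * s).sum()))

    if Ngp > 1:
        pi = p[present]
        ip = i[present]
        si = s[present]
        dif = ip[:, None] - ip[None, :]
        contrast = (float((pi[:, None] * pi[None, :] * dif ** 2).sum())
                    / (Ngp * (Ngp - 1))) * (float(s.sum()) / N)
        busy_den = float(np.abs(ip[:, None] * pi[:, None] - ip[None, :] * pi[None, :]).sum())
        busyness = float((p * s).sum()) / busy_den if busy_den > EPS else 0.0
        ps = pi[:, None] + pi[None, :]
        complexity = float((np.abs(dif) * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
                            / ps).sum()) / N
        strength = float((ps * dif ** 2).sum()) / (EPS + float(s.sum()))
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "GTDM_Coarseness": float(coarseness),
        "GTDM_Contrast": float(contrast),
        "GTDM_Busyness": float(busyness),
        "GTDM_Complexity": float(complexity),
        "GTDM_Strength": float(strength),
    }


# --------------------------------------------------------------------------
# run length
# --------------------------------------------------------------------------

RL_FEATURE_NAMES = ("RL_SRE", "RL_LRE", "RL_GLN", "RL_RLN", "RL_RP",
                    "RL_LGRE", "RL_HGRE", "RL_SRLGE", "RL_SRHGE",
                    "RL_LRLGE", "RL_LRHGE")

RL_DIRECTIONS = ("horizontal", "vertical", "diagonal", "antidiagonal")


def _direction_lines(L: np.ndarray, direction: str) -> List[np.ndarray]:
    if direction == "horizontal":
        return list(L)
    if direction == "vertical":
        return list(L.T)
    if direction == "diagonal":
        return [np.diagonal(L, k) for k in range(-L.shape[0] + 1, L.shape[1])]
    if direction == "antidiagonal":
        F = np.fliplr(L)
        return [np.diagonal(F, k) for k in range(-F.shape[0] + 1, F.shape[1])]
    raise ValueError(direction)


def runlength_matrix(q: QuantizedROI, directions=RL_DIRECTIONS) -> Tuple[np.ndarray, int]:
    """Gray-level run-length matrix summed over slices and directions.

    A run is a maximal collinear sequence of equal nonzero levels; out-of-mask
    pixels break runs.  Returns (R, n_pixel_direction) where R[g-1, l-1]
    counts runs of level g and length l and ``n_pixel_direction`` is the
    in-mask pixel count times the number of directions (the run-percentage
    denominator).
    """
    G = q.n_levels
    max_len = max(q.levels.shape[1], q.levels.shape[2])
    R = np.zeros((G, max_len), dtype=np.float64)
    n_pixels = 0
    for z in range(q.levels.shape[0]):
        L = q.levels[z]
        if not (L > 0).any():
            continue
        n_pixels += int((L > 0).sum())
        for direction in directions:
            lines = _direction_lines(L, direction)
            # concatenate with 0 separators; 0 never forms a run
            flat = np.concatenate([np.concatenate([line, [0]]) for line in lines])
            change = np.flatnonzero(np.diff(flat)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(flat)]])
            vals = flat[starts]
            lens = ends - starts
            keep = vals > 0
            if keep.any():
                np.add.at(R, (vals[keep] - 1, lens[keep] - 1), 1.0)
    return R, n_pixels * len(directions)


def runlength_features(q: QuantizedROI, directions=RL_DIRECTIONS) -> Dict[str, float]:
    """The 11 classic run-length features (Galloway / Chu / Dasarathy set)."""
    R, np_dir = runlength_matrix(q, directions)
    Nr = R.sum()
    if Nr == 0:
        return {n: NA for n in RL_FEATURE_NAMES}
    G, Lmax = R.shape
    g = np.arange(1, G + 1, dtype=np.float64)[:, None]
    l = np.arange(1, Lmax + 1, dtype=np.float64)[None, :]
    return {
        "RL_SRE": float((R / l ** 2).sum() / Nr),
        "RL_LRE": float((R * l ** 2).sum() / Nr),
        "RL_GLN": float((R.sum(axis=1) ** 2).sum() / Nr),
        "RL_RLN": float((R.sum(axis=0) ** 2).sum() / Nr),
        "RL_RP": float(Nr / np_dir),
        "RL_LGRE": float((R / g ** 2).sum() / Nr),
        "RL_HGRE": float((R * g ** 2).sum() / Nr),
        "RL_SRLGE": float((R / (g ** 2 * l ** 2)).sum() / Nr),
        "RL_SRHGE": float((R * g ** 2 / l ** 2).sum() / Nr),
        "RL_LRLGE": float((R * l ** 2 / g ** 2).sum() / Nr),
        "RL_LRHGE": float((R * g ** 2 * l ** 2).sum() / Nr),
    }


# --------------------------------------------------------------------------
# Laws energy
# --------------------------------------------------------------------------

_L5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0])
_E5 = np.array([-1.0, -2.0, 0.0, 2.0, 1.0])
_S5 = np.array([-1.0, 0.0, 2.0, 0.0, -1.0])

LAWS_PAIRS = {
    "Laws_L5E5": [(_L5, _E5), (_E5, _L5)],
    "Laws_L5S5": [(_L5, _S5), (_S5, _L5)],
    "Laws_E5E5": [(_E5, _E5)],
    "Laws_E5S5": [(_E5, _S5), (_S5, _E5)],
    "Laws_S5S5": [(_S5, _S5)],
}


def laws_features(grid: VoxelGrid, mask: SegmentationMask,
                  min_bbox: int = 5) -> Dict[str, float]:
    """Mean absolute Laws filter response over in-mask pixels.

    The five zero-mean separable 5x5 kernels are built from the level (L5),
    edge (E5) and spot (S5) vectors; asymmetric pairs are averaged.  Slices
    whose in-mask bounding box is smaller than 5x5 are skipped; with no
    eligible slice all five features are Not-Available.
    """
    mask.check_alignment(grid)
    sums = {n: 0.0 for n in LAWS_PAIRS}
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
        for name, pairs in LAWS_PAIRS.items():
            resp = np.zeros(img.shape)
            for a, b in pairs:
                kernel = np.outer(a, b)
                resp += np.abs(ndimage.convolve(img, kernel, mode="reflect"))
            sums[name] += float(resp[m2d].sum() / len(pairs))
    if count == 0:
        return {n: NA for n in LAWS_PAIRS}
    return {n: sums[n] / count for n in LAWS_PAIRS}


# --------------------------------------------------------------------------
# edge frequency
# --------------------------------------------------------------------------

EF_DISTANCES = (1, 2, 3)
EF_DIRS = ((0, 1), (0, -1), (1, 0), (-1, 0))


def edge_frequency_features(grid: VoxelGrid, mask: SegmentationMask) -> Dict[str, float]:
    """Mean absolute intensity difference at pixel distances 1-3, plus coarseness.

    EF(d) averages |I(p) - I(p + d*u)| over in-mask pixels, the four in-plane
    axis directions and all slices, restricted to pairs whose both ends are in
    the mask.  Coarseness = 1 / (1 + mean_d EF(d)) equals 1 for a constant ROI
    and decreases with edge content.
    """
    mask.check_alignment(grid)
    sums = {d: 0.0 for d in EF_DISTANCES}
    counts = {d: 0 for d in EF_DISTANCES}
    for z in range(mask.shape[0]):
        m2d = mask.data[z].astype(bool)
        if not m2d.any():
            continue
        img = grid.data[z].astype(np.float64)
        for d in EF_DISTANCES:
            for dy, dx in EF_DIRS:
                a, b = _offset_pairs(img, abs(dy) * d, dx * d if dy >= 0 else -dx * d)
                ma, mb = _offset_pairs(m2d, abs(dy) * d, dx * d if dy >= 0 else -dx * d)
                valid = ma & mb
                if valid.any():
                    sums[d] += float(np.abs(a - b)[valid].sum())
                    counts[d] += int(valid.sum())
    out: Dict[str, float] = {}
    efs = []
    for d in EF_DISTANCES:
        ef = sums[d] / counts[d] if counts[d] > 0 else NA
        out[f"EF_d{d}"] = ef
        efs.append(ef)
    if any(math.isnan(e) for e in efs):
        out["EF_Coarseness"] = NA
    else:
        out["EF_Coarseness"] = float(1.0 / (1.0 + sum(efs) / len(efs)))
    return out


# --------------------------------------------------------------------------
# spatial correlation
# --------------------------------------------------------------------------

def spatial_correlation_features(grid: VoxelGrid, mask: SegmentationMask,
                                 min_pairs: int = 10) -> Dict[str, float]:
    """Lag-1 Pearson autocorrelation of in-mask HU along x and along y.

    Pairs are pooled over all axial slices; a flat ROI is defined as
    perfectly correlated (1.0).  Fewer than ``min_pairs`` valid pairs in a
    direction yields Not-Available.
    """
    mask.check_alignment(grid)
    out = {}
    for name, (dy, dx) in (("AutoCorr_X", (0, 1)), ("AutoCorr_Y", (1, 0))):
        xs_all, ys_all = [], []
        for z in range(mask.shape[0]):
            m2d = mask.data[z].astype(bool)
            if not m2d.any():
                continue
            img = grid.data[z].astype(np.float64)
            a, b = _offset_pairs(img, dy, dx)
            ma, mb = _offset_pairs(m2d, dy, dx)
            valid = ma & mb
            if valid.any():
                xs_all.append(a[valid])
                ys_all.append(b[valid])
        if not xs_all:
            out[name] = NA
            continue
        xv = np.concatenate(xs_all)
        yv = np.concatenate(ys_all)
        if len(xv) < min_pairs:
            out[name] = NA
        elif xv.std() == 0 or yv.std() == 0:
            out[name] = 1.0
        else:
            out[name] = float(np.corrcoef(xv, yv)[0, 1])
    return out
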