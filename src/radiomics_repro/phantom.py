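"""Synthetic CT tumor phantoms and repeat-scan / reconstruction emulation.

The generator produces a lung-like background (about -850 HU) containing a
roughly ellipsoidal soft-tissue tumor (about 0 HU) whose interior is a
stationary Gaussian random field and whose margin can be spiculated by a
low-order spherical-harmonic radial perturbation; an optional vessel runs
adjacent to the tumor.  Repeat acquisition draws an independent small rigid
displacement plus independent Gaussian noise per scan.  Reconstruction
slab-averages the through-plane axis to the target slice thickness and applies
an image-space kernel model in-plane: a Gaussian blur for the smooth
(standard) kernel, unsharp enhancement for the sharp (lung) kernel — the
sharp kernel amplifies both texture detail and noise, the smooth kernel
suppresses both, which is the contrast between reconstruction algorithms the
concordance analysis studies.

Everything is deterministic given the seeds carried in the parameter objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.special import sph_harm_y

from .volume_io import (
    ImagingSetting,
    STUDY_SETTINGS,
    SegmentationMask,
    VoxelGrid,
    write_manifest,
    write_volume,
)

#: High-resolution grid step (mm, isotropic).  1.25/2.5/5 mm slices are exact
#: slabs of 2/4/8 of these voxels.
HIGHRES_SPACING_MM = 0.625

#: In-plane kernel parameters of the image-space reconstruction model.
SMOOTH_SIGMA_MM = 1.0
SHARP_ALPHA = 1.0
SHARP_SIGMA_MM = 1.0


class PhantomError(ValueError):
    """Raised for phantom specifications that cannot be realised."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic tumor volume.

    Defaults emulate a mid-sized solid lung tumor on unenhanced CT: lung
    parenchyma near -850 HU, tumor near 0 HU, internal texture of a few tens
    of HU with a millimetre-scale correlation length.
    """

    tumor_radius_mm: float = 9.0
    texture_sd_hu: float = 40.0
    texture_corr_len_mm: float = 2.5
    spiculation_amp: float = 0.15
    vessel: bool = False
    vessel_radius_mm: float = 1.5
    background_hu: float = -850.0
    tumor_hu: float = 0.0
    noise_sd_hu: float = 20.0
    seed: int = 0
    shape: Tuple[int, int, int] = (72, 80, 80)

    def __post_init__(self) -> None:
        if not (2.0 <= self.tumor_radius_mm <= 30.0):
            raise PhantomError("tumor_radius_mm must be in [2, 30]")
        if not (0.0 <= self.spiculation_amp <= 0.5):
            raise PhantomError("spiculation_amp must be in [0, 0.5]")
        if self.texture_sd_hu < 0 or self.noise_sd_hu < 0:
            raise PhantomError("noise/texture standard deviations must be >= 0")
        if self.texture_corr_len_mm < HIGHRES_SPACING_MM:
            raise PhantomError(
                f"texture_corr_len_mm must be >= voxel size {HIGHRES_SPACING_MM}"
            )
        max_extent = self.tumor_radius_mm * (1.0 + self.spiculation_amp)
        half_fov = min(s * HIGHRES_SPACING_MM / 2 for s in self.shape)
        if max_extent + 2.0 > half_fov:
            raise PhantomError(
                f"tumor (radial extent {max_extent:.1f} mm) exceeds field of view "
                f"(half-extent {half_fov:.1f} mm) with < 2 mm margin"
            )


@dataclass
class AcquisitionParams:
    """Repeat-scan emulation: rigid displacement and acquisition noise.

    ``shift_sd_mm`` is the per-axis standard deviation of the rigid translation
    drawn independently for each scan; the 15-minute repeat interval justifies
    translation-only motion.  ``seed`` fans out per scan index.
    """

    shift_sd_mm: float = 1.0
    noise_sd_hu: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift_sd_mm < 0:
            raise PhantomError("shift_sd_mm must be >= 0")


def _spiculation_field(spec: PhantomSpec, rng: np.random.Generator,
                       theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Band-limited random radial perturbation on the direction sphere.

    Real combinations of spherical harmonics with degrees 2..5, normalised to
    max |f| = 1, give a smooth, controllable margin irregularity.
    """
    f = np.zeros_like(theta)
    for ell in range(2, 6):
        for m in range(0, ell + 1):
            a = rng.normal()
            b = rng.normal()
            y = sph_harm_y(ell, m, theta, phi)
            f += a * y.real + (b * y.imag if m > 0 else 0.0)
    peak = np.max(np.abs(f))
    if peak > 0:
        f /= peak
    return f


def generate_phantom(spec: PhantomSpec) -> Tuple[VoxelGrid, SegmentationMask]:
    """Generate the high-resolution phantom volume and its ground-truth mask.

    The grid is isotropic at :data:`HIGHRES_SPACING_MM`.  With
    ``texture_sd_hu = 0`` every in-mask voxel equals ``tumor_hu`` exactly.
    Deterministic given ``spec.seed``.
    """
    h = HIGHRES_SPACING_MM
    nz, ny, nx = spec.shape
    rng = np.random.default_rng(spec.seed)

    z = (np.arange(nz) - (nz - 1) / 2) * h
    y = (np.arange(ny) - (ny - 1) / 2) * h
    x = (np.arange(nx) - (nx - 1) / 2) * h
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij", sparse=True)
    r = np.sqrt(zz ** 2 + yy ** 2 + xx ** 2)

    if spec.spiculation_amp > 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.arccos(np.clip(np.divide(zz, r, out=np.zeros((nz, ny, nx)),
                                                where=r > 0), -1, 1))
            phi = np.arctan2(yy + 0 * r, xx + 0 * r)
        pert = _spiculation_field(spec, rng, theta, phi)
        radius = spec.tumor_radius_mm * (1.0 + spec.spiculation_amp * pert)
    else:
        radius = spec.tumor_radius_mm

    mask = (r <= radius).astype(np.uint8)
    if mask.sum() == 0:
        raise PhantomError("empty tumor mask; radius too small for the grid")

    data = np.full((nz, ny, nx), spec.background_hu, dtype=np.float64)

    if spec.texture_sd_hu > 0:
        white = rng.standard_normal((nz, ny, nx))
        sigma_vox = spec.texture_corr_len_mm / h
        field_ = ndimage.gaussian_filter(white, sigma_vox, mode="reflect")
        sd = field_.std()
        texture = field_ * (spec.texture_sd_hu / sd) if sd > 0 else 0.0
        data[mask == 1] = spec.tumor_hu + texture[mask == 1]
    else:
        rng.standard_normal((nz, ny, nx))  # keep the stream layout fixed
        data[mask == 1] = spec.tumor_hu

    if spec.vessel:
        # Cylinder parallel to z, tangent to the nominal tumor boundary;
        # soft-tissue density, excluded from the ground-truth mask.
        cx = spec.tumor_radius_mm + 0.5 * spec.vessel_radius_mm
        dist2 = (yy - 0 * h) ** 2 + (xx - cx) ** 2 + 0 * zz
        vessel = (dist2 <= spec.vessel_radius_mm ** 2) & (mask == 0)
        data[vessel] = 50.0

    spacing = (h, h, h)
    return VoxelGrid(data, spacing), SegmentationMask(mask, spacing)


def acquire(highres: VoxelGrid, truth: SegmentationMask,
            params: AcquisitionParams, scan_index: int) -> Tuple[VoxelGrid, SegmentationMask]:
    """Emulate one acquisition: rigid shift then additive Gaussian noise.

    Scans 1 and 2 of the same phantom differ only in the shift draw and the
    noise realisation.  The truth mask is translated identically (linear
    interpolation thresholded at 0.5).
    """
    if scan_index not in (1, 2):
        raise ValueError("scan_index must be 1 or 2")
    truth.check_alignment(highres)
    rng = np.random.default_rng([int(params.seed), int(scan_index)])
    shift_mm = rng.normal(0.0, params.shift_sd_mm, size=3) if params.shift_sd_mm > 0 else np.zeros(3)

    data = highres.data.astype(np.float64, copy=True)
    mask = truth.data
    if np.any(shift_mm != 0.0):
        shift_vox = shift_mm / np.asarray(highres.spacing)
        data = ndimage.shift(data, shift_vox, order=1, mode="nearest")
        mask = (ndimage.shift(mask.astype(np.float64), shift_vox, order=1,
                              mode="constant", cval=0.0) >= 0.5).astype(np.uint8)
    if params.noise_sd_hu > 0:
        data = data + rng.normal(0.0, params.noise_sd_hu, size=data.shape)
    return (VoxelGrid(data, highres.spacing, highres.origin),
            SegmentationMask(mask, highres.spacing, highres.origin))


def reconstruct(scan: VoxelGrid, mask: SegmentationMask,
                setting: ImagingSetting) -> Tuple[VoxelGrid, SegmentationMask]:
    """Reconstruct an acquired scan at an imaging setting.

    The z axis is slab-averaged to the target slice thickness (which must be
    an integer multiple of the source z spacing); the mask is resampled by
    slab majority.  In-plane, the smooth kernel applies a Gaussian blur of
    sigma :data:`SMOOTH_SIGMA_MM`, the sharp kernel unsharp enhancement
    ``img + alpha * (img - blur)``; both preserve constants.
    """
    mask.check_alignment(scan)
    dz, dy, dx = scan.spacing
    ratio = setting.thickness / dz
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise PhantomError(
            f"slice thickness {setting.thickness} mm is not an integer multiple "
            f"of source z spacing {dz} mm"
        )
    nz, ny, nx = scan.shape
    if nz % factor != 0:
        raise PhantomError(f"z dimension {nz} not divisible by slab factor {factor}")

    slabbed = scan.data.reshape(nz // factor, factor, ny, nx).mean(axis=1)
    mask_slab = mask.data.reshape(nz // factor, factor, ny, nx).mean(axis=1)
    out_mask = (mask_slab >= 0.5).astype(np.uint8)

    sigma_px = (SMOOTH_SIGMA_MM if setting.kernel == "smooth" else SHARP_SIGMA_MM) / dy
    blur = ndimage.gaussian_filter(slabbed, sigma=(0.0, sigma_px, sigma_px), mode="nearest")
    if setting.kernel == "smooth":
        out = blur
    else:
        out = slabbed + SHARP_ALPHA * (slabbed - blur)

    spacing = (setting.thickness, dy, dx)
    return VoxelGrid(out, spacing, scan.origin), SegmentationMask(out_mask, spacing, scan.origin)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

@dataclass
class CohortRanges:
    """Per-subject sampling ranges for the synthetic cohort.

    Defaults emulate a same-day repeat CT lung cohort at desk scale: solid
    tumors 10-24 mm in diameter with heterogeneous internal texture, a
    minority abutting a vessel, 20 HU acquisition noise and ~1 mm
    repositioning between repeat scans.
    """

    tumor_radius_mm: Tuple[float, float] = (5.0, 12.0)
    texture_sd_hu: Tuple[float, float] = (20.0, 60.0)
    texture_corr_len_mm: Tuple[float, float] = (1.5, 4.0)
    spiculation_amp: Tuple[float, float] = (0.0, 0.3)
    vessel_probability: float = 0.3
    noise_sd_hu: float = 20.0
    shift_sd_mm: float = 1.0


def sample_spec(ranges: CohortRanges, rng: np.random.Generator, seed: int) -> PhantomSpec:
    """Draw one subject's phantom parameters uniformly within the ranges."""
    return PhantomSpec(
        tumor_radius_mm=float(rng.uniform(*ranges.tumor_radius_mm)),
        texture_sd_hu=float(rng.uniform(*ranges.texture_sd_hu)),
        texture_corr_len_mm=float(rng.uniform(*ranges.texture_corr_len_mm)),
        spiculation_amp=float(rng.uniform(*ranges.spiculation_amp)),
        vessel=bool(rng.uniform() < ranges.vessel_probability),
        noise_sd_hu=ranges.noise_sd_hu,
        seed=seed,
    )


def generate_cohort(n: int, out_dir: Path | str,
                    ranges: Optional[CohortRanges] = None,
                    seed: int = 0,
                    settings: Tuple[ImagingSetting, ...] = STUDY_SETTINGS):
    """Write an ``n``-subject synthetic cohort (2 scans x settings) to disk.

    Produces NRRD volumes/masks, a ``manifest.tsv`` and a JSON sidecar with
    the sampled phantom parameters.  Deterministic given ``seed``.
    Returns the loaded, validated :class:`~radiomics_repro.volume_io.CohortManifest`.
    """
    from .volume_io import load_manifest  # local import to avoid cycle confusion

    if n < 2:
        raise PhantomError("cohort needs n >= 2 subjects")
    ranges = ranges or CohortRanges()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    master = np.random.default_rng(seed)
    rows = []
    sidecar: Dict[str, dict] = {}
    for i in range(n):
        subject = f"S{i + 1:03d}"
        subj_seed = int(master.integers(0, 2 ** 31 - 1))
        acq_seed = int(master.integers(0, 2 ** 31 - 1))
        spec = sample_spec(ranges, master, seed=subj_seed)
        params = AcquisitionParams(shift_sd_mm=ranges.shift_sd_mm,
                                   noise_sd_hu=ranges.noise_sd_hu, seed=acq_seed)
        sidecar[subject] = {"spec": asdict(spec), "acquisition": asdict(params)}

        highres, truth = generate_phantom(spec)
        for scan in (1, 2):
            acquired, moved = acquire(highres, truth, params, scan)
            for setting in settings:
                vol, msk = reconstruct(acquired, moved, setting)
                vol_name = f"{subject}_scan{scan}_{setting.label}.nrrd"
                mask_name = f"{subject}_scan{scan}_{setting.label}_mask.nrrd"
                write_volume(VoxelGrid(vol.data.astype(np.float32), vol.spacing, vol.origin),
                             out_dir / vol_name)
                write_volume(msk, out_dir / mask_name)
                rows.append({
                    "subject_id": subject, "scan": scan, "setting": setting.label,
                    "volume_path": vol_name, "mask_path": mask_name,
                })

    write_manifest(rows, out_dir)
    with open(out_dir / "phantom_params.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return load_manifest(out_dir)
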