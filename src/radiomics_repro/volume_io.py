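"""Volumes, masks and cohort manifests.

All 3D arrays use (z, y, x) axis order with 0-based indices; spacing is stored
per axis in millimetres as (dz, dy, dx).  NRRD and NIfTI-1 are supported through
SimpleITK; spacing metadata is required, never defaulted.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import SimpleITK as sitk

logger = logging.getLogger(__name__)

KERNELS = ("sharp", "smooth")
THICKNESSES = (1.25, 2.5, 5.0)


class VolumeIOError(RuntimeError):
    """Raised for unreadable, malformed or inconsistent image files."""


@dataclass
class VoxelGrid:
    """A 3D scalar image (Hounsfield units) with per-axis spacing in mm.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar intensities, axis order (slice, row, column).
    spacing : tuple of float
        (dz, dy, dx) in mm, each strictly positive.
    origin : tuple of float
        (z, y, x) position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeIOError(
                f"non-3D payload: expected 3 axes, got {self.data.ndim}"
            )
        if min(self.data.shape) < 1:
            raise VolumeIOError("every axis must have dimension >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeIOError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class SegmentationMask:
    """Binary ROI aligned to a :class:`VoxelGrid` (same shape and spacing)."""

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise VolumeIOError(
                f"non-3D payload: expected 3 axes, got {arr.ndim}"
            )
        if arr.dtype != np.uint8 or not np.isin(arr, (0, 1)).all():
            vals = np.unique(arr)
            if not np.isin(vals, (0, 1)).all():
                logger.warning(
                    "mask contains values other than {0,1} (%s); coercing nonzero to 1",
                    vals[:8],
                )
            arr = (arr != 0).astype(np.uint8)
        self.data = arr
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise VolumeIOError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def check_alignment(self, grid: VoxelGrid) -> None:
        if self.data.shape != grid.data.shape:
            raise VolumeIOError(
                f"mask shape {self.data.shape} does not match grid {grid.data.shape}"
            )
        if not np.allclose(self.spacing, grid.spacing):
            raise VolumeIOError(
                f"mask spacing {self.spacing} does not match grid {grid.spacing}"
            )


@dataclass(frozen=True)
class ImagingSetting:
    """A reconstruction setting: slice thickness (mm) and kernel.

    The label convention follows clinical usage for GE reconstructions:
    ``L`` (lung) is the sharp, edge-enhancing kernel and ``S`` (standard)
    the smooth one, e.g. ``"1.25L"``.
    """

    thickness: float
    kernel: str

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}, got {self.kernel!r}")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")

    @property
    def label(self) -> str:
        return f"{self.thickness:g}{'L' if self.kernel == 'sharp' else 'S'}"

    @classmethod
    def from_label(cls, label: str) -> "ImagingSetting":
        label = label.strip()
        if not label or label[-1] not in ("L", "S"):
            raise ValueError(f"setting label must end in L or S, got {label!r}")
        try:
            thickness = float(label[:-1])
        except ValueError as exc:
            raise ValueError(f"bad setting label {label!r}") from exc
        return cls(thickness, "sharp" if label[-1] == "L" else "smooth")


#: The six-setting grid of the study: {1.25, 2.5, 5} mm x {sharp, smooth}.
STUDY_SETTINGS: Tuple[ImagingSetting, ...] = tuple(
    ImagingSetting(t, k) for t in THICKNESSES for k in KERNELS
)


# --------------------------------------------------------------------------
# file I/O
# --------------------------------------------------------------------------

_SUFFIXES = (".nrrd", ".nhdr", ".nii", ".nii.gz")


def _check_format(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUFFIXES):
        raise VolumeIOError(f"unsupported format for {path} (expected NRRD or NIfTI)")


def _nrrd_header_has_spacing(path: Path) -> bool:
    # NRRD headers are plain text up to the first blank line.
    with open(path, "rb") as fh:
        for raw in fh:
            line = raw.decode("ascii", errors="replace").strip().lower()
            if not line:
                break
            if line.startswith(("spacings:", "space directions:")):
                return True
    return False


def read_volume(path: os.PathLike | str) -> VoxelGrid:
    """Read a 3D NRRD or NIfTI volume, preserving intensities and spacing.

    Raises :class:`VolumeIOError` for missing files, unsupported formats,
    non-3D payloads, or absent/non-positive spacing metadata.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"file not found: {path}")
    _check_format(path)
    if path.name.lower().endswith((".nrrd", ".nhdr")) and not _nrrd_header_has_spacing(path):
        raise VolumeIOError(
            f"{path}: NRRD header carries no spacing metadata; refusing to default to 1 mm"
        )
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise VolumeIOError(
            f"{path}: non-3D payload (dimension {img.GetDimension()})"
        )
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = tuple(reversed(img.GetSpacing()))  # sitk is (x, y, z)
    origin = tuple(reversed(img.GetOrigin()))
    if any(s <= 0 for s in spacing):
        raise VolumeIOError(f"{path}: non-positive spacing {spacing}")
    return VoxelGrid(data, spacing, origin)


def write_volume(grid: VoxelGrid | SegmentationMask, path: os.PathLike | str) -> None:
    """Write a grid or mask to NRRD/NIfTI; the stored dtype is the array dtype."""
    path = Path(path)
    _check_format(path)
    if not path.parent.is_dir():
        raise VolumeIOError(f"directory does not exist: {path.parent}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.data))
    img.SetSpacing(tuple(reversed(grid.spacing)))
    img.SetOrigin(tuple(reversed(grid.origin)))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_mask(path: os.PathLike | str) -> SegmentationMask:
    """Read a binary mask; nonzero values are coerced to 1 (with a warning)."""
    grid = read_volume(path)
    return SegmentationMask(grid.data, grid.spacing, grid.origin)


# --------------------------------------------------------------------------
# cohort manifest
# --------------------------------------------------------------------------

MANIFEST_NAME = "manifest.tsv"
MANIFEST_COLUMNS = ["subject_id", "scan", "setting", "volume_path", "mask_path"]


@dataclass
class CohortManifest:
    """Pairing of repeat scans per subject per imaging setting.

    ``entries`` maps (subject_id, scan, setting label) to (volume path,
    tuple of mask paths).  A single mask is used as-is; three masks
    (semicolon-separated in the manifest, one per reader) are combined by
    the 2-of-3 consensus vote.  Every subject must have both scan 1 and
    scan 2 at every listed setting.
    """

    root: Path
    subjects: List[str]
    settings: List[str]
    entries: Dict[Tuple[str, int, str], Tuple[Path, Tuple[Path, ...]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def volume_and_mask(self, subject: str, scan: int, setting: str) -> Tuple[VoxelGrid, SegmentationMask]:
        vol_path, mask_paths = self.entries[(subject, scan, setting)]
        masks = [read_mask(p) for p in mask_paths]
        if len(masks) == 1:
            mask = masks[0]
        elif len(masks) == 3:
            from .roi import consensus_mask  # deferred: roi depends on these types
            mask = consensus_mask(masks)
        else:
            raise VolumeIOError(
                f"{subject}/{scan}/{setting}: expected 1 or 3 masks, got {len(masks)}")
        return read_volume(vol_path), mask


def load_manifest(root: os.PathLike | str) -> CohortManifest:
    """Load and validate ``manifest.tsv`` under ``root``.

    The manifest is a tab-delimited table with columns subject_id, scan (1|2),
    setting (e.g. ``2.5S``), volume_path and mask_path (relative to ``root``).
    A subject missing one scan of any pair, or a missing file, is an error that
    names the (subject, scan, setting) gap.
    """
    root = Path(root)
    manifest_path = root / MANIFEST_NAME
    if not manifest_path.exists():
        raise VolumeIOError(f"no manifest: {manifest_path} does not exist")
    table = pd.read_csv(manifest_path, sep="\t", dtype=str)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing_cols:
        raise VolumeIOError(f"manifest missing columns: {missing_cols}")

    entries: Dict[Tuple[str, int, str], Tuple[Path, Path]] = {}
    for row in table.itertuples(index=False):
        scan = int(row.scan)
        if scan not in (1, 2):
            raise VolumeIOError(f"scan must be 1 or 2, got {row.scan} for {row.subject_id}")
        ImagingSetting.from_label(row.setting)  # validates
        entries[(row.subject_id, scan, row.setting)] = (
            root / row.volume_path,
            tuple(root / p for p in row.mask_path.split(";")),
        )

    subjects = sorted({k[0] for k in entries})
    settings = sorted({k[2] for k in entries}, key=lambda s: (float(s[:-1]), s[-1]))

    gaps = []
    for subj in subjects:
        for setting in settings:
            for scan in (1, 2):
                if (subj, scan, setting) not in entries:
                    gaps.append((subj, scan, setting))
    if gaps:
        raise VolumeIOError(f"manifest pairing incomplete; missing (subject, scan, setting): {gaps}")

    missing_files = [
        (k, p)
        for k, (vol_path, mask_paths) in entries.items()
        for p in (vol_path, *mask_paths)
        if not Path(p).exists()
    ]
    if missing_files:
        detail = ", ".join(f"{k} -> {p}" for k, p in missing_files[:10])
        raise VolumeIOError(f"manifest references missing files: {detail}")

    return CohortManifest(root=root, subjects=subjects, settings=settings, entries=entries)


def write_manifest(manifest_rows: List[dict], root: os.PathLike | str) -> Path:
    """Write manifest rows (dicts with MANIFEST_COLUMNS keys) to root/manifest.tsv."""
    root = Path(root)
    path = root / MANIFEST_NAME
    pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)
    return path
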