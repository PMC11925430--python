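"""Reading, validation, resampling and resolution filtering of CT volumes.

Volumes are scalar 3-D grids in Hounsfield units with physical metadata
(spacing, origin, direction), stored internally with index order (x, y, z).
NIfTI and NRRD files are handled through SimpleITK, so spacing and
orientation always come from the file headers.

The preprocessing contract mirrors a clinical CT pipeline: scans whose
in-plane resolution exceeds 0.5 mm or slice thickness exceeds 1.5 mm are
excluded (boundary inclusive), and retained scans are resampled to a uniform
0.5 x 0.5 x 1.5 mm grid by trilinear interpolation.  The voxel volume used
as a regression covariate downstream is always the ORIGINAL, pre-resampling
one, which :func:`resample_volume` preserves on the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk

DEFAULT_TARGET_SPACING = (0.5, 0.5, 1.5)
MAX_INPLANE_MM = 0.5
MAX_SLICE_MM = 1.5
AIR_HU = -1000.0
_SPACING_TOL = 1e-6

SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".nrrd")


class VolumeIOError(RuntimeError):
    """Unreadable or unsupported volume file."""


class VolumeValidationError(ValueError):
    """Volume metadata violates an invariant (e.g. non-positive spacing)."""


@dataclass
class Volume:
    """A 3-D scalar image in HU with physical-space metadata.

    ``values`` is indexed (x, y, z); ``spacing`` is (in-plane x, in-plane y,
    slice) in mm; ``orientation`` is the 3x3 direction matrix mapping index
    axes to physical axes (identity unless the file says otherwise).
    ``original_voxel_volume_mm3`` carries the acquisition voxel volume
    through resampling.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    original_voxel_volume_mm3: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise VolumeValidationError(
                f"expected a 3-D grid, got ndim={self.values.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise VolumeValidationError(f"non-positive spacing {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise VolumeValidationError("volume contains non-finite values")
        self.origin = tuple(float(o) for o in self.origin)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        if self.original_voxel_volume_mm3 is None:
            self.original_voxel_volume_mm3 = self.voxel_volume_mm3

    @property
    def voxel_volume_mm3(self) -> float:
        """Current-grid voxel volume (product of spacing, mm^3)."""
        return float(self.spacing[0] * self.spacing[1] * self.spacing[2])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return (idx * np.asarray(self.spacing)) @ self.orientation.T + np.asarray(
            self.origin
        )

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return ((pts - np.asarray(self.origin)) @ self.orientation) / np.asarray(
            self.spacing
        )


def _to_sitk(vol: Volume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.T))  # (z, y, x)
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    img.SetDirection(tuple(vol.orientation.ravel()))
    return img


def _from_sitk(img: sitk.Image, original_voxel_volume: float | None = None) -> Volume:
    values = sitk.GetArrayFromImage(img).T  # back to (x, y, z)
    return Volume(
        values=values,
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        orientation=np.asarray(img.GetDirection()).reshape(3, 3),
        original_voxel_volume_mm3=original_voxel_volume,
    )


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD (.nrrd) volume.

    Raises :class:`VolumeIOError` for missing/unsupported files and
    :class:`VolumeValidationError` if the header carries non-positive
    spacing.
    """
    path = Path(path)
    name = path.name.lower()
    if not any(name.endswith(s) for s in SUPPORTED_SUFFIXES):
        raise VolumeIOError(
            f"unsupported volume format for {path.name!r}; "
            f"expected NIfTI (.nii/.nii.gz) or NRRD (.nrrd)"
        )
    if not path.exists():
        raise VolumeIOError(f"volume file not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - corrupt file path
        raise VolumeIOError(f"could not read {path}: {exc}") from exc
    vol = _from_sitk(img)
    return vol


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI or NRRD, inferred from the file suffix."""
    path = Path(path)
    name = path.name.lower()
    if not any(name.endswith(s) for s in SUPPORTED_SUFFIXES):
        raise VolumeIOError(f"unsupported output format for {path.name!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(_to_sitk(vol), str(path))
    return path


def passes_resolution_filter(
    spacing: tuple[float, float, float],
    max_inplane: float = MAX_INPLANE_MM,
    max_slice: float = MAX_SLICE_MM,
) -> bool:
    """True when in-plane spacing <= 0.5 mm and slice thickness <= 1.5 mm.

    The boundary is inclusive: a (0.5, 0.5, 1.5) mm scan is kept.
    """
    sx, sy, sz = spacing
    return (
        max(sx, sy) <= max_inplane + _SPACING_TOL and sz <= max_slice + _SPACING_TOL
    )


def filter_by_resolution(
    vols: list[Volume],
    max_inplane: float = MAX_INPLANE_MM,
    max_slice: float = MAX_SLICE_MM,
) -> tuple[list[Volume], list[Volume]]:
    """Partition volumes into (kept, excluded) by the resolution rule."""
    kept, excluded = [], []
    for vol in vols:
        (kept if passes_resolution_filter(vol.spacing, max_inplane, max_slice) else excluded).append(vol)
    return kept, excluded


def resample_volume(
    vol: Volume,
    target_spacing: tuple[float, float, float] = DEFAULT_TARGET_SPACING,
    fill_hu: float = AIR_HU,
) -> Volume:
    """Resample to ``target_spacing`` with trilinear interpolation.

    The physical extent is preserved to within one voxel; points that fall
    outside the input grid are filled with air (-1000 HU).  The output keeps
    the input's ``original_voxel_volume_mm3`` so the acquisition-resolution
    covariate survives preprocessing.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise VolumeValidationError(f"non-positive target spacing {target_spacing}")
    if min(vol.shape) < 2:
        raise VolumeValidationError(
            f"cannot resample degenerate volume of shape {vol.shape}"
        )
    img = _to_sitk(vol)
    new_size = [
        max(1, int(math.ceil(vol.shape[i] * vol.spacing[i] / target_spacing[i])))
        for i in range(3)
    ]
    res = sitk.Resample(
        img,
        new_size,
        sitk.Transform(),
        sitk.sitkLinear,
        img.GetOrigin(),
        target_spacing,
        img.GetDirection(),
        float(fill_hu),
        sitk.sitkFloat32,
    )
    return _from_sitk(res, original_voxel_volume=vol.original_voxel_volume_mm3)
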