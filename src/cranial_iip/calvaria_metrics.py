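"""Calvaria segmentation, bone labeling and local thickness/density maps.

The quantification pipeline is:

1. :func:`segment_calvaria` — threshold the HU volume, keep the largest
   connected component, close small holes.
2. :func:`label_bones` — assign each bone voxel to one of the five
   calvarial bones (frontal L/R, parietal L/R, occipital) by angular sector
   around the mask centroid, carving out canonical suture bands.
3. :func:`build_location_grid` — a fixed icosphere direction grid centred
   at the calvarial centroid.  Because the grid is identical for every
   subject it provides the cross-subject correspondence for location-wise
   statistics.
4. :func:`compute_local_thickness` / :func:`compute_local_density` — for
   each grid direction, cast a ray from the centroid and measure the chord
   length through the bone mask (mm) and the mean HU along that chord.
5. :func:`summarize_bones` — per-bone and whole-calvaria means, optionally
   side-resolved for unicoronal cases.

All operations are deterministic; ray directions honour the volume's
orientation metadata, so a rigidly rotated scan with a correct direction
matrix yields the same maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import geometry
from .geometry import (
    BONE_LABELS,
    LABEL_NAMES,
    LABEL_SUTURE,
    SutureBand,
    canonical_sutures,
)
from .volume_io import Volume

DEFAULT_HU_THRESHOLD = 150.0
DEFAULT_N_LOCATIONS = 2562


class SegmentationError(RuntimeError):
    """Raised when no bone can be segmented from a volume."""


@dataclass
class CalvariaMask:
    """Binary calvaria mask plus per-voxel bone labels, on a volume's grid."""

    mask: np.ndarray  # bool, (x, y, z)
    bone_labels: np.ndarray  # uint8 codes from .geometry (0 = unlabeled)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    orientation: np.ndarray

    @property
    def centroid(self) -> np.ndarray:
        """Mask centroid in physical coordinates."""
        idx = np.argwhere(self.mask)
        phys = (idx * np.asarray(self.spacing)) @ self.orientation.T + np.asarray(
            self.origin
        )
        return phys.mean(axis=0)

    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class LocationGrid:
    """Standardized per-location surface parameterization.

    The same direction grid is used for every subject; location ``l`` in one
    subject corresponds to location ``l`` in any other.
    """

    directions: np.ndarray  # (N, 3) canonical-frame unit vectors
    labels: np.ndarray  # per-location bone label codes
    centroid: np.ndarray  # physical coordinates of the casting origin

    def __len__(self) -> int:
        return len(self.directions)

    @property
    def azimuth_deg(self) -> np.ndarray:
        return geometry.azimuth_elevation(self.directions)[0]

    @property
    def elevation_deg(self) -> np.ndarray:
        return geometry.azimuth_elevation(self.directions)[1]


@dataclass
class CalvariaMaps:
    """Per-location thickness (mm) and density (HU) with validity flags."""

    thickness: np.ndarray
    density: np.ndarray
    valid: np.ndarray

    def to_frame(self, grid: LocationGrid) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "location_id": np.arange(len(grid)),
                "azimuth_deg": grid.azimuth_deg,
                "elevation_deg": grid.elevation_deg,
                "bone_label": [LABEL_NAMES[int(c)] for c in grid.labels],
                "thickness_mm": self.thickness,
                "density_hu": self.density,
                "valid": self.valid,
            }
        )


def segment_calvaria(
    vol: Volume, hu_threshold: float = DEFAULT_HU_THRESHOLD
) -> CalvariaMask:
    """Threshold + largest connected component + morphological closing.

    Classical stand-in for a learned calvaria segmenter: adequate for
    phantoms, where bone is the only high-HU structure.  Raises
    :class:`SegmentationError` when nothing exceeds the threshold.
    """
    above = vol.values >= hu_threshold
    if not np.any(above):
        raise SegmentationError(f"no bone found above {hu_threshold} HU")
    labels, n = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        above = labels == int(np.argmax(counts))
    closed = ndimage.binary_closing(
        above, structure=ndimage.generate_binary_structure(3, 1)
    )
    mask = above | closed
    return CalvariaMask(
        mask=mask,
        bone_labels=np.zeros(mask.shape, dtype=np.uint8),
        spacing=vol.spacing,
        origin=vol.origin,
        orientation=np.asarray(vol.orientation),
    )


def label_bones(
    cmask: CalvariaMask,
    suture_bands: list[SutureBand] | None = None,
) -> CalvariaMask:
    """Assign every mask voxel a bone label by angular sector.

    Sectors are taken around the mask centroid in the canonical frame (the
    volume's orientation maps index axes to canonical axes).  Voxels inside
    a suture band get the ``suture`` label and are excluded from bone
    summaries downstream.
    """
    if not np.any(cmask.mask):
        raise SegmentationError("cannot label an empty mask")
    if suture_bands is None:
        suture_bands = canonical_sutures()
    idx = np.argwhere(cmask.mask)
    phys = (idx * np.asarray(cmask.spacing)) @ cmask.orientation.T + np.asarray(
        cmask.origin
    )
    centroid = phys.mean(axis=0)
    rel = phys - centroid
    radii = np.linalg.norm(rel, axis=1)
    dirs = rel / np.maximum(radii[:, None], 1e-9)
    labels = geometry.label_directions(
        dirs, suture_bands, radius_mm=float(radii.mean())
    )
    out = np.zeros(cmask.mask.shape, dtype=np.uint8)
    out[tuple(idx.T)] = labels
    return CalvariaMask(
        mask=cmask.mask,
        bone_labels=out,
        spacing=cmask.spacing,
        origin=cmask.origin,
        orientation=cmask.orientation,
    )


def _ray_samples(
    cmask: CalvariaMask, grid_dirs: np.ndarray, step_mm: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Sample voxel indices along rays from the centroid.

    Returns (flat linear indices (N, S), inside-grid flags (N, S), radii
    (S,), step).  Directions are canonical-frame; the volume orientation is
    applied when converting to index space.
    """
    centroid = cmask.centroid
    shape = np.asarray(cmask.mask.shape)
    spacing = np.asarray(cmask.spacing)
    corners_idx = np.array(
        [[i, j, k] for i in (0, shape[0] - 1) for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)],
        dtype=float,
    )
    corners = (corners_idx * spacing) @ cmask.orientation.T + np.asarray(cmask.origin)
    r_max = float(np.linalg.norm(corners - centroid, axis=1).max()) + step_mm
    radii = np.arange(step_mm, r_max, step_mm)
    # physical points: centroid + r * dir  -> index space
    pts = centroid[None, None, :] + radii[None, :, None] * grid_dirs[:, None, :]
    rel = (pts - np.asarray(cmask.origin)) @ cmask.orientation
    ijk = np.rint(rel / spacing).astype(np.int64)
    inside = np.all((ijk >= 0) & (ijk < shape), axis=-1)
    ijk_c = np.clip(ijk, 0, shape - 1)
    lin = np.ravel_multi_index(
        (ijk_c[..., 0], ijk_c[..., 1], ijk_c[..., 2]), cmask.mask.shape
    )
    return lin, inside, radii, step_mm


def build_location_grid(
    cmask: CalvariaMask, n_locations: int = DEFAULT_N_LOCATIONS
) -> LocationGrid:
    """Icosphere direction grid centred at the calvarial centroid.

    The per-location bone label is the label of the first labeled voxel the
    ray meets walking outward from the centroid (the inner bone surface).
    """
    dirs = geometry.icosphere_directions(n_locations)
    step = float(min(cmask.spacing)) / 2.0
    lin, inside, _, _ = _ray_samples(cmask, dirs, step)
    lab = cmask.bone_labels.ravel()[lin]
    lab[~inside] = 0
    hit = lab > 0
    first = np.argmax(hit, axis=1)
    any_hit = hit.any(axis=1)
    labels = np.where(any_hit, lab[np.arange(len(dirs)), first], 0).astype(np.uint8)
    return LocationGrid(directions=dirs, labels=labels, centroid=cmask.centroid)


def compute_local_thickness(
    cmask: CalvariaMask, grid: LocationGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Chord-length thickness (mm) per location.

    Thickness at location ``l`` is the outer minus the inner crossing radius
    of the centroid ray with the bone mask.  Locations whose ray misses the
    mask are flagged invalid (thickness NaN).
    """
    step = float(min(cmask.spacing)) / 2.0
    lin, inside, radii, _ = _ray_samples(cmask, grid.directions, step)
    hit = cmask.mask.ravel()[lin] & inside
    any_hit = hit.any(axis=1)
    first = np.argmax(hit, axis=1)
    last = hit.shape[1] - 1 - np.argmax(hit[:, ::-1], axis=1)
    thickness = np.where(any_hit, (last - first + 1) * step, np.nan)
    return thickness, any_hit


def compute_local_density(
    vol: Volume, cmask: CalvariaMask, grid: LocationGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Mean HU over the bone-mask voxels along each location's ray chord."""
    step = float(min(cmask.spacing)) / 2.0
    lin, inside, _, _ = _ray_samples(cmask, grid.directions, step)
    hit = cmask.mask.ravel()[lin] & inside
    any_hit = hit.any(axis=1)
    vals = vol.values.ravel()[lin]
    sums = np.where(hit, vals, 0.0).sum(axis=1)
    counts = hit.sum(axis=1)
    density = np.where(any_hit, sums / np.maximum(counts, 1), np.nan)
    return density, any_hit


def compute_maps(vol: Volume, cmask: CalvariaMask, grid: LocationGrid) -> CalvariaMaps:
    """Thickness and density maps with a joint validity flag."""
    thickness, v1 = compute_local_thickness(cmask, grid)
    density, v2 = compute_local_density(vol, cmask, grid)
    valid = v1 & v2
    return CalvariaMaps(thickness=thickness, density=density, valid=valid)


#: merged bones reported in the standard summaries
_MERGED = {
    "frontal": ("frontal_L", "frontal_R"),
    "parietal": ("parietal_L", "parietal_R"),
    "occipital": ("occipital",),
}


def summarize_bones(
    maps: CalvariaMaps,
    grid: LocationGrid,
    ucc_fused_side: str | None = None,
) -> pd.DataFrame:
    """Per-bone and global means of thickness and density.

    Left and right are merged for the frontal and parietal bones; when
    ``ucc_fused_side`` ('left'/'right') is given, frontal and parietal means
    are additionally reported per fused/open side.  Suture locations are
    excluded everywhere; the global row averages all valid bone-labeled
    locations.  Regions with no valid locations yield NaN.
    """
    if len(maps.thickness) != len(grid):
        raise ValueError("maps and grid have different location counts")
    codes = grid.labels
    valid = maps.valid & np.isin(codes, BONE_LABELS)

    regions: dict[str, np.ndarray] = {}
    for name, parts in _MERGED.items():
        part_codes = [geometry.LABEL_CODES[p] for p in parts]
        regions[name] = valid & np.isin(codes, part_codes)
    regions["global"] = valid
    if ucc_fused_side is not None:
        if ucc_fused_side not in ("left", "right"):
            raise ValueError(f"ucc_fused_side must be 'left'/'right', got {ucc_fused_side!r}")
        fused, opened = ("L", "R") if ucc_fused_side == "left" else ("R", "L")
        for bone in ("frontal", "parietal"):
            regions[f"{bone}_fused_side"] = valid & (
                codes == geometry.LABEL_CODES[f"{bone}_{fused}"]
            )
            regions[f"{bone}_open_side"] = valid & (
                codes == geometry.LABEL_CODES[f"{bone}_{opened}"]
            )

    rows = []
    for name, sel in regions.items():
        n = int(sel.sum())
        rows.append(
            {
                "region": name,
                "n_locations": n,
                "thickness_mm": float(np.mean(maps.thickness[sel])) if n else np.nan,
                "density_hu": float(np.mean(maps.density[sel])) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def quantify_volume(
    vol: Volume,
    hu_threshold: float = DEFAULT_HU_THRESHOLD,
    n_locations: int = DEFAULT_N_LOCATIONS,
    suture_bands: list[SutureBand] | None = None,
    ucc_fused_side: str | None = None,
) -> tuple[CalvariaMaps, LocationGrid, pd.DataFrame]:
    """Full quantification of one volume: maps, grid and bone summaries."""
    cmask = segment_calvaria(vol, hu_threshold)
    cmask = label_bones(cmask, suture_bands)
    grid = build_location_grid(cmask, n_locations)
    maps = compute_maps(vol, cmask, grid)
    summary = summarize_bones(maps, grid, ucc_fused_side=ucc_fused_side)
    return maps, grid, summary


def write_maps(maps: CalvariaMaps, grid: LocationGrid, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    maps.to_frame(grid).to_csv(path, index=False)
    return path
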