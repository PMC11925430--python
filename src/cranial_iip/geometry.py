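"""Canonical calvarial frame, bone sectors and suture bands.

The package works in a canonical anatomical frame centred at the calvarial
centroid: +x anterior, +y left, +z superior.  Surface locations are unit
directions from the centroid, described by azimuth (degrees from anterior,
positive toward the left) and elevation (degrees above the axial plane).

The five calvarial bones are assigned by azimuthal sector:

* ``|azimuth| <= 55``   -> frontal (left / right by sign of y)
* ``55 < |azimuth| <= 125`` -> parietal (left / right)
* ``|azimuth| > 125``   -> occipital (single bone)

Sutures are modelled as great-circle bands of configurable width: a coronal
pair at the frontal/parietal boundaries, a lambdoid pair at the
parietal/occipital boundaries and a midline sagittal band.  Locations inside
a band are labelled ``suture`` and excluded from per-bone statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

# integer label codes used in label volumes and location grids
LABEL_NONE = 0
LABEL_FRONTAL_L = 1
LABEL_FRONTAL_R = 2
LABEL_PARIETAL_L = 3
LABEL_PARIETAL_R = 4
LABEL_OCCIPITAL = 5
LABEL_SUTURE = 6

LABEL_NAMES = {
    LABEL_NONE: "none",
    LABEL_FRONTAL_L: "frontal_L",
    LABEL_FRONTAL_R: "frontal_R",
    LABEL_PARIETAL_L: "parietal_L",
    LABEL_PARIETAL_R: "parietal_R",
    LABEL_OCCIPITAL: "occipital",
    LABEL_SUTURE: "suture",
}
LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}
BONE_LABELS = (
    LABEL_FRONTAL_L,
    LABEL_FRONTAL_R,
    LABEL_PARIETAL_L,
    LABEL_PARIETAL_R,
    LABEL_OCCIPITAL,
)

CORONAL_AZ_DEG = 55.0
LAMBDOID_AZ_DEG = 125.0


def azimuth_elevation(dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Azimuth/elevation (degrees) of unit directions, canonical frame."""
    dirs = np.asarray(dirs, dtype=float)
    az = np.degrees(np.arctan2(dirs[..., 1], dirs[..., 0]))
    el = np.degrees(np.arcsin(np.clip(dirs[..., 2], -1.0, 1.0)))
    return az, el


def directions_from_angles(az_deg: np.ndarray, el_deg: np.ndarray) -> np.ndarray:
    az = np.radians(np.asarray(az_deg, dtype=float))
    el = np.radians(np.asarray(el_deg, dtype=float))
    return np.stack(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)], axis=-1
    )


def sector_labels(dirs: np.ndarray) -> np.ndarray:
    """Bone label of each direction by azimuthal sector (no sutures)."""
    az, _ = azimuth_elevation(dirs)
    a = np.abs(az)
    left = np.asarray(dirs)[..., 1] > 0
    out = np.full(az.shape, LABEL_OCCIPITAL, dtype=np.uint8)
    frontal = a <= CORONAL_AZ_DEG
    parietal = (a > CORONAL_AZ_DEG) & (a <= LAMBDOID_AZ_DEG)
    out[frontal] = np.where(left[frontal], LABEL_FRONTAL_L, LABEL_FRONTAL_R)
    out[parietal] = np.where(left[parietal], LABEL_PARIETAL_L, LABEL_PARIETAL_R)
    return out


@dataclass(frozen=True)
class SutureBand:
    """A great-circle band on the calvarial surface.

    ``normal`` is the unit normal of the band's great-circle plane; a
    direction u lies in the band when the angular distance from the plane,
    ``arcsin(|u . normal|)``, is below the half-width angle implied by
    ``width_mm`` at the working surface radius.  ``restrict`` optionally
    confines the band to the half-space ``u . restrict > 0`` so the two
    coronal (and lambdoid) bands stay on their own side.
    """

    name: str
    normal: tuple[float, float, float]
    width_mm: float
    gap_hu: float = 60.0
    restrict: tuple[float, float, float] | None = None

    def contains(self, dirs: np.ndarray, radius_mm: float) -> np.ndarray:
        dirs = np.asarray(dirs, dtype=float)
        half_angle = 0.5 * self.width_mm / max(radius_mm, 1e-9)
        n = np.asarray(self.normal, dtype=float)
        n = n / np.linalg.norm(n)
        inband = np.abs(dirs @ n) < np.sin(min(half_angle, np.pi / 2))
        if self.restrict is not None:
            inband &= dirs @ np.asarray(self.restrict, dtype=float) > 0
        return inband


def _meridian_band(name: str, az_deg: float, width_mm: float, gap_hu: float) -> SutureBand:
    az = np.radians(az_deg)
    return SutureBand(
        name=name,
        normal=(-np.sin(az), np.cos(az), 0.0),
        width_mm=width_mm,
        gap_hu=gap_hu,
        restrict=(np.cos(az), np.sin(az), 0.0),
    )


def canonical_sutures(width_mm: float = 2.0, gap_hu: float = 60.0) -> list[SutureBand]:
    """The canonical suture layout: coronal pair, lambdoid pair, sagittal.

    Widths are in mm on the outer surface; the gap tissue HU defaults to a
    fibrous soft-tissue value well below any bone threshold.
    """
    bands = [
        _meridian_band("coronal_L", CORONAL_AZ_DEG, width_mm, gap_hu),
        _meridian_band("coronal_R", -CORONAL_AZ_DEG, width_mm, gap_hu),
        _meridian_band("lambdoid_L", LAMBDOID_AZ_DEG, width_mm, gap_hu),
        _meridian_band("lambdoid_R", -LAMBDOID_AZ_DEG, width_mm, gap_hu),
        # the midline band (metopic + sagittal) does not cross the occiput
        SutureBand(
            name="sagittal",
            normal=(0.0, 1.0, 0.0),
            width_mm=width_mm,
            gap_hu=gap_hu,
            restrict=(1.0, 0.0, 0.0),
        ),
    ]
    return bands


def suture_mask(
    dirs: np.ndarray, bands: list[SutureBand], radius_mm: float
) -> np.ndarray:
    """Boolean mask of directions falling inside any suture band."""
    dirs = np.asarray(dirs, dtype=float)
    out = np.zeros(dirs.shape[:-1], dtype=bool)
    for band in bands:
        out |= band.contains(dirs, radius_mm)
    return out


def label_directions(
    dirs: np.ndarray,
    bands: list[SutureBand] | None = None,
    radius_mm: float = 70.0,
) -> np.ndarray:
    """Sector labels with suture-band override."""
    labels = sector_labels(dirs)
    if bands:
        labels = labels.copy()
        labels[suture_mask(dirs, bands, radius_mm)] = LABEL_SUTURE
    return labels


_ICOSPHERE_COUNTS = {12: 0, 42: 1, 162: 2, 642: 3, 2562: 4, 10242: 5}


def icosphere_directions(n_locations: int = 2562) -> np.ndarray:
    """Deterministic unit-direction grid from an icosphere subdivision.

    Supported counts are the icosphere vertex counts 12, 42, 162, 642, 2562
    (default, subdivision level 4) and 10242.
    """
    try:
        level = _ICOSPHERE_COUNTS[int(n_locations)]
    except KeyError:
        raise ValueError(
            f"n_locations must be an icosphere vertex count "
            f"{sorted(_ICOSPHERE_COUNTS)}, got {n_locations}"
        ) from None
    verts = np.asarray(trimesh.creation.icosphere(subdivisions=level).vertices)
    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    # sort lexicographically so the grid is independent of mesh library internals
    order = np.lexsort((verts[:, 2], verts[:, 1], verts[:, 0]))
    return verts[order]
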