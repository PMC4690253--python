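"""AHA 16-segment segmentation of short-axis myocardium.

Converts endocardial/epicardial contours plus a right-ventricular (RV)
insertion reference angle into per-pixel segment labels (1-16, 0 outside
the myocardium), and pools the labelled pixels of a T2 map into a
per-segment table of mean T2 and pixel-SD.

Conventions
-----------
* world coordinates are mm, with the image centre at (0, 0); the centre of
  pixel ``(i, j)`` is ``((i-(nx-1)/2)*dx, (j-(ny-1)/2)*dx)``;
* sector angles are measured from the anterior RV-insertion ray,
  counterclockwise by default (``clockwise=True`` flips chirality for
  mirrored image orientations);
* basal and mid levels are split into six 60-degree sectors
  (anterior, anteroseptal, inferoseptal, inferior, inferolateral,
  anterolateral), the apical level into four 90-degree sectors;
* segment ids: basal 1-6, mid 7-12, apical 13-16;
* the two slices sharing a level are pooled before statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

__all__ = [
    "ImageGrid",
    "SliceContour",
    "ContourSet",
    "build_segment_masks",
    "segment_statistics",
    "sector_segment_ids",
    "segment_level",
    "LEVELS",
]

LEVELS = ("basal", "mid", "apical")

#: (first segment id, number of sectors) per level
_LEVEL_SECTORS = {"basal": (1, 6), "mid": (7, 6), "apical": (13, 4)}


def segment_level(segment_id: int) -> str:
    """Level ('basal' | 'mid' | 'apical') of an AHA segment id 1-16."""
    if 1 <= segment_id <= 6:
        return "basal"
    if 7 <= segment_id <= 12:
        return "mid"
    if 13 <= segment_id <= 16:
        return "apical"
    raise ValueError(f"segment id out of range: {segment_id}")


def slice_level(slice_index: int, n_slices: int) -> str:
    """Map a slice index (0 = most basal) onto basal/mid/apical thirds."""
    if not 0 <= slice_index < n_slices:
        raise ValueError("slice index out of range")
    return LEVELS[min(2, slice_index * 3 // n_slices)]


def sector_segment_ids(rel_angle_deg, level: str, clockwise: bool = False):
    """Segment ids for angles measured from the RV-insertion ray.

    ``rel_angle_deg`` is the (counterclockwise) angle of each pixel from the
    reference ray; the sector index increases counterclockwise so that the
    first sector after the ray is anterior, the next anteroseptal, and so on.
    """
    if level not in _LEVEL_SECTORS:
        raise ValueError(f"unknown level: {level!r}")
    base, n_sec = _LEVEL_SECTORS[level]
    a = np.mod(-np.asarray(rel_angle_deg, float) if clockwise else np.asarray(rel_angle_deg, float), 360.0)
    idx = np.minimum((a / (360.0 / n_sec)).astype(int), n_sec - 1)
    return base + idx


@dataclass
class ImageGrid:
    """Geometry of the short-axis image stack."""

    shape: tuple[int, int, int]  # (nx, ny, n_slices)
    pixel_spacing_mm: float = 2.0
    slice_thickness_mm: float = 10.0

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny, _ = self.shape
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.pixel_spacing_mm
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.pixel_spacing_mm
        return np.meshgrid(x, y, indexing="ij")


@dataclass
class SliceContour:
    """Endocardial and epicardial polygons (mm) of one slice."""

    endo: np.ndarray
    epi: np.ndarray
    rv_insertion_angle_deg: float
    level: str

    def __post_init__(self):
        self.endo = np.asarray(self.endo, dtype=float)
        self.epi = np.asarray(self.epi, dtype=float)
        if self.level not in LEVELS:
            raise ValueError(f"unknown slice level: {self.level!r}")
        for name, poly in (("endo", self.endo), ("epi", self.epi)):
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError(f"{name} contour must be an (n>=3, 2) array")
        p_endo, p_epi = Polygon(self.endo), Polygon(self.epi)
        if not (p_endo.is_valid and p_epi.is_valid):
            raise ValueError("contours must be simple (non-self-intersecting) polygons")
        if not p_epi.contains(p_endo):
            raise ValueError("endocardial contour must lie strictly inside the epicardial contour")


@dataclass
class ContourSet:
    """Per-slice contours of one subject, ordered base to apex."""

    slices: list[SliceContour] = field(default_factory=list)

    def __post_init__(self):
        if len(self.slices) < 3:
            raise ValueError("need at least 3 contoured slices")

    def to_json(self) -> str:
        return json.dumps({
            "slices": [
                {
                    "endo": s.endo.tolist(),
                    "epi": s.epi.tolist(),
                    "rv_angle_deg": s.rv_insertion_angle_deg,
                    "level": s.level,
                }
                for s in self.slices
            ]
        })

    @classmethod
    def from_json(cls, text: str) -> "ContourSet":
        data = json.loads(text)
        return cls(slices=[
            SliceContour(
                endo=np.asarray(s["endo"], float),
                epi=np.asarray(s["epi"], float),
                rv_insertion_angle_deg=float(s["rv_angle_deg"]),
                level=s["level"],
            )
            for s in data["slices"]
        ])


def build_segment_masks(contours: ContourSet, grid: ImageGrid,
                        clockwise: bool = False) -> np.ndarray:
    """Per-pixel AHA segment labels (0 outside the myocardium).

    A pixel belongs to the myocardium when its centre lies inside the
    epicardial polygon and outside the endocardial polygon; its sector is
    determined by the angle of the pixel centre around the epicardial
    centroid, measured from the RV-insertion ray.
    """
    if len(contours.slices) != grid.shape[2]:
        raise ValueError("number of contoured slices must match the grid")
    xs, ys = grid.pixel_centers()
    labels = np.zeros(grid.shape, dtype=np.int16)
    for k, sl in enumerate(contours.slices):
        p_endo, p_epi = Polygon(sl.endo), Polygon(sl.epi)
        inside_epi = shapely.contains_xy(p_epi, xs.ravel(), ys.ravel()).reshape(xs.shape)
        inside_endo = shapely.contains_xy(p_endo, xs.ravel(), ys.ravel()).reshape(xs.shape)
        myo = inside_epi & ~inside_endo
        if not myo.any():
            raise ValueError(f"empty myocardial annulus on slice {k}")
        cx, cy = p_epi.centroid.x, p_epi.centroid.y
        ang = np.degrees(np.arctan2(ys - cy, xs - cx))
        rel = ang - sl.rv_insertion_angle_deg
        seg = sector_segment_ids(rel, sl.level, clockwise=clockwise)
        labels[:, :, k] = np.where(myo, seg, 0)
    return labels


def segment_statistics(t2, labels, subject_id: str = "subject",
                       min_pixels: int = 10) -> pd.DataFrame:
    """Per-segment mean T2 and pixel-SD, pooled across slices of a level.

    Parameters
    ----------
    t2 : a :class:`~cardiomad.t2fit.T2Map` or a float array aligned with
        ``labels``; only converged, finite pixels enter the statistics.
    labels : integer segment labels (0 = background) on the same grid.
    min_pixels : segments with fewer contributing pixels are flagged
        (``ok=False``) so downstream feature extraction can reject them.

    Returns
    -------
    DataFrame with one row per segment id 1-16:
    subject_id, segment_id, mean_T2_ms, pixel_SD_ms (sample SD, n-1),
    n_pixels, level, ok.
    """
    from .t2fit import T2Map  # local import avoids cycles at module load

    labels = np.asarray(labels)
    if isinstance(t2, T2Map):
        values = t2.T2_ms
        usable = t2.converged & np.isfinite(values)
    else:
        values = np.asarray(t2, dtype=float)
        usable = np.isfinite(values)
    if values.shape != labels.shape:
        raise ValueError("labels must align with the T2 map grid")

    rows = []
    for seg in range(1, 17):
        sel = (labels == seg) & usable
        n = int(sel.sum())
        vals = values[sel]
        mean = float(vals.mean()) if n else np.nan
        sd = float(vals.std(ddof=1)) if n >= 2 else (0.0 if n == 1 else np.nan)
        rows.append({
            "subject_id": subject_id,
            "segment_id": seg,
            "mean_T2_ms": mean,
            "pixel_SD_ms": sd,
            "n_pixels": n,
            "level": segment_level(seg),
            "ok": n >= min_pixels,
        })
    return pd.DataFrame(rows)
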