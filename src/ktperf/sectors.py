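"""Myocardial sector partition and signal-intensity curve extraction.

Short-axis analysis follows the three-segment convention used for mouse
perfusion: the annulus between the endocardial and epicardial contours is
divided into sectors of equal circumferential extent, counted
counterclockwise from the anterior septal insertion of the right ventricle.
With three sectors the labels are ``septal``, ``anterolateral`` and
``inferolateral``.

Coordinate convention: pixel-centered, 0-based, ``(x, y) = (column, row)``;
angles are measured counterclockwise from the image +x axis in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon
from skimage.draw import polygon2mask

from .core import DynamicSeries, GeometryError, InputError, SICurve

__all__ = [
    "Contour",
    "SectorMasks",
    "SECTOR_LABELS_3",
    "sector_partition",
    "extract_curve",
    "shift_contours",
]

SECTOR_LABELS_3 = ("septal", "anterolateral", "inferolateral")


@dataclass
class Contour:
    """Ordered closed polygon in pixel coordinates.

    ``points`` has shape (n, 2) with columns ``(x, y)``; the polygon is
    closed logically (the first point is not repeated).
    """

    points: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise GeometryError("contour points must have shape (n, 2)")
        pts = self.points
        # drop an explicitly repeated closing point
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
            self.points = pts
        if len(pts) < 8:
            raise GeometryError(f"contour needs >= 8 points, got {len(pts)}")
        if not self.polygon.is_simple:
            raise GeometryError(f"contour {self.label!r} is self-intersecting")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)

    def centroid(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize to a boolean (rows, cols) mask."""
        rc = np.column_stack([self.points[:, 1], self.points[:, 0]])
        return polygon2mask(shape, rc)

    def shifted(self, dx: float, dy: float) -> "Contour":
        return Contour(self.points + np.array([dx, dy]), label=self.label)


@dataclass
class SectorMasks:
    """Disjoint boolean sector masks partitioning the myocardial annulus."""

    masks: list[np.ndarray]
    labels: list[str]
    rv_insertion_angle_deg: float

    def __getitem__(self, label: str) -> np.ndarray:
        return self.masks[self.labels.index(label)]

    @property
    def annulus(self) -> np.ndarray:
        out = np.zeros_like(self.masks[0])
        for m in self.masks:
            out |= m
        return out


def sector_partition(
    epi: Contour,
    endo: Contour,
    rv_insertion_angle_deg: float,
    n_sectors: int = 3,
    shape: tuple[int, int] | None = None,
) -> SectorMasks:
    """Partition the myocardial annulus into equal-angle sectors.

    Every annulus pixel (inside ``epi``, outside ``endo``) is assigned to
    exactly one sector by the angle of its center about the midwall center
    (mean of the two contour centroids), relative to the RV insertion
    reference angle.  Sectors span consecutive ``360/n_sectors`` degree arcs
    counterclockwise from the insertion point.

    Parameters
    ----------
    shape
        (rows, cols) of the pixel grid. Required; typically the image shape.
    """
    if n_sectors < 2:
        raise InputError("n_sectors must be >= 2")
    if shape is None:
        raise InputError("shape (rows, cols) is required to rasterize sector masks")
    if not endo.polygon.within(epi.polygon):
        raise GeometryError("endocardial contour must lie strictly inside the epicardial contour")

    epi_mask = epi.to_mask(shape)
    endo_mask = endo.to_mask(shape)
    annulus = epi_mask & ~endo_mask
    if not annulus.any():
        raise GeometryError("annulus between contours contains no pixels")

    center = 0.5 * (epi.centroid() + endo.centroid())
    rows, cols = np.nonzero(annulus)
    theta = np.degrees(np.arctan2(rows - center[1], cols - center[0]))
    rel = np.mod(theta - rv_insertion_angle_deg, 360.0)
    width = 360.0 / n_sectors
    idx = np.minimum((rel // width).astype(int), n_sectors - 1)

    masks = []
    for i in range(n_sectors):
        m = np.zeros(shape, dtype=bool)
        m[rows[idx == i], cols[idx == i]] = True
        if not m.any():
            raise GeometryError(f"sector {i} is empty; annulus too thin for {n_sectors} sectors")
        masks.append(m)

    if n_sectors == 3:
        labels = list(SECTOR_LABELS_3)
    else:
        labels = [f"sector_{i}" for i in range(n_sectors)]
    return SectorMasks(masks=masks, labels=labels, rv_insertion_angle_deg=float(rv_insertion_angle_deg))


def extract_curve(series: DynamicSeries, mask: np.ndarray, label: str = "") -> SICurve:
    """Mean signal over ``mask`` for every frame of ``series``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.data.shape[1:]:
        raise InputError(f"mask shape {mask.shape} does not match frames {series.data.shape[1:]}")
    n = int(mask.sum())
    if n == 0:
        raise InputError("empty ROI mask")
    si = series.data[:, mask].mean(axis=1)
    return SICurve(t_s=series.frame_times_s.copy(), si=si, roi_label=label, n_pixels=n)


def shift_contours(
    contours: Sequence[Contour],
    dx_px: np.ndarray,
    dy_px: np.ndarray,
) -> list[list[Contour]]:
    """Rigidly translate a contour set by per-frame offsets.

    Returns one contour set per frame; emulates scripted correction of
    respiratory in-plane drift (contours drawn on one frame and nudged on
    the others).
    """
    dx_px = np.atleast_1d(np.asarray(dx_px, dtype=float))
    dy_px = np.atleast_1d(np.asarray(dy_px, dtype=float))
    if dx_px.shape != dy_px.shape:
        raise InputError("dx_px and dy_px must have the same length")
    if not (np.all(np.isfinite(dx_px)) and np.all(np.isfinite(dy_px))):
        raise InputError("offsets must be finite")
    return [[c.shifted(dx, dy) for c in contours] for dx, dy in zip(dx_px, dy_px)]
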