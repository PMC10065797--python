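"""Spatial event heat maps in a heart-tube-aligned lobe frame.

Event locations (divisions or differentiation events) from one video are
first brought into a common orientation: the lobe is rotated so the heart
tube runs along the y-axis and, if necessary, mirrored so the lobe faces
right of the tube.  The aligned lobe boundary's bounding box is then divided
into an n x n grid (default 5 x 5, each cell 20% of the width/height) and
events are counted per cell.  Per-video maps are combined by element-wise
summation, and two maps are compared by the Pearson correlation of their
flattened counts with the conventional category table: r in [0, 0.25) none,
[0.25, 0.5) weak, [0.5, 0.75) moderate, [0.75, 1] strong (negative r is
reported raw and categorized as none).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon

from .errors import GeometryError, ValidationError
from .trackio import LGGeometry

__all__ = [
    "AlignmentTransform",
    "HeatMap5x5",
    "CorrelationReport",
    "align_lobe",
    "build_heatmap",
    "combine_heatmaps",
    "compare_heatmaps",
    "area_normalized_intensity",
    "correlation_category",
]

CATEGORY_EDGES = ((0.25, "none"), (0.5, "weak"), (0.75, "moderate"))


@dataclass
class AlignmentTransform:
    """Rigid planar transform (rotation about a pivot, optional mirror about
    the vertical tube line) that aligned a lobe; invertible."""

    pivot_xy: np.ndarray
    angle_deg: float            # rotation applied, counter-clockwise
    flip: bool                  # mirrored about the tube line (x = pivot x)

    def apply(self, points_xy: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
        a = math.radians(self.angle_deg)
        rot = np.array([[math.cos(a), -math.sin(a)],
                        [math.sin(a), math.cos(a)]])
        out = (pts - self.pivot_xy) @ rot.T
        if self.flip:
            out[:, 0] = -out[:, 0]
        return out + self.pivot_xy

    def invert(self, points_xy: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_xy, dtype=float)) - self.pivot_xy
        if self.flip:
            pts = pts * np.array([-1.0, 1.0])
        a = math.radians(-self.angle_deg)
        rot = np.array([[math.cos(a), -math.sin(a)],
                        [math.sin(a), math.cos(a)]])
        return pts @ rot.T + self.pivot_xy


@dataclass
class HeatMap5x5:
    """Aligned event-count grid.

    ``counts[i, j]``: row i bins distance from the heart tube (x after
    alignment, row 0 nearest the tube), column j bins position along the
    tube (y after alignment).  Bin intervals are half-open with the last bin
    closed.
    """

    counts: np.ndarray
    bbox: tuple[float, float, float, float]      # (xmin, ymin, xmax, ymax), um
    transform: AlignmentTransform | None
    n_events_in: int
    n_events_excluded: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValidationError("heat-map counts must be non-negative")
        if int(self.counts.sum()) != self.n_events_in:
            raise ValidationError("heat-map counts do not sum to n_events_in")

    @property
    def grid_n(self) -> int:
        return self.counts.shape[0]


@dataclass
class CorrelationReport:
    r: float
    category: str


def align_lobe(points_xy: np.ndarray, geometry: LGGeometry):
    """Rotate/flip planar points into the canonical lobe orientation.

    The smallest-magnitude rotation bringing the heart-tube direction
    parallel to the y-axis is applied about the tube point; if the lobe
    centroid then lies left of the tube line, the frame is mirrored about
    that line so the lobe faces right.  Returns ``(transformed points,
    transform)``; the same transform must be applied to the boundary.
    """
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    if pts.shape[0] < 1 or pts.shape[1] != 2:
        raise ValidationError("need at least one planar (x, y) point")
    tube_xy = geometry.tube_dir[:2]
    if np.linalg.norm(tube_xy) < 1e-12:
        raise GeometryError("heart tube is vertical in the imaging plane; "
                            "in-plane alignment undefined")
    tube_angle = math.degrees(math.atan2(tube_xy[1], tube_xy[0]))
    # smallest rotation mapping the tube *line* onto the y-axis
    delta = 90.0 - tube_angle
    delta = (delta + 90.0) % 180.0 - 90.0
    pivot = geometry.tube_point[:2].copy()
    transform = AlignmentTransform(pivot_xy=pivot, angle_deg=delta, flip=False)
    boundary = transform.apply(geometry.lobe_boundary)
    centroid_x = float(np.asarray(Polygon(boundary).centroid.coords)[0][0])
    if centroid_x < pivot[0]:
        transform.flip = True
    return transform.apply(pts), transform


def build_heatmap(points_xy: np.ndarray, boundary_xy: np.ndarray,
                  grid_n: int = 5,
                  transform: AlignmentTransform | None = None) -> HeatMap5x5:
    """Bin aligned event locations into the lobe bounding-box grid.

    The bounding box is that of the (aligned) lobe boundary polygon; each
    side is divided into ``grid_n`` equal segments.  Points outside the
    boundary polygon are excluded and counted in ``n_events_excluded`` —
    no event is ever silently dropped.
    """
    if grid_n < 1:
        raise ValidationError("grid_n must be >= 1")
    boundary = np.asarray(boundary_xy, dtype=float)
    poly = Polygon(boundary)
    if poly.area <= 0:
        raise GeometryError("degenerate (zero-area) lobe boundary")
    xmin, ymin, xmax, ymax = poly.bounds
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    counts = np.zeros((grid_n, grid_n), dtype=int)
    excluded = 0
    wx = (xmax - xmin) / grid_n
    wy = (ymax - ymin) / grid_n
    for x, y in pts:
        if not poly.covers(Point(x, y)):
            excluded += 1
            continue
        i = grid_n - 1 if x == xmax else int((x - xmin) // wx)
        j = grid_n - 1 if y == ymax else int((y - ymin) // wy)
        counts[min(max(i, 0), grid_n - 1), min(max(j, 0), grid_n - 1)] += 1
    return HeatMap5x5(counts=counts, bbox=(xmin, ymin, xmax, ymax),
                      transform=transform,
                      n_events_in=int(counts.sum()), n_events_excluded=excluded)


def combine_heatmaps(maps) -> HeatMap5x5:
    """Element-wise sum of per-video heat maps (raw counts, no weighting)."""
    maps = list(maps)
    if not maps:
        raise ValidationError("no heat maps to combine")
    n = maps[0].grid_n
    if any(m.grid_n != n for m in maps):
        raise ValidationError("heat maps have mismatched grid sizes")
    counts = np.sum([m.counts for m in maps], axis=0)
    return HeatMap5x5(
        counts=counts, bbox=maps[0].bbox, transform=None,
        n_events_in=int(sum(m.n_events_in for m in maps)),
        n_events_excluded=int(sum(m.n_events_excluded for m in maps)))


def correlation_category(r: float) -> str:
    """Correlation category table; boundaries assigned upward, negative r
    mapped to 'none' (the raw r is always reported alongside)."""
    if r < 0.25:
        return "none"
    if r < 0.5:
        return "weak"
    if r < 0.75:
        return "moderate"
    return "strong"


def compare_heatmaps(a: HeatMap5x5, b: HeatMap5x5) -> CorrelationReport:
    """Pearson correlation of two maps' flattened counts, with category."""
    if a.grid_n != b.grid_n:
        raise ValidationError("heat maps have mismatched grid sizes")
    if a.n_events_in == 0 or b.n_events_in == 0:
        raise ValidationError("cannot correlate an empty heat map")
    av, bv = a.counts.ravel().astype(float), b.counts.ravel().astype(float)
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise ValidationError("a heat map with zero variance across cells "
                              "has undefined correlation")
    r = float(np.corrcoef(av, bv)[0, 1])
    return CorrelationReport(r=r, category=correlation_category(r))


def area_normalized_intensity(total_intensity: float,
                              roi_area_um2: float) -> float:
    """Lobe reporter intensity normalized to ROI/lobe area (a.u. per um^2).

    Used for whole-lobe stress-reporter (gstD-GFP) time courses.
    """
    if roi_area_um2 <= 0:
        raise ValidationError("ROI area must be > 0")
    return total_intensity / roi_area_um2
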