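"""Polygon contour measurements: area, perimeter, centroid, Feret diameters.

Contours are the ordered vertex lists emitted by upstream segmentation tools
(ImageJ, Neurolucida and the like).  Coordinates are continuous, in
micrometres; no pixel grid is modelled.  Area, perimeter and centroid are
delegated to shapely; the Feret (caliper) diameters are computed exactly on
the convex hull — the maximum Feret as the largest pairwise hull-vertex
distance, the minimum Feret by rotating calipers over hull-edge directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

from .errors import DomainError, InvalidContourError

__all__ = [
    "Contour",
    "ContourMeasurements",
    "measure_contour",
    "measure_contours",
    "feret_diameters",
    "scale_contour",
    "STRUCTURE_TYPES",
]

STRUCTURE_TYPES = ("fiber_outer", "axon_inner", "unmyelinated")


@dataclass
class Contour:
    """An implicitly closed polygon outlining one segmented structure."""

    vertices: np.ndarray
    structure_type: str = "fiber_outer"
    id: object = None
    simple: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidContourError(
                f"contour {self.id!r} needs an (n>=3, 2) vertex array, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidContourError(f"contour {self.id!r} has non-finite vertices")
        self.vertices = v


@dataclass(frozen=True)
class ContourMeasurements:
    """Per-contour scalar measurements, all in micrometre units."""

    area: float
    perimeter: float
    centroid: tuple[float, float]
    feret_max: float
    feret_min: float


def _hull_points(contour: Contour) -> np.ndarray:
    try:
        hull = ConvexHull(contour.vertices)
    except QhullError as exc:
        raise InvalidContourError(
            f"contour {contour.id!r} is degenerate (collinear vertices?): {exc}"
        ) from exc
    return contour.vertices[hull.vertices]  # counter-clockwise order


def feret_diameters(contour: Contour) -> tuple[float, float]:
    """(min, max) Feret diameters of the contour's convex hull.

    The minimum width is attained perpendicular to some hull edge, so the
    rotating-calipers sweep over edge normals is exact for polygons.
    """
    hp = _hull_points(contour)
    n = hp.shape[0]

    # maximum Feret: largest pairwise distance between hull vertices
    fmax = 0.0
    chunk = 512
    for i in range(0, n, chunk):
        block = hp[i : i + chunk]
        d2 = ((block[:, None, :] - hp[None, :, :]) ** 2).sum(axis=2)
        fmax = max(fmax, float(np.sqrt(d2.max())))

    # minimum Feret: smallest width over hull-edge normal directions
    edges = np.roll(hp, -1, axis=0) - hp
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    keep = lengths > 0
    if not np.any(keep):
        raise InvalidContourError(f"contour {contour.id!r} has no extent")
    normals = np.column_stack([-edges[keep, 1], edges[keep, 0]]) / lengths[keep, None]
    fmin = np.inf
    for i in range(0, normals.shape[0], chunk):
        proj = normals[i : i + chunk] @ hp.T
        widths = proj.max(axis=1) - proj.min(axis=1)
        fmin = min(fmin, float(widths.min()))
    return fmin, fmax


def measure_contour(contour: Contour) -> ContourMeasurements:
    """Measure one contour: shoelace area, edge-sum perimeter, area-weighted
    centroid, and the two Feret diameters.

    Orientation-independent: clockwise and counter-clockwise vertex orders
    give identical results.
    """
    poly = Polygon(contour.vertices)
    area = poly.area
    if area <= 0:
        raise InvalidContourError(f"contour {contour.id!r} has zero area")
    perimeter = poly.exterior.length
    cx, cy = poly.centroid.x, poly.centroid.y
    fmin, fmax = feret_diameters(contour)
    return ContourMeasurements(
        area=area,
        perimeter=perimeter,
        centroid=(cx, cy),
        feret_max=fmax,
        feret_min=fmin,
    )


def measure_contours(contours) -> "pandas.DataFrame":  # noqa: F821
    """Measure a sequence of contours into a tidy measurement table."""
    import pandas as pd

    rows = []
    for c in contours:
        m = measure_contour(c)
        rows.append(
            {
                "id": c.id,
                "structure_type": c.structure_type,
                "area": m.area,
                "perimeter": m.perimeter,
                "feret_min": m.feret_min,
                "feret_max": m.feret_max,
                "centroid_x": m.centroid[0],
                "centroid_y": m.centroid[1],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "structure_type",
            "area",
            "perimeter",
            "feret_min",
            "feret_max",
            "centroid_x",
            "centroid_y",
        ],
    )


def scale_contour(contour: Contour, um_per_pixel: float) -> Contour:
    """Convert pixel coordinates to micrometres by a uniform scale factor."""
    if um_per_pixel <= 0:
        raise DomainError(f"scale factor must be positive, got {um_per_pixel}")
    return replace(contour, vertices=contour.vertices * um_per_pixel)
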