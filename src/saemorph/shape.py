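"""Dimensionless shape descriptors quantifying departure from circularity.

Five classical descriptors computed from the scalar measurements of a
contour (not from its vertices, so tabulated upstream data without polygons
can be scored too):

    shape_factor = perimeter / sqrt(area)          (circle: 2 sqrt(pi) ~ 3.54)
    form_factor  = 4 pi area / perimeter^2         (circle: 1; maximal)
    aspect_ratio = feret_min / feret_max           (circle: 1)
    compactness  = sqrt(4 area / pi) / feret_max   (circle: 1)
    roundness    = 4 area / (pi feret_max^2)       (circle: 1)

For an exact ellipse, roundness = compactness^2 = aspect_ratio.  When Feret
diameters are unavailable the three Feret-based descriptors are reported as
NaN, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["ShapeMetrics", "compute_shape_metrics", "shape_metrics_table", "CIRCLE_SHAPE_FACTOR"]

CIRCLE_SHAPE_FACTOR = 2.0 * math.sqrt(math.pi)


@dataclass(frozen=True)
class ShapeMetrics:
    shape_factor: float
    form_factor: float
    aspect_ratio: float
    compactness: float
    roundness: float


def compute_shape_metrics(m) -> ShapeMetrics:
    """Compute the five descriptors from a measurement record.

    ``m`` is any object with ``area``, ``perimeter``, ``feret_min`` and
    ``feret_max`` attributes (a :class:`~saemorph.contours.ContourMeasurements`
    or a table row); the Feret fields may be None/NaN.
    """
    area = float(m.area)
    perimeter = float(m.perimeter)
    if area <= 0 or perimeter <= 0:
        raise DomainError(
            f"area and perimeter must be positive, got area={area}, perimeter={perimeter}"
        )
    fmin = m.feret_min
    fmax = m.feret_max
    have_ferets = (
        fmin is not None
        and fmax is not None
        and np.isfinite(fmin)
        and np.isfinite(fmax)
    )
    if have_ferets and fmax <= 0:
        raise DomainError(f"feret_max must be positive, got {fmax}")
    shape_factor = perimeter / math.sqrt(area)
    form_factor = 4.0 * math.pi * area / perimeter**2
    if have_ferets:
        aspect_ratio = fmin / fmax
        compactness = math.sqrt(4.0 * area / math.pi) / fmax
        roundness = 4.0 * area / (math.pi * fmax**2)
    else:
        aspect_ratio = compactness = roundness = float("nan")
    return ShapeMetrics(
        shape_factor=shape_factor,
        form_factor=form_factor,
        aspect_ratio=aspect_ratio,
        compactness=compactness,
        roundness=roundness,
    )


def shape_metrics_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised descriptors for a measurement table.

    Requires ``area`` and ``perimeter`` columns; ``feret_min``/``feret_max``
    are optional (NaN propagates into the Feret-based descriptors).
    """
    for col in ("area", "perimeter"):
        if col not in df.columns:
            raise DomainError(f"missing required column {col!r}")
    area = df["area"].to_numpy(dtype=float)
    perim = df["perimeter"].to_numpy(dtype=float)
    if np.any(area <= 0) or np.any(perim <= 0):
        raise DomainError("area and perimeter must be positive in every row")
    out = pd.DataFrame(index=df.index)
    out["shape_factor"] = perim / np.sqrt(area)
    out["form_factor"] = 4.0 * np.pi * area / perim**2
    if "feret_min" in df.columns and "feret_max" in df.columns:
        fmin = df["feret_min"].to_numpy(dtype=float)
        fmax = df["feret_max"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out["aspect_ratio"] = fmin / fmax
            out["compactness"] = np.sqrt(4.0 * area / np.pi) / fmax
            out["roundness"] = 4.0 * area / (np.pi * fmax**2)
    else:
        out["aspect_ratio"] = np.nan
        out["compactness"] = np.nan
        out["roundness"] = np.nan
    return out
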