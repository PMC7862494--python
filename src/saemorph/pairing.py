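"""Axon-to-fiber linkage and myelination metrics.

Electron-microscopy segmentation yields two independent contour sets — the
outer myelin boundary of each fiber and the inner axon boundary — without an
explicit link between them.  The pairing here reconstructs that link: the
Euclidean distance matrix between axon and fiber centroids is fed to the
Hungarian (minimum-cost assignment) method, and each retained pair is scored
with

    myelin_thickness = (fiber_diameter - axon_diameter) / 2
    g_ratio          = axon_diameter / fiber_diameter.

Assignment is delegated to :func:`scipy.optimize.linear_sum_assignment`; a
lexicographic tie-break (exact for problems up to 64 x 64) makes the matching
deterministic when several assignments share the optimal cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .errors import DomainError

__all__ = [
    "CentroidSet",
    "FiberAxonPair",
    "PairingResult",
    "distance_matrix",
    "optimal_assignment",
    "pair_and_score",
]

logger = logging.getLogger(__name__)

_LEX_REFINE_LIMIT = 64  # exact tie-break only for matrices up to this side


@dataclass(frozen=True)
class CentroidSet:
    """Labelled centroid coordinates for one structure class."""

    ids: tuple
    xy: np.ndarray

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise DomainError(f"centroids must be an (n, 2) array, got {xy.shape}")
        if xy.shape[0] != len(self.ids):
            raise DomainError("ids and coordinates differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise DomainError("centroid ids must be unique")
        object.__setattr__(self, "xy", xy)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CentroidSet":
        for col in ("id", "centroid_x", "centroid_y"):
            if col not in df.columns:
                raise DomainError(f"missing required column {col!r}")
        return cls(
            ids=tuple(df["id"]),
            xy=df[["centroid_x", "centroid_y"]].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class FiberAxonPair:
    """One matched (outer fiber, inner axon) contour pair with myelin metrics.

    ``valid`` is False for physically implausible pairs (g_ratio >= 1); such
    records are reported but must be excluded from myelin statistics.
    """

    fiber_id: object
    axon_id: object
    centroid_distance: float
    fiber_diameter: float
    axon_diameter: float
    myelin_thickness: float
    g_ratio: float
    valid: bool


@dataclass
class PairingResult:
    pairs: list[FiberAxonPair] = field(default_factory=list)
    dropped: list[dict] = field(default_factory=list)
    unmatched_axons: list = field(default_factory=list)
    unmatched_fibers: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "fiber_id": p.fiber_id,
                    "axon_id": p.axon_id,
                    "centroid_distance": p.centroid_distance,
                    "fiber_diameter": p.fiber_diameter,
                    "axon_diameter": p.axon_diameter,
                    "myelin_thickness": p.myelin_thickness,
                    "g_ratio": p.g_ratio,
                    "valid": p.valid,
                }
                for p in self.pairs
            ],
            columns=[
                "fiber_id",
                "axon_id",
                "centroid_distance",
                "fiber_diameter",
                "axon_diameter",
                "myelin_thickness",
                "g_ratio",
                "valid",
            ],
        )


def distance_matrix(axons: CentroidSet, fibers: CentroidSet) -> np.ndarray:
    """Euclidean distances, entry (i, j) = |axon_i - fiber_j|."""
    if len(axons.ids) == 0 or len(fibers.ids) == 0:
        raise DomainError("centroid sets must be non-empty")
    return cdist(axons.xy, fibers.xy)


def _masked_optimum(costs: np.ndarray, rows: list[int], cols: list[int]) -> float:
    """Optimal assignment cost using only the given rows/columns."""
    if not rows or not cols:
        return 0.0
    sub = costs[np.ix_(rows, cols)]
    ri, ci = linear_sum_assignment(sub)
    return float(sub[ri, ci].sum())


def optimal_assignment(costs) -> list[tuple[int, int]]:
    """Minimum-cost matching covering the smaller dimension of ``costs``.

    Returns (row, column) index pairs sorted by row.  Among equal-cost
    matchings the lexicographically smallest (row, column) sequence is
    preferred, computed exactly for matrices up to 64 x 64; beyond that the
    (deterministic) scipy solution is returned as-is.
    """
    costs = np.asarray(costs, dtype=float)
    if costs.ndim != 2 or costs.size == 0:
        raise DomainError(f"cost matrix must be 2-D and non-empty, got shape {costs.shape}")
    if not np.all(np.isfinite(costs)):
        raise DomainError("cost matrix entries must be finite")
    n, m = costs.shape
    ri, ci = linear_sum_assignment(costs)
    best = float(costs[ri, ci].sum())
    if max(n, m) > _LEX_REFINE_LIMIT:
        return sorted(zip(ri.tolist(), ci.tolist()))

    tol = 1e-9 * (1.0 + abs(best))
    k = min(n, m)
    fixed: list[tuple[int, int]] = []
    fixed_cost = 0.0
    rows_left = list(range(n))
    cols_left = list(range(m))
    for i in list(rows_left):
        if len(fixed) == k:
            break
        rest_rows = [r for r in rows_left if r != i]
        matched = False
        for j in cols_left:
            rest_cols = [c for c in cols_left if c != j]
            total = fixed_cost + costs[i, j] + _masked_optimum(costs, rest_rows, rest_cols)
            if total <= best + tol:
                fixed.append((i, j))
                fixed_cost += float(costs[i, j])
                rows_left = rest_rows
                cols_left = rest_cols
                matched = True
                break
        if not matched:
            # only possible when rows outnumber columns: row i stays unmatched
            rows_left = rest_rows
    return fixed


def pair_and_score(
    axon_records: pd.DataFrame,
    fiber_records: pd.DataFrame,
    max_distance: float | None = None,
    require_containment: bool = False,
    fiber_contours: dict | None = None,
) -> PairingResult:
    """Assign axons to fibers by centroid distance and compute myelin metrics.

    Both tables need ``id``, ``centroid_x``, ``centroid_y`` and
    ``sae_diameter`` columns.  ``max_distance`` drops pairs whose centroid
    separation exceeds the threshold; when None, each fiber's own SAE radius
    is used (the centroid of a correctly segmented axon lies inside its
    fiber).  With ``require_containment`` the axon centroid must fall inside
    the fiber contour supplied via ``fiber_contours`` (a fiber_id -> Contour
    mapping).  Dropped pairs and unmatched structures are reported, never
    silently discarded.
    """
    for name, df in (("axon", axon_records), ("fiber", fiber_records)):
        for col in ("id", "centroid_x", "centroid_y", "sae_diameter"):
            if col not in df.columns:
                raise DomainError(f"{name} records lack required column {col!r}")
    if len(axon_records) == 0 or len(fiber_records) == 0:
        raise DomainError("axon and fiber record sets must be non-empty")

    axons = axon_records.sort_values("id", kind="stable").reset_index(drop=True)
    fibers = fiber_records.sort_values("id", kind="stable").reset_index(drop=True)
    dmat = distance_matrix(CentroidSet.from_frame(axons), CentroidSet.from_frame(fibers))
    matches = optimal_assignment(dmat)

    result = PairingResult()
    matched_a, matched_f = set(), set()
    for i, j in matches:
        a = axons.iloc[i]
        f = fibers.iloc[j]
        dist = float(dmat[i, j])
        limit = max_distance if max_distance is not None else float(f["sae_diameter"]) / 2.0
        if dist > limit:
            result.dropped.append(
                {
                    "axon_id": a["id"],
                    "fiber_id": f["id"],
                    "reason": f"centroid distance {dist:.3g} exceeds limit {limit:.3g}",
                }
            )
            logger.warning(
                "dropped pair axon=%r fiber=%r: distance %.4g > %.4g",
                a["id"], f["id"], dist, limit,
            )
            continue
        if require_containment:
            contour = (fiber_contours or {}).get(f["id"])
            if contour is None:
                result.dropped.append(
                    {"axon_id": a["id"], "fiber_id": f["id"], "reason": "no fiber contour for containment check"}
                )
                continue
            from shapely.geometry import Point, Polygon

            if not Polygon(contour.vertices).contains(Point(a["centroid_x"], a["centroid_y"])):
                result.dropped.append(
                    {"axon_id": a["id"], "fiber_id": f["id"], "reason": "axon centroid outside fiber contour"}
                )
                logger.warning(
                    "dropped pair axon=%r fiber=%r: centroid outside contour", a["id"], f["id"]
                )
                continue
        fd = float(f["sae_diameter"])
        ad = float(a["sae_diameter"])
        g = ad / fd
        valid = 0.0 < g < 1.0
        if not valid:
            logger.warning(
                "implausible pair axon=%r fiber=%r: g_ratio=%.4g", a["id"], f["id"], g
            )
        result.pairs.append(
            FiberAxonPair(
                fiber_id=f["id"],
                axon_id=a["id"],
                centroid_distance=dist,
                fiber_diameter=fd,
                axon_diameter=ad,
                myelin_thickness=(fd - ad) / 2.0,
                g_ratio=g,
                valid=valid,
            )
        )
        matched_a.add(a["id"])
        matched_f.add(f["id"])

    dropped_ids = {d["axon_id"] for d in result.dropped}
    result.unmatched_axons = [x for x in axons["id"] if x not in matched_a]
    result.unmatched_fibers = [x for x in fibers["id"] if x not in matched_f]
    # ids dropped by filters are part of unmatched too; keep both reports
    _ = dropped_ids
    return result
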