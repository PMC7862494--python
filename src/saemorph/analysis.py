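"""Population-level summaries: size classes, frequency distributions,
method comparison and regression agreement.

The method comparison computes four diameters per fiber from the same
measured (area, perimeter, min-Feret) triple:

    sae              tilt-corrected minor diameter (2 r from the inversion)
    feret_min        the minimum Feret diameter itself
    area_circle      2 sqrt(area / pi)
    perimeter_circle perimeter / pi

For any record with perimeter >= the isoperimetric bound the per-fiber chain
``sae <= area_circle <= perimeter_circle`` holds, with equality only for a
circle.  Overestimation of each traditional method is expressed relative to
the SAE diameter; the mean-based figure is the primary one, the
median-based figure is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ellipse import solve_sae_batch
from .errors import DomainError

__all__ = [
    "SizeClassTable",
    "FrequencyDistribution",
    "RegressionResult",
    "MethodComparison",
    "size_class_counts",
    "frequency_distribution",
    "density_modes",
    "regression_agreement",
    "compare_methods",
    "method_diameters",
    "SIZE_CLASS_EDGES",
]

# Right-closed bins: (0, 4], (4, 10], (10, inf) micrometres — the small
# autonomic, gamma-motor and alpha-motor diameter bands.
SIZE_CLASS_EDGES = (0.0, 4.0, 10.0, math.inf)
SIZE_CLASS_LABELS = ("0-4", ">4-10", ">10")


@dataclass(frozen=True)
class SizeClassTable:
    counts: tuple[int, int, int]
    fractions: tuple[float, float, float]
    n: int
    n_rejected: int
    labels: tuple[str, str, str] = SIZE_CLASS_LABELS


def size_class_counts(diameters) -> SizeClassTable:
    """Bin diameters into the (0-4], (4-10], (10, inf) um size classes.

    Non-positive or non-finite diameters are rejected and counted, never
    silently dropped.
    """
    d = np.asarray(list(diameters), dtype=float)
    ok = np.isfinite(d) & (d > 0)
    n_rejected = int(np.sum(~ok)) if d.size else 0
    d = d[ok]
    counts = (
        int(np.sum(d <= 4.0)),
        int(np.sum((d > 4.0) & (d <= 10.0))),
        int(np.sum(d > 10.0)),
    )
    n = int(d.size)
    fractions = tuple(c / n if n else 0.0 for c in counts)
    return SizeClassTable(counts=counts, fractions=fractions, n=n, n_rejected=n_rejected)


@dataclass(frozen=True)
class FrequencyDistribution:
    bin_edges: np.ndarray
    counts: np.ndarray
    grid: np.ndarray | None
    density: np.ndarray | None


def frequency_distribution(
    diameters, bin_width: float = 0.5, smooth: bool = True, grid_points: int = 512
) -> FrequencyDistribution:
    """Histogram of diameters plus an optional kernel-smoothed density.

    Smoothing uses a Gaussian kernel with the normal-reference (Silverman)
    bandwidth, evaluated on a grid extending five bandwidths beyond the data
    range so the density integrates to 1 within 1e-3.  Smoothing requires at
    least two distinct values; otherwise only the histogram is returned.
    """
    d = np.asarray(list(diameters), dtype=float)
    if d.size < 1:
        raise DomainError("at least one diameter is required")
    if bin_width <= 0:
        raise DomainError(f"bin_width must be positive, got {bin_width}")
    lo = min(0.0, math.floor(d.min() / bin_width) * bin_width)
    hi = math.ceil(d.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    grid = density = None
    if smooth and d.size >= 2 and np.std(d) > 0:
        kde = stats.gaussian_kde(d, bw_method="silverman")
        bw = float(kde.factor * np.std(d, ddof=1))
        grid = np.linspace(d.min() - 5 * bw, d.max() + 5 * bw, grid_points)
        density = kde(grid)
    return FrequencyDistribution(bin_edges=edges, counts=counts, grid=grid, density=density)


def density_modes(diameters, grid_points: int = 1024, min_rel_height: float = 0.05):
    """Locations of local maxima of the kernel-smoothed diameter density,
    ordered by peak height (highest first).

    Peaks below ``min_rel_height`` times the global maximum are ignored.
    """
    from scipy.signal import find_peaks

    d = np.asarray(list(diameters), dtype=float)
    if d.size < 2 or np.std(d) == 0:
        raise DomainError("mode detection needs at least two distinct values")
    kde = stats.gaussian_kde(d, bw_method="silverman")
    bw = float(kde.factor * np.std(d, ddof=1))
    grid = np.linspace(d.min() - 3 * bw, d.max() + 3 * bw, grid_points)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, height=min_rel_height * dens.max())
    order = np.argsort(dens[peaks])[::-1]
    return [float(grid[p]) for p in np.asarray(peaks)[order]]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


def regression_agreement(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with the coefficient of determination."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise DomainError("x and y must have equal length >= 3")
    if np.var(x) == 0:
        raise DomainError("x has zero variance")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


METHODS = ("sae", "feret_min", "area_circle", "perimeter_circle")


def method_diameters(measurements: pd.DataFrame, n_terms: int = 4) -> pd.DataFrame:
    """Per-fiber diameters under all four methods, from one measurement table.

    Requires ``area`` and ``perimeter`` columns; ``feret_min`` is carried
    through when present (NaN otherwise).
    """
    for col in ("area", "perimeter"):
        if col not in measurements.columns:
            raise DomainError(f"missing required column {col!r}")
    area = measurements["area"].to_numpy(dtype=float)
    perim = measurements["perimeter"].to_numpy(dtype=float)
    if np.any(~np.isfinite(area)) or np.any(area <= 0):
        raise DomainError("areas must be positive and finite")
    if np.any(~np.isfinite(perim)) or np.any(perim <= 0):
        raise DomainError("perimeters must be positive and finite")
    sae = solve_sae_batch(area, perim, n_terms=n_terms)
    out = pd.DataFrame(index=measurements.index)
    out["sae"] = sae["sae_diameter"].to_numpy()
    out["feret_min"] = (
        measurements["feret_min"].to_numpy(dtype=float)
        if "feret_min" in measurements.columns
        else np.nan
    )
    out["area_circle"] = 2.0 * np.sqrt(area / np.pi)
    out["perimeter_circle"] = perim / np.pi
    out["tilt_angle"] = sae["tilt_angle"].to_numpy()
    out["rho"] = sae["rho"].to_numpy()
    out["sae_feasible"] = sae["sae_feasible"].to_numpy()
    return out


@dataclass(frozen=True)
class MethodComparison:
    per_fiber: pd.DataFrame
    summary: pd.DataFrame
    n: int
    n_infeasible: int


def compare_methods(measurements, n_terms: int = 4) -> MethodComparison:
    """Compare the four diameter methods on one set of measurements.

    ``measurements`` is a DataFrame (area/perimeter/feret_min columns) or a
    sequence of :class:`~saemorph.contours.ContourMeasurements`.  The summary
    carries per-method mean, standard error, median, and percent
    overestimation relative to SAE on two bases:

        pct_over_mean   = 100 (mean_m - mean_sae) / mean_sae
        pct_over_median = 100 * median over fibers of (d_m / d_sae - 1)

    The median basis is computed per fiber because the comparison is paired
    (every fiber is measured by all four methods); a ratio of pooled medians
    would be dominated by which mode of a multimodal size distribution the
    pooled median happens to fall in.

    Infeasible SAE records (perimeter below the isoperimetric bound) are
    retained with their clamped circle-equivalent diameter and counted.
    """
    if not isinstance(measurements, pd.DataFrame):
        measurements = pd.DataFrame(
            [
                {
                    "area": m.area,
                    "perimeter": m.perimeter,
                    "feret_min": m.feret_min,
                    "feret_max": m.feret_max,
                }
                for m in measurements
            ]
        )
    if len(measurements) < 1:
        raise DomainError("at least one measurement is required")
    per_fiber = method_diameters(measurements, n_terms=n_terms)
    n = len(per_fiber)
    n_infeasible = int((~per_fiber["sae_feasible"]).sum())
    mean_sae = float(per_fiber["sae"].mean())
    sae_vals = per_fiber["sae"].to_numpy(dtype=float)
    rows = []
    for m in METHODS:
        vals = per_fiber[m].to_numpy(dtype=float)
        mean = float(np.nanmean(vals))
        median = float(np.nanmedian(vals))
        se = float(np.nanstd(vals, ddof=1) / math.sqrt(np.sum(np.isfinite(vals)))) if n > 1 else 0.0
        rows.append(
            {
                "method": m,
                "mean": mean,
                "se": se,
                "median": median,
                "pct_over_mean": 100.0 * (mean - mean_sae) / mean_sae,
                "pct_over_median": float(100.0 * np.nanmedian(vals / sae_vals - 1.0)),
            }
        )
    summary = pd.DataFrame(rows).set_index("method")
    return MethodComparison(
        per_fiber=per_fiber, summary=summary, n=n, n_infeasible=n_infeasible
    )
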