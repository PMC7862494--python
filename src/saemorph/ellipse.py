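"""Inverse ellipse geometry: the shape-adjusted ellipse (SAE) diameter.

A myelinated nerve fiber is modelled as a cylinder with a circular base of
radius ``r``.  When the fiber runs at a dispersion (tilt) angle ``theta``
relative to the sectioning plane normal, its cut surface is an ellipse whose
semi-minor axis equals ``r`` and whose semi-major axis is
``R = r / cos(theta)``.  Oblique sectioning therefore inflates the measured
cross-sectional area by the factor ``rho = 1 / cos(theta)`` while leaving the
minor diameter unchanged.

Because an ellipse is uniquely determined by its area and perimeter, the true
fiber diameter ``2 r`` can be recovered from the two quantities every
segmentation tool reports.  Combining the exact area formula
``A = pi * r * R`` with the Gauss–Kummer series for the ellipse perimeter,

    p = pi * (r + R) * sum_n binom(1/2, n)^2 * h^n,
    h = (R - r)^2 / (R + r)^2,

and substituting ``R = A / (pi * r)`` yields, after truncating the series at
four terms, a single equation in ``r`` that is solved here with a safeguarded
Newton iteration.

All angles at this interface are in degrees; lengths are in micrometres
(any consistent length unit works — outputs scale accordingly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .errors import DomainError

__all__ = [
    "EllipseSpec",
    "TiltedCylinderSection",
    "SAESolution",
    "ellipse_area",
    "ellipse_perimeter_series",
    "ellipse_perimeter_exact",
    "truncated_perimeter_given_area",
    "solve_sae",
    "solve_sae_batch",
    "tilt_angle",
    "overestimation_factor",
    "circle_diameter_from_area",
    "circle_diameter_from_perimeter",
]


@dataclass(frozen=True)
class EllipseSpec:
    """An ellipse given by its semi-minor radius ``r`` and semi-major ``R``.

    Invariant: ``0 < r <= R``.
    """

    r: float
    R: float

    def __post_init__(self) -> None:
        if not (self.r > 0 and self.R > 0):
            raise DomainError(f"radii must be positive, got r={self.r}, R={self.R}")
        if self.r > self.R * (1 + 1e-12):
            raise DomainError(f"semi-minor r={self.r} exceeds semi-major R={self.R}")

    @property
    def h(self) -> float:
        """Eccentricity-like series parameter ``(R - r)^2 / (R + r)^2`` in [0, 1)."""
        return ((self.R - self.r) / (self.R + self.r)) ** 2


@dataclass(frozen=True)
class TiltedCylinderSection:
    """Cross-section of a circular cylinder cut at ``tilt_angle`` degrees."""

    base_radius: float
    tilt_angle: float

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise DomainError(f"base_radius must be positive, got {self.base_radius}")
        if not (0.0 <= self.tilt_angle < 90.0):
            raise DomainError(f"tilt_angle must lie in [0, 90), got {self.tilt_angle}")

    @property
    def semi_major(self) -> float:
        return self.base_radius / math.cos(math.radians(self.tilt_angle))

    def ellipse(self) -> EllipseSpec:
        return EllipseSpec(r=self.base_radius, R=self.semi_major)


@dataclass(frozen=True)
class SAESolution:
    """Result of inverting (area, perimeter) to the generating ellipse.

    ``feasible`` is False only when the input perimeter falls below the
    isoperimetric bound ``2 * sqrt(pi * area)``: no ellipse exists, and the
    circle-equivalent radius is reported with zero tilt instead.
    """

    minor_radius: float
    major_radius: float
    tilt_angle: float
    rho: float
    h: float
    iterations: int
    converged: bool
    feasible: bool

    @property
    def minor_diameter(self) -> float:
        return 2.0 * self.minor_radius


def ellipse_area(spec: EllipseSpec) -> float:
    """Area ``pi * r * R`` of the ellipse."""
    return math.pi * spec.r * spec.R


def ellipse_perimeter_series(spec: EllipseSpec, n_terms: int = 4) -> float:
    """Gauss–Kummer partial sum for the ellipse perimeter.

    ``p = pi (r + R) * sum_{n<n_terms} binom(1/2, n)^2 h^n``.  Every term is
    non-negative, so the partial sums increase monotonically to the exact
    perimeter.
    """
    if n_terms < 1:
        raise DomainError(f"n_terms must be >= 1, got {n_terms}")
    h = spec.h
    n = np.arange(n_terms)
    coef = special.binom(0.5, n) ** 2
    return math.pi * (spec.r + spec.R) * float(np.sum(coef * h**n))


def ellipse_perimeter_exact(spec: EllipseSpec) -> float:
    """Exact perimeter ``4 R E(e^2)`` via the complete elliptic integral."""
    m = 1.0 - (spec.r / spec.R) ** 2
    return 4.0 * spec.R * float(special.ellipe(m))


def _series_coefficients(n_terms: int) -> np.ndarray:
    n = np.arange(n_terms)
    return special.binom(0.5, n) ** 2


def truncated_perimeter_given_area(r: float, area: float, n_terms: int = 4) -> float:
    """Perimeter of the ellipse with semi-minor ``r`` and area ``area``.

    Substitutes ``R = area / (pi r)`` into the truncated Gauss–Kummer series,
    with ``h = ((area - pi r^2) / (area + pi r^2))^2``.  The default four
    terms carry coefficients 1, 1/4, 1/64, 1/256.
    """
    if r <= 0 or area <= 0:
        raise DomainError(f"r and area must be positive, got r={r}, area={area}")
    c = math.pi * r * r
    if c > area * (1 + 1e-12):
        raise DomainError(
            f"pi*r^2 = {c:.6g} exceeds area = {area:.6g}: r would exceed R"
        )
    h = ((area - c) / (area + c)) ** 2
    coef = _series_coefficients(n_terms)
    s = float(np.sum(coef * h ** np.arange(n_terms)))
    return math.pi * (area / (math.pi * r) + r) * s


def _trunc_perimeter_and_grad(
    r: float, area: float, n_terms: int
) -> tuple[float, float]:
    """Truncated perimeter and its derivative with respect to ``r``."""
    c = math.pi * r * r
    u = (area - c) / (area + c)
    h = u * u
    k = np.arange(n_terms)
    coef = _series_coefficients(n_terms)
    s = float(np.sum(coef * h**k))
    ds_dh = float(np.sum(k[1:] * coef[1:] * h ** (k[1:] - 1)))
    dh_dr = -8.0 * math.pi * area * r * u / (area + c) ** 2
    lin = area / r + math.pi * r  # pi * (R + r)
    p = lin * s
    dp = (math.pi - area / (r * r)) * s + lin * ds_dh * dh_dr
    return p, dp


def solve_sae(
    area: float,
    perimeter: float,
    tolerance: float = 1e-10,
    max_iter: int = 100,
    n_terms: int = 4,
) -> SAESolution:
    """Recover the semi-minor radius of the ellipse with the given area and
    perimeter (the SAE inversion).

    A safeguarded Newton iteration solves ``p_trunc(r; area) = perimeter`` on
    ``(0, sqrt(area/pi)]``, starting from the circle-equivalent radius
    ``r0 = sqrt(area/pi)`` (an upper bound for the root).  The residual is
    strictly decreasing in ``r`` on that interval, so any Newton step that
    escapes the current bracket is replaced by a bisection step.

    Perimeters below the isoperimetric bound ``2 sqrt(pi * area)`` cannot
    arise from any ellipse; such inputs are clamped to the circle-equivalent
    solution with ``feasible=False``.
    """
    if area <= 0 or perimeter <= 0:
        raise DomainError(
            f"area and perimeter must be positive, got area={area}, perimeter={perimeter}"
        )
    r0 = math.sqrt(area / math.pi)
    p_min = 2.0 * math.sqrt(math.pi * area)
    if perimeter <= p_min * (1 + 1e-15):
        feasible = perimeter >= p_min * (1 - 1e-12)
        return SAESolution(
            minor_radius=r0,
            major_radius=r0,
            tilt_angle=0.0,
            rho=1.0,
            h=0.0,
            iterations=0,
            converged=True,
            feasible=feasible,
        )

    lo, hi = 0.0, r0  # residual > 0 as r -> 0+, <= 0 at r0
    r = r0
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        p, dp = _trunc_perimeter_and_grad(r, area, n_terms)
        f = p - perimeter
        if f > 0:
            lo = r
        else:
            hi = r
        if f == 0.0:
            converged = True
            break
        if dp != 0 and math.isfinite(dp):
            r_new = r - f / dp
        else:
            r_new = 0.5 * (lo + hi)
        if not (lo < r_new <= hi) or not math.isfinite(r_new):
            r_new = 0.5 * (lo + hi)
        if abs(r_new - r) <= tolerance * max(r_new, 1e-300):
            r = r_new
            converged = True
            break
        r = r_new

    R = area / (math.pi * r)
    if R < r:  # floating-point guard near the circular limit
        R = r
    ratio = min(1.0, r / R)
    theta = math.degrees(math.acos(ratio))
    return SAESolution(
        minor_radius=r,
        major_radius=R,
        tilt_angle=theta,
        rho=R / r,
        h=((R - r) / (R + r)) ** 2,
        iterations=iterations,
        converged=converged,
        feasible=True,
    )


def solve_sae_batch(
    areas,
    perimeters,
    tolerance: float = 1e-10,
    max_iter: int = 100,
    n_terms: int = 4,
) -> pd.DataFrame:
    """Vectorised convenience wrapper around :func:`solve_sae` for tables.

    Returns a DataFrame with columns ``sae_diameter``, ``sae_minor_radius``,
    ``sae_major_radius``, ``tilt_angle``, ``rho``, ``sae_converged`` and
    ``sae_feasible``, aligned with the inputs.
    """
    areas = np.asarray(areas, dtype=float)
    perimeters = np.asarray(perimeters, dtype=float)
    if areas.shape != perimeters.shape:
        raise DomainError("areas and perimeters must have matching shapes")
    rows = []
    for a, p in zip(areas.ravel(), perimeters.ravel()):
        sol = solve_sae(a, p, tolerance=tolerance, max_iter=max_iter, n_terms=n_terms)
        rows.append(
            (
                sol.minor_diameter,
                sol.minor_radius,
                sol.major_radius,
                sol.tilt_angle,
                sol.rho,
                sol.converged,
                sol.feasible,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sae_diameter",
            "sae_minor_radius",
            "sae_major_radius",
            "tilt_angle",
            "rho",
            "sae_converged",
            "sae_feasible",
        ],
    )


def tilt_angle(r: float, R: float) -> float:
    """Dispersion angle ``arccos(r / R)`` in degrees, from the two semi-axes."""
    if r <= 0 or R <= 0:
        raise DomainError(f"radii must be positive, got r={r}, R={R}")
    if r > R * (1 + 1e-12):
        raise DomainError(f"r={r} exceeds R={R}")
    return math.degrees(math.acos(min(1.0, r / R)))


def overestimation_factor(tilt_angle_deg: float) -> float:
    """Area inflation factor ``rho = 1 / cos(theta)`` = ellipse / base-circle area."""
    if not (0.0 <= tilt_angle_deg < 90.0):
        raise DomainError(f"tilt angle must lie in [0, 90), got {tilt_angle_deg}")
    return 1.0 / math.cos(math.radians(tilt_angle_deg))


def circle_diameter_from_area(area: float) -> float:
    """Diameter of the circle with the given area: ``2 sqrt(area / pi)``."""
    if area <= 0:
        raise DomainError(f"area must be positive, got {area}")
    return 2.0 * math.sqrt(area / math.pi)


def circle_diameter_from_perimeter(perimeter: float) -> float:
    """Diameter of the circle with the given perimeter: ``perimeter / pi``."""
    if perimeter <= 0:
        raise DomainError(f"perimeter must be positive, got {perimeter}")
    return perimeter / math.pi
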