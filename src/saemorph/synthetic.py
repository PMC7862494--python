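"""Ground-truth generator: tilted-cylinder sections and fiber populations.

Every fiber is a circular cylinder of known base diameter cut at a known
dispersion (tilt) angle, so its cross-section contour is an ellipse polygon
whose true minor diameter is exactly the base diameter.  Populations mix
several Gaussian size components (emulating the alpha-motor, gamma-motor and
small autonomic fiber classes of lumbosacral ventral roots), draw tilt
angles from a configurable model, and attach a concentric inner (axon)
contour scaled by a per-fiber g-ratio whose mean rises linearly with fiber
diameter.

Boundary noise is multiplicative and radial: each vertex radius is scaled by
``1 + noise * u`` with ``u ~ uniform(-1, 1)`` drawn per vertex.  Because the
perturbation is independent vertex to vertex, its effect on the measured
perimeter depends on vertex spacing; the default vertex count is kept at
manual-tracing granularity (see the methods note) so the model behaves like
click-placement jitter rather than a fractal boundary.

Everything is driven by a seeded :class:`numpy.random.Generator`, so fixtures
are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contours import Contour
from .errors import DomainError

__all__ = [
    "UniformTilt",
    "FoldedNormalTilt",
    "GRatioModel",
    "SizeComponent",
    "PopulationSpec",
    "SyntheticFiber",
    "render_ellipse_contour",
    "sample_population",
    "write_fixture",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class UniformTilt:
    """Tilt angles uniform on [0, theta_max] degrees."""

    theta_max: float = 60.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_max < 90.0):
            raise DomainError(f"theta_max must lie in [0, 90), got {self.theta_max}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(0.0, self.theta_max, size=n)


@dataclass(frozen=True)
class FoldedNormalTilt:
    """Tilt angles |N(0, sigma)| degrees, clipped below 89 degrees."""

    sigma: float = 20.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise DomainError(f"sigma must be positive, got {self.sigma}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.clip(np.abs(rng.normal(0.0, self.sigma, size=n)), 0.0, 89.0)


@dataclass(frozen=True)
class GRatioModel:
    """Mean g-ratio rises linearly with fiber diameter; draws are clipped.

    Defaults give g ~ 0.62-0.67 across the 2-12 um fiber range, in the
    physiological band, with a positive diameter correlation.
    """

    intercept: float = 0.60
    slope: float = 0.006  # per micrometre of fiber diameter
    sd: float = 0.04
    clip: tuple[float, float] = (0.05, 0.95)

    def sample(self, rng: np.random.Generator, fiber_diameters: np.ndarray) -> np.ndarray:
        mean = self.intercept + self.slope * fiber_diameters
        return np.clip(rng.normal(mean, self.sd), *self.clip)


@dataclass(frozen=True)
class SizeComponent:
    """One Gaussian mode of the fiber-diameter mixture (diameters in um)."""

    weight: float
    mean_diameter: float
    sd: float


# Default mixture loosely modelled on lumbosacral ventral root composition:
# small preganglionic autonomic (~2.5 um), gamma-motor (~4 um) and
# alpha-motor (~11 um) myelinated fibers.
_DEFAULT_COMPONENTS = (
    SizeComponent(0.25, 2.5, 0.4),
    SizeComponent(0.30, 4.0, 0.7),
    SizeComponent(0.45, 11.0, 1.8),
)


@dataclass(frozen=True)
class PopulationSpec:
    """Mixture + tilt + noise model describing a synthetic fiber population."""

    components: tuple[SizeComponent, ...] = _DEFAULT_COMPONENTS
    tilt_model: object = UniformTilt(60.0)
    g_ratio_model: GRatioModel = field(default_factory=GRatioModel)
    boundary_noise: float = 0.02
    vertices_per_contour: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.components:
            raise DomainError("at least one size component is required")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise DomainError(f"component weights must sum to 1, got {total}")
        for c in self.components:
            if c.mean_diameter - 3.0 * c.sd <= 0:
                raise DomainError(
                    f"component mean {c.mean_diameter} um is not > 3 sd ({c.sd} um)"
                )
        if not (0.0 <= self.boundary_noise < 1.0):
            raise DomainError(f"boundary_noise must lie in [0, 1), got {self.boundary_noise}")
        if self.vertices_per_contour < 32:
            raise DomainError(
                f"vertices_per_contour must be >= 32, got {self.vertices_per_contour}"
            )


@dataclass
class SyntheticFiber:
    """One generated fiber with its ground truth and both contours."""

    id: str
    true_base_diameter: float
    tilt_angle: float
    true_g_ratio: float
    outer_contour: Contour
    inner_contour: Contour
    component_label: int


def render_ellipse_contour(
    r: float,
    tilt: float,
    orientation: float = 0.0,
    center: tuple[float, float] = (0.0, 0.0),
    n_vertices: int = 360,
    noise: float = 0.0,
    rng=None,
    structure_type: str = "fiber_outer",
    contour_id=None,
) -> Contour:
    """Polygonal cross-section of a cylinder of base radius ``r`` (um) cut at
    ``tilt`` degrees.

    The ellipse has semi-axes ``(r / cos(tilt), r)`` (major along x before
    the ``orientation`` rotation is applied).  With ``noise > 0`` every
    vertex radius is multiplied by ``1 + noise * u``, ``u ~ uniform(-1, 1)``;
    noise below 1 keeps the polygon star-shaped, hence simple.
    """
    if r <= 0:
        raise DomainError(f"radius must be positive, got {r}")
    if not (0.0 <= tilt < 90.0):
        raise DomainError(f"tilt must lie in [0, 90), got {tilt}")
    if n_vertices < 32:
        raise DomainError(f"n_vertices must be >= 32, got {n_vertices}")
    if not (0.0 <= noise < 1.0):
        raise DomainError(f"noise must lie in [0, 1), got {noise}")
    rng = _as_rng(rng)
    t = 2.0 * math.pi * np.arange(n_vertices) / n_vertices
    major = r / math.cos(math.radians(tilt))
    xy = np.column_stack([major * np.cos(t), r * np.sin(t)])
    if noise > 0:
        xy *= (1.0 + noise * rng.uniform(-1.0, 1.0, size=n_vertices))[:, None]
    phi = math.radians(orientation)
    rot = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
    xy = xy @ rot.T + np.asarray(center, dtype=float)
    return Contour(vertices=xy, structure_type=structure_type, id=contour_id)


def sample_population(spec: PopulationSpec, n: int, rng=None) -> list[SyntheticFiber]:
    """Draw ``n`` fibers from the population model.

    Fibers are laid out on a jittered square grid so centroids are distinct
    and axon/fiber pairing has an unambiguous ground truth.  The inner
    contour is the outer one scaled by the fiber's g-ratio about the shared
    centroid.
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    rng = _as_rng(spec.seed if rng is None else rng)
    weights = np.array([c.weight for c in spec.components])
    means = np.array([c.mean_diameter for c in spec.components])
    sds = np.array([c.sd for c in spec.components])

    comp = rng.choice(len(weights), size=n, p=weights)
    diam = np.maximum(rng.normal(means[comp], sds[comp]), 1e-3)
    tilt = np.asarray(spec.tilt_model.sample(rng, n), dtype=float)
    orient = rng.uniform(0.0, 180.0, size=n)
    g = spec.g_ratio_model.sample(rng, diam)

    side = math.ceil(math.sqrt(n))
    spacing = 3.0 * float(means.max())
    jitter = rng.uniform(-0.25 * spacing, 0.25 * spacing, size=(n, 2))

    fibers: list[SyntheticFiber] = []
    for i in range(n):
        cx = (i % side) * spacing + jitter[i, 0]
        cy = (i // side) * spacing + jitter[i, 1]
        fid = f"f{i:05d}"
        outer = render_ellipse_contour(
            r=diam[i] / 2.0,
            tilt=tilt[i],
            orientation=orient[i],
            center=(cx, cy),
            n_vertices=spec.vertices_per_contour,
            noise=spec.boundary_noise,
            rng=rng,
            structure_type="fiber_outer",
            contour_id=fid,
        )
        centroid = np.array([cx, cy])
        inner_vertices = centroid + g[i] * (outer.vertices - centroid)
        inner = Contour(vertices=inner_vertices, structure_type="axon_inner", id=fid)
        fibers.append(
            SyntheticFiber(
                id=fid,
                true_base_diameter=float(diam[i]),
                tilt_angle=float(tilt[i]),
                true_g_ratio=float(g[i]),
                outer_contour=outer,
                inner_contour=inner,
                component_label=int(comp[i]),
            )
        )
    return fibers


def truth_table(fibers: list[SyntheticFiber]) -> pd.DataFrame:
    """Ground-truth table for a generated population."""
    return pd.DataFrame(
        [
            {
                "id": f.id,
                "component_label": f.component_label,
                "true_base_diameter": f.true_base_diameter,
                "tilt_angle": f.tilt_angle,
                "true_g_ratio": f.true_g_ratio,
            }
            for f in fibers
        ],
        columns=["id", "component_label", "true_base_diameter", "tilt_angle", "true_g_ratio"],
    )


def write_fixture(fibers: list[SyntheticFiber], directory) -> dict[str, Path]:
    """Persist a population as ``contours.jsonl`` + ``truth.csv``.

    Outer and inner contours share the fiber id and are told apart by their
    ``structure_type``.  Both files round-trip losslessly through
    :mod:`saemorph.io` (vertices are serialised at full double precision).
    """
    from . import io as io_mod

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    contours_path = directory / "contours.jsonl"
    truth_path = directory / "truth.csv"
    contours = []
    for f in fibers:
        contours.append(f.outer_contour)
        contours.append(f.inner_contour)
    io_mod.write_contours(contours, contours_path)
    truth_table(fibers).to_csv(truth_path, index=False)
    return {"contours": contours_path, "truth": truth_path}
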