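"""Shared fixtures: analytic ellipse helpers and session-scoped populations."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import saemorph as sm
from saemorph.contours import measure_contours
from saemorph.ellipse import solve_sae_batch


def analytic_ellipse_measurements(r: float, theta_deg: float) -> sm.ContourMeasurements:
    """Exact measurements of the tilted-cylinder section (elliptic-integral
    perimeter), the continuous-geometry oracle for polygon-based code paths."""
    R = r / math.cos(math.radians(theta_deg))
    spec = sm.EllipseSpec(r, R)
    return sm.ContourMeasurements(
        area=sm.ellipse_area(spec),
        perimeter=sm.ellipse_perimeter_exact(spec),
        centroid=(0.0, 0.0),
        feret_max=2.0 * R,
        feret_min=2.0 * r,
    )


def sae_table(contours) -> pd.DataFrame:
    """Measure contours and append the SAE solution columns."""
    meas = measure_contours(contours)
    sol = solve_sae_batch(meas["area"], meas["perimeter"])
    return pd.concat([meas, sol], axis=1)


BIMODAL_COMPONENTS = (
    sm.SizeComponent(0.5, 3.0, 0.5),
    sm.SizeComponent(0.5, 10.0, 1.0),
)

POPULATION_SEED = 20210204


def _population(noise: float, vertices: int, n: int = 2000) -> dict:
    spec = sm.PopulationSpec(
        components=BIMODAL_COMPONENTS,
        tilt_model=sm.UniformTilt(60.0),
        boundary_noise=noise,
        vertices_per_contour=vertices,
        seed=POPULATION_SEED,
    )
    fibers = sm.sample_population(spec, n)
    meas = measure_contours([f.outer_contour for f in fibers])
    per_fiber = sm.method_diameters(meas)
    truth = np.array([f.true_base_diameter for f in fibers])
    tilts = np.array([f.tilt_angle for f in fibers])
    return {"fibers": fibers, "measurements": meas, "per_fiber": per_fiber,
            "truth": truth, "tilts": tilts}


@pytest.fixture(scope="session")
def noiseless_population() -> dict:
    """Bimodal (3, 10 um) tilted population, exact contours (fine polygons)."""
    return _population(noise=0.0, vertices=360)


@pytest.fixture(scope="session")
def noisy_population() -> dict:
    """Same population with 2% radial boundary noise at tracing-click vertex
    density (the generator default)."""
    return _population(noise=0.02, vertices=32)
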