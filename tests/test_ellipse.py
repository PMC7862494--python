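"""Ellipse geometry and the SAE inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

import saemorph as sm
from saemorph.errors import DomainError


class TestForwardFormulas:
    @pytest.mark.parametrize(
        "r, R, expected",
        [(1, 1, math.pi), (2, 3, 6 * math.pi), (1, 2, 2 * math.pi)],
    )
    def test_area(self, r, R, expected):
        assert sm.ellipse_area(sm.EllipseSpec(r, R)) == pytest.approx(expected, rel=1e-14)

    @pytest.mark.parametrize("n_terms", [1, 4, 20])
    def test_circle_perimeter_any_truncation(self, n_terms):
        assert sm.ellipse_perimeter_series(sm.EllipseSpec(1, 1), n_terms) == pytest.approx(
            2 * math.pi, rel=1e-14
        )

    def test_four_term_series_value(self):
        assert sm.ellipse_perimeter_series(sm.EllipseSpec(1, 2), 4) == pytest.approx(
            9.6884459, abs=1e-6
        )

    def test_long_series_matches_elliptic_integral(self):
        exact = 4 * 2 * special.ellipe(1 - 0.25)  # 4 R E(1 - (r/R)^2)
        assert sm.ellipse_perimeter_series(sm.EllipseSpec(1, 2), 20) == pytest.approx(
            exact, abs=1e-9
        )
        assert sm.ellipse_perimeter_exact(sm.EllipseSpec(1, 2)) == pytest.approx(exact, rel=1e-12)

    @pytest.mark.parametrize("r, R", [(1, 2), (1, 5), (0.3, 4)])
    def test_series_monotone_in_terms(self, r, R):
        spec = sm.EllipseSpec(r, R)
        vals = [sm.ellipse_perimeter_series(spec, n) for n in range(1, 30)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert sm.ellipse_perimeter_series(spec, 200) == pytest.approx(
            sm.ellipse_perimeter_exact(spec), rel=1e-9
        )

    def test_invalid_spec(self):
        with pytest.raises(DomainError):
            sm.EllipseSpec(-1, 2)
        with pytest.raises(DomainError):
            sm.EllipseSpec(3, 2)


class TestTruncatedPerimeter:
    def test_circle(self):
        assert sm.truncated_perimeter_given_area(1, math.pi) == pytest.approx(
            2 * math.pi, rel=1e-14
        )

    def test_matches_series_after_substitution(self):
        # R = area / (pi r): (r=1, A=2pi) -> R=2; (r=0.5, A=pi) -> R=2
        assert sm.truncated_perimeter_given_area(1, 2 * math.pi) == pytest.approx(
            sm.ellipse_perimeter_series(sm.EllipseSpec(1, 2), 4), rel=1e-13
        )
        assert sm.truncated_perimeter_given_area(0.5, math.pi) == pytest.approx(
            sm.ellipse_perimeter_series(sm.EllipseSpec(0.5, 2), 4), rel=1e-13
        )

    def test_r_exceeding_circle_radius_rejected(self):
        with pytest.raises(DomainError):
            sm.truncated_perimeter_given_area(2, math.pi)


class TestSolveSAE:
    def test_circle(self):
        sol = sm.solve_sae(math.pi, 2 * math.pi)
        assert sol.minor_diameter == pytest.approx(2.0, rel=1e-10)
        assert sol.tilt_angle == pytest.approx(0.0, abs=1e-8)
        assert sol.rho == pytest.approx(1.0, rel=1e-10)
        assert sol.feasible and sol.converged

    def test_tilted_section(self):
        sol = sm.solve_sae(2 * math.pi, 9.68846)
        assert sol.minor_diameter == pytest.approx(2.0, rel=1e-4)
        assert sol.major_radius == pytest.approx(2.0, rel=1e-4)
        assert sol.tilt_angle == pytest.approx(60.0, abs=0.01)
        assert sol.rho == pytest.approx(2.0, rel=1e-4)

    def test_sub_isoperimetric_input_clamped(self):
        sol = sm.solve_sae(math.pi, 6.0)  # no ellipse has p < 2 sqrt(pi A)
        assert not sol.feasible
        assert sol.minor_diameter == pytest.approx(2.0, rel=1e-12)
        assert sol.tilt_angle == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            sm.solve_sae(-1.0, 5.0)
        with pytest.raises(DomainError):
            sm.solve_sae(1.0, 0.0)

    @pytest.mark.parametrize("r", [0.5, 1, 2, 6])
    @pytest.mark.parametrize("theta", [0, 30, 45, 60, 75])
    def test_round_trip_recovery(self, r, theta):
        """Analytic area + elliptic-integral perimeter recover 2r to 0.1%."""
        R = r / math.cos(math.radians(theta))
        area = math.pi * r * R
        perimeter = sm.ellipse_perimeter_exact(sm.EllipseSpec(r, R))
        sol = sm.solve_sae(area, perimeter)
        assert sol.converged
        assert sol.minor_diameter == pytest.approx(2 * r, rel=1e-3)
        assert sol.tilt_angle == pytest.approx(theta, abs=0.2)

    def test_newton_agrees_with_bisection_oracle(self):
        """Safeguarded Newton and plain bisection find the same root of the
        truncated-perimeter residual on 500 random feasible inputs."""
        rng = np.random.default_rng(42)
        for _ in range(500):
            r = rng.uniform(0.2, 8.0)
            theta = rng.uniform(0.5, 80.0)
            R = r / math.cos(math.radians(theta))
            area = math.pi * r * R
            perimeter = sm.truncated_perimeter_given_area(r, area)
            lo, hi = 1e-12, math.sqrt(area / math.pi)
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if sm.truncated_perimeter_given_area(mid, area) > perimeter:
                    lo = mid
                else:
                    hi = mid
            oracle = 0.5 * (lo + hi)
            sol = sm.solve_sae(area, perimeter)
            assert sol.minor_radius == pytest.approx(oracle, rel=1e-8)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        r=st.floats(0.1, 20.0),
        ratio=st.floats(1.0, 10.0),
    )
    def test_round_trip_property(self, r, ratio):
        R = r * ratio
        area = math.pi * r * R
        perimeter = sm.ellipse_perimeter_exact(sm.EllipseSpec(r, R))
        sol = sm.solve_sae(area, perimeter)
        assert sol.feasible
        assert sol.minor_diameter == pytest.approx(2 * r, rel=1e-2)


class TestDerivedQuantities:
    @pytest.mark.parametrize(
        "r, R, expected",
        [(1, 1, 0.0), (1, 2, 60.0), (1, math.sqrt(2), 45.0)],
    )
    def test_tilt_angle(self, r, R, expected):
        assert sm.tilt_angle(r, R) == pytest.approx(expected, abs=1e-9)

    def test_tilt_angle_domain(self):
        with pytest.raises(DomainError):
            sm.tilt_angle(2, 1)
        with pytest.raises(DomainError):
            sm.tilt_angle(0, 1)

    @pytest.mark.parametrize(
        "theta, expected", [(0, 1.0), (60, 2.0), (45, math.sqrt(2))]
    )
    def test_overestimation_factor(self, theta, expected):
        assert sm.overestimation_factor(theta) == pytest.approx(expected, rel=1e-12)

    def test_overestimation_factor_domain(self):
        with pytest.raises(DomainError):
            sm.overestimation_factor(90.0)
        with pytest.raises(DomainError):
            sm.overestimation_factor(-1.0)

    def test_rho_matches_area_ratio(self):
        # rho = Ae / Ac for the tilted-cylinder section
        sec = sm.TiltedCylinderSection(base_radius=1.5, tilt_angle=55.0)
        ae = sm.ellipse_area(sec.ellipse())
        ac = math.pi * sec.base_radius**2
        assert sm.overestimation_factor(55.0) == pytest.approx(ae / ac, rel=1e-12)

    def test_rho_strictly_increasing_and_convex(self):
        theta = np.arange(0.0, 89.0, 1.0)
        rho = np.array([sm.overestimation_factor(t) for t in theta])
        assert np.all(np.diff(rho) > 0)
        assert np.all(np.diff(rho, 2) > 0)

    @pytest.mark.parametrize(
        "area, expected", [(math.pi, 2.0), (2 * math.pi, 2 * math.sqrt(2)), (4 * math.pi, 4.0)]
    )
    def test_circle_diameter_from_area(self, area, expected):
        assert sm.circle_diameter_from_area(area) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "p, expected", [(2 * math.pi, 2.0), (9.68846, 3.0839326), (math.pi, 1.0)]
    )
    def test_circle_diameter_from_perimeter(self, p, expected):
        assert sm.circle_diameter_from_perimeter(p) == pytest.approx(expected, rel=1e-6)


class TestDiameterChain:
    def test_sae_below_area_circle_below_perimeter_circle(self):
        """sae <= area-circle <= perimeter-circle, equality only for circles."""
        for r in (0.25, 0.5, 1, 2, 4, 8):
            for theta in range(0, 76, 5):
                R = r / math.cos(math.radians(theta))
                area = math.pi * r * R
                perimeter = sm.ellipse_perimeter_exact(sm.EllipseSpec(r, R))
                d_sae = sm.solve_sae(area, perimeter).minor_diameter
                d_area = sm.circle_diameter_from_area(area)
                d_perim = sm.circle_diameter_from_perimeter(perimeter)
                if theta == 0:
                    assert d_sae == pytest.approx(d_area, rel=1e-9)
                    assert d_area == pytest.approx(d_perim, rel=1e-9)
                else:
                    assert d_sae < d_area < d_perim
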