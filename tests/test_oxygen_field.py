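import numpy as np
import pytest

from spheroidox.geometry import Shape, SpheroidGeometry
from spheroidox.oxygen import (
    FullyOxygenatedError,
    OxygenModelParams,
    boundary_bracket,
    contour_map,
    minimum_ocr_for_anoxia,
    pressure,
    profile,
    solve_anoxic_geometry,
)
from spheroidox.ocr import estimate_ocr

UM = 1e-6


class TestSphereBranch:
    def test_outer_surface_pressure(self, params):
        g = solve_anoxic_geometry(Shape.SPHERE, 500 * UM, 0.0, params)
        assert pressure(g, params, g.r_o, 0.7) == pytest.approx(100.0, rel=1e-10)

    def test_anoxic_radius_closed_form(self, params):
        # (r_o - r_n)^2 (r_o + 2 r_n) = 6 D p_o r_o / a
        g = solve_anoxic_geometry(Shape.SPHERE, 500 * UM, 0.0, params)
        lhs = (g.r_o - g.r_n) ** 2 * (g.r_o + 2 * g.r_n)
        rhs = 6 * params.D * params.p_o * g.r_o / params.a
        assert lhs == pytest.approx(rhs, rel=1e-10)
        assert g.r_n == pytest.approx(341 * UM, abs=1 * UM)

    def test_fully_oxygenated_threshold(self, params):
        assert minimum_ocr_for_anoxia(500 * UM, params) == pytest.approx(4.8)
        with pytest.raises(FullyOxygenatedError):
            solve_anoxic_geometry(Shape.SPHERE, 500 * UM, 0.0, params.with_a(4.0))

    def test_clamped_inside_core(self, params):
        g = solve_anoxic_geometry(Shape.SPHERE, 500 * UM, 0.0, params)
        assert pressure(g, params, 0.5 * g.r_n, 1.0) == 0.0
        assert pressure(g, params, 0.0, 0.0) == 0.0


class TestBoundaryConditions:
    @pytest.mark.parametrize("shape", [Shape.PROLATE, Shape.OBLATE])
    def test_anoxic_shell_pressure_zero_everywhere(self, shape, params):
        g = solve_anoxic_geometry(shape, 500 * UM, 0.5, params)
        b_n = g.b_n
        for t in np.linspace(0, np.pi, 100):
            # parametric point of the anoxic shell
            if shape == Shape.PROLATE:
                z, rho = g.r_n * np.cos(t), b_n * np.sin(t)
            else:
                z, rho = b_n * np.cos(t), g.r_n * np.sin(t)
            r, th = np.hypot(rho, z), np.arctan2(rho, z)
            # evaluate just outside the shell to dodge the core clamp
            P = pressure(g, params, r * 1.0000001, th, clamp=False)
            assert abs(P) < 1e-6 * params.p_o

    @pytest.mark.parametrize("shape", [Shape.PROLATE, Shape.OBLATE])
    def test_outer_anchor_pressure(self, shape, params):
        # the outer boundary value is pinned at the semi-minor vertex
        g = solve_anoxic_geometry(shape, 500 * UM, 0.5, params)
        theta_minor = np.pi / 2 if shape == Shape.PROLATE else 0.0
        P = pressure(g, params, g.b_o, theta_minor)
        assert P == pytest.approx(params.p_o, rel=1e-10)

    @pytest.mark.parametrize("shape", [Shape.PROLATE, Shape.OBLATE])
    def test_zero_normal_derivative_on_axes(self, shape, params):
        # numerical radial derivative at the anoxic boundary, on both axes
        g = solve_anoxic_geometry(shape, 500 * UM, 0.5, params)
        h = 1e-9
        if shape == Shape.PROLATE:
            points = ((g.r_n, 0.0), (g.b_n, np.pi / 2))
        else:  # oblate: the semi-major axis is equatorial
            points = ((g.b_n, 0.0), (g.r_n, np.pi / 2))
        for axis_r, th in points:
            d = (pressure(g, params, axis_r + 2 * h, th, clamp=False)
                 - pressure(g, params, axis_r + h, th, clamp=False)) / h
            # compare against the interior pressure scale per metre
            scale = params.p_o / (g.r_o - g.r_n)
            assert abs(d) < 1e-3 * scale


class TestSphereLimit:
    @pytest.mark.parametrize("shape", [Shape.PROLATE, Shape.OBLATE])
    @pytest.mark.parametrize("ratio", [1e-3, 1e-4])
    def test_near_sphere_fields_agree(self, shape, ratio, params, rng):
        r_o, r_n = 500 * UM, 340 * UM
        f = ratio * r_n
        g = SpheroidGeometry(shape, r_o, r_n, f)
        gs = SpheroidGeometry(Shape.SPHERE, r_o, r_n, 0.0)
        rs = rng.uniform(r_n * 1.02, r_o, 1000)
        ths = rng.uniform(0, np.pi, 1000)
        for r, th in zip(rs, ths):
            pe = pressure(g, params, r, th)
            ps = pressure(gs, params, r, th)
            assert pe == pytest.approx(ps, rel=1e-4, abs=1e-4 * params.p_o)

    def test_tiny_focus_matches_sphere_closely(self, params):
        # f -> 1e-9 * r_n: ellipsoidal branch equals the sphere branch
        r_o, r_n = 500 * UM, 340 * UM
        g = SpheroidGeometry(Shape.PROLATE, r_o, r_n, 1e-9 * r_n)
        gs = SpheroidGeometry(Shape.SPHERE, r_o, r_n, 0.0)
        for r, th in [(400 * UM, 0.3), (450 * UM, 1.2), (480 * UM, 2.6)]:
            assert pressure(g, params, r, th) == pytest.approx(
                pressure(gs, params, r, th), rel=1e-6
            )


class TestMonotonicityAndShape:
    @pytest.mark.parametrize("shape", [Shape.PROLATE, Shape.OBLATE])
    @pytest.mark.parametrize("theta", [0.0, 0.6, np.pi / 2])
    def test_pressure_nondecreasing_outward(self, shape, theta, params):
        g = solve_anoxic_geometry(shape, 500 * UM, 0.6, params)
        # march along the ray to the outer surface
        if shape == Shape.PROLATE:
            r_surf = 1.0 / np.hypot(np.cos(theta) / g.r_o, np.sin(theta) / g.b_o)
        else:
            r_surf = 1.0 / np.hypot(np.cos(theta) / g.b_o, np.sin(theta) / g.r_o)
        rs = np.linspace(0, r_surf, 120)
        Ps = [pressure(g, params, r, theta) for r in rs]
        assert all(b - a >= -1e-9 * params.p_o for a, b in zip(Ps, Ps[1:]))

    def test_profiles(self, params):
        gs = solve_anoxic_geometry(Shape.SPHERE, 500 * UM, 0.0, params)
        maj = profile(gs, params, "major", 50)
        mino = profile(gs, params, "minor", 50)
        assert [s.P for s in maj] == pytest.approx([s.P for s in mino])

        gp = solve_anoxic_geometry(Shape.PROLATE, 500 * UM, 0.9, params)
        maj = profile(gp, params, "major", 80)
        mino = profile(gp, params, "minor", 80)
        # anoxic extent is longer along the major axis
        r_zero_major = max(s.r for s in maj if s.P <= 1e-9)
        r_zero_minor = max(s.r for s in mino if s.P <= 1e-9)
        assert r_zero_major > r_zero_minor
        # both profiles respect the boundary values
        assert maj[0].P == pytest.approx(0.0, abs=1e-8)
        assert mino[-1].P == pytest.approx(params.p_o, rel=1e-9)

    def test_low_eccentricity_prolate_oblate_overlap(self, params):
        # at e = 0.25 the prolate and oblate axis profiles nearly coincide
        gp = solve_anoxic_geometry(Shape.PROLATE, 500 * UM, 0.25, params)
        go = solve_anoxic_geometry(Shape.OBLATE, 500 * UM, 0.25, params)
        for axis in ("major", "minor"):
            pp = profile(gp, params, axis, 40)
            po = profile(go, params, axis, 40)
            # same axis label, same start/end semi-axes up to < 1% shift;
            # compare pressure at matching fractional positions
            for sp_, so_ in zip(pp, po):
                assert abs(sp_.P - so_.P) < 0.05 * params.p_o


class TestAnoxicGeometrySolver:
    @pytest.mark.parametrize("shape", [Shape.PROLATE, Shape.OBLATE])
    def test_round_trip_with_estimator(self, shape, params):
        g = solve_anoxic_geometry(shape, 500 * UM, 0.5, params)
        method = "prolate" if shape == Shape.PROLATE else "oblate"
        assert estimate_ocr(g, params, method).a == pytest.approx(params.a, rel=1e-8)

    @pytest.mark.parametrize("e", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_anoxic_axes_agree_between_shapes(self, e, params):
        gp = solve_anoxic_geometry(Shape.PROLATE, 500 * UM, e, params)
        go = solve_anoxic_geometry(Shape.OBLATE, 500 * UM, e, params)
        assert abs(gp.r_n - go.r_n) / gp.r_n <= 0.02
        assert abs(gp.b_n - go.b_n) / gp.b_n <= 0.02

    def test_outer_convention(self, params):
        g = solve_anoxic_geometry(Shape.PROLATE, 500 * UM, 0.3, params, convention="outer")
        assert g.f == pytest.approx(0.3 * 500 * UM)
        assert estimate_ocr(g, params, "prolate").a == pytest.approx(params.a, rel=1e-8)


class TestAlternativeCast:
    """The boundary relation can be driven by (r_n, e_n) or recast through
    (r_o, e_o); both parametrisations of the same confocal family must give
    identical fields."""

    @pytest.mark.parametrize("shape", [Shape.PROLATE, Shape.OBLATE])
    def test_casts_agree(self, shape, params):
        g = solve_anoxic_geometry(shape, 500 * UM, 0.55, params)
        # rebuild the geometry from the outer shell's (r_o, e_o)
        f2 = g.e_o * g.r_o
        g2 = SpheroidGeometry(shape, g.r_o, np.hypot(g.b_n, f2), f2)
        assert boundary_bracket(shape, g2.r_o, g2.r_n, g2.f) == pytest.approx(
            boundary_bracket(shape, g.r_o, g.r_n, g.f), rel=1e-10
        )


class TestContourMap:
    def test_sphere_contours_are_circles(self, params):
        g = solve_anoxic_geometry(Shape.SPHERE, 500 * UM, 0.0, params)
        fld = contour_map(g, params, n=61)
        rr = np.hypot(fld.rho, fld.z)
        # pressure depends on radius only
        vals = {}
        for r, p in zip(np.round(rr.ravel(), 9), fld.P.ravel()):
            if np.isnan(p):
                continue
            vals.setdefault(r, []).append(p)
        for r, ps in vals.items():
            assert np.ptp(ps) < 1e-8 * params.p_o

    def test_iso_contours_near_confocal_at_low_eccentricity(self, params):
        """Iso-pressure surfaces are ellipses close to confocal with the
        shells; the agreement is exact on the anoxic shell and degrades
        with eccentricity as the outer-surface nonuniformity grows."""
        from scipy.optimize import brentq

        g = solve_anoxic_geometry(Shape.PROLATE, 500 * UM, 0.3, params)
        # locate the P = 50 mmHg level on both principal axes
        r50_maj = brentq(lambda r: pressure(g, params, r, 0.0) - 50.0, g.r_n, g.r_o)
        r50_min = brentq(lambda r: pressure(g, params, r, np.pi / 2) - 50.0, g.b_n, g.b_o)
        # the level set is accurately elliptical: mid-angle crossing sits on
        # the ellipse through the two axis crossings
        th = np.pi / 4
        r_ell = 1.0 / np.hypot(np.cos(th) / r50_maj, np.sin(th) / r50_min)
        assert pressure(g, params, r_ell, th) == pytest.approx(50.0, abs=0.2)
        # its focal length sits near, though not exactly at, the shell value
        f_level = np.sqrt(r50_maj**2 - r50_min**2)
        assert f_level == pytest.approx(g.f, rel=0.25)

    def test_anoxic_shell_is_exact_contour(self, params):
        # the inner boundary itself is an exactly confocal iso-surface
        g = solve_anoxic_geometry(Shape.PROLATE, 500 * UM, 0.75, params)
        for t in np.linspace(0, np.pi / 2, 25):
            z, rho = g.r_n * np.cos(t), g.b_n * np.sin(t)
            r, th = np.hypot(rho, z), np.arctan2(rho, z)
            assert pressure(g, params, r * 1.0000001, th, clamp=False) == pytest.approx(
                0.0, abs=1e-6 * params.p_o
            )

    def test_anoxic_core_reports_zero(self, params):
        g = solve_anoxic_geometry(Shape.PROLATE, 500 * UM, 0.5, params)
        fld = contour_map(g, params, n=61)
        inside = (fld.rho / g.b_n) ** 2 + (fld.z / g.r_n) ** 2 < 0.95**2
        assert np.all(fld.P[inside] == 0.0)
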