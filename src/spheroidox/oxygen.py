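"""Closed-form steady-state oxygen fields in spherical and spheroidal shells.

Model
-----
Oxygen partial pressure P obeys the steady-state reaction-diffusion
(Poisson) equation

    D lap(P) = a,

with D the oxygen diffusion constant in water (default 2e-9 m^2 s^-1) and
``a`` the volumetric oxygen consumption rate expressed as a partial-pressure
depletion rate (mmHg s^-1).  Consumption is constant in the viable shell and
the central core is anoxic: on the anoxic boundary both the pressure and the
oxygen flux vanish; on the outer surface the pressure equals the external
value p_o.

For a sphere the textbook solution applies,

    P(r) = a/(6 D) * (r^2 + 2 r_n^3 / r - 3 r_n^2),

and evaluating it at r_o links consumption rate to anoxic extent.

For prolate/oblate spheroids the field is built in spheroidal coordinates
(sigma, tau) sharing the focal length f of the confocal shells.  The
particular solution of the Poisson equation is a*r^2/(6D); adding the
axisymmetric harmonics of degree 0 and 2 gives the complete solution family
that can cancel the particular solution's angular content on a coordinate
shell.  The four harmonic coefficients are fixed by requiring P = 0 *and*
dP/dsigma = 0 on the entire anoxic shell; the remaining scale is fixed by
P = p_o at the semi-minor vertex of the outer shell.  The resulting field
satisfies the PDE and the anoxic-boundary conditions exactly; the price of
the closed form is that the outer-surface pressure is uniform only in the
spherical limit — its angular spread grows with eccentricity and is exactly
what the sphericity-error metrics quantify.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from ._legendre import (
    legendre_q0,
    legendre_q2,
    legendre_q2_prime,
    oblate_p2,
    oblate_q0,
    oblate_q2,
    oblate_q2_prime,
)
from .geometry import Shape, SpheroidGeometry, to_spheroidal

__all__ = [
    "OxygenModelParams",
    "PressureSample",
    "PressureField",
    "FullyOxygenatedError",
    "pressure",
    "solve_anoxic_geometry",
    "minimum_ocr_for_anoxia",
    "profile",
    "contour_map",
    "boundary_bracket",
]


@dataclass(frozen=True)
class OxygenModelParams:
    """Physics constants of the oxygen model.

    p_o : external partial pressure at the outer surface, mmHg.
    D   : oxygen diffusion constant, m^2 s^-1.
    a   : oxygen consumption rate, mmHg s^-1 (may be None when the task is
          to estimate it).
    """

    p_o: float = 100.0
    D: float = 2e-9
    a: float | None = 20.0

    def __post_init__(self):
        if self.p_o <= 0 or self.D <= 0 or (self.a is not None and self.a <= 0):
            raise ValueError("p_o, D and a must be strictly positive")

    def with_a(self, a: float) -> "OxygenModelParams":
        return replace(self, a=a)


class PressureSample(NamedTuple):
    """Oxygen partial pressure at a polar point of the meridional plane."""

    r: float        # metres
    theta: float    # radians from the symmetry axis
    P: float        # mmHg (clamped at 0 inside the anoxic core)
    anoxic: bool


class FullyOxygenatedError(ValueError):
    """No anoxic core exists for these parameters (consumption too low)."""


# ---------------------------------------------------------------------------
# dimensionless unit fields: P = (a f^2 / D) * Pi(sigma, tau)

def _prolate_coeffs(sigma_n: float):
    q0n = legendre_q0(sigma_n)
    c1 = sigma_n * (sigma_n**2 - 1.0) / 3.0
    c2 = -(sigma_n**2 / 6.0 + 1.0 / 18.0 + c1 * q0n)
    p2n = (3.0 * sigma_n**2 - 1.0) / 2.0
    q2n = legendre_q2(sigma_n)
    dp2n = 3.0 * sigma_n
    dq2n = legendre_q2_prime(sigma_n)
    det = p2n * dq2n - q2n * dp2n
    c3 = (-1.0 / 9.0) * dq2n / det
    c4 = (1.0 / 9.0) * dp2n / det
    return c1, c2, c3, c4


def _prolate_unit(sigma, tau, sigma_n: float):
    c1, c2, c3, c4 = _prolate_coeffs(sigma_n)
    sigma = np.asarray(sigma, dtype=float)
    tau = np.asarray(tau, dtype=float)
    p2s = (3.0 * sigma**2 - 1.0) / 2.0
    u = sigma**2 / 6.0 + 1.0 / 18.0 + c1 * legendre_q0(sigma) + c2
    w = 1.0 / 9.0 + c3 * p2s + c4 * legendre_q2(sigma)
    return u + w * (3.0 * tau**2 - 1.0) / 2.0


def _oblate_coeffs(xi_n: float):
    c1 = -xi_n * (xi_n**2 + 1.0) / 3.0
    c2 = -(xi_n**2 / 6.0 - 1.0 / 18.0 - c1 * oblate_q0(xi_n))
    p2n = oblate_p2(xi_n)
    q2n = oblate_q2(xi_n)
    dp2n = 3.0 * xi_n
    dq2n = oblate_q2_prime(xi_n)
    det = p2n * dq2n - q2n * dp2n
    c3 = (1.0 / 9.0) * dq2n / det
    c4 = (-1.0 / 9.0) * dp2n / det
    return c1, c2, c3, c4


def _oblate_unit(xi, tau, xi_n: float):
    c1, c2, c3, c4 = _oblate_coeffs(xi_n)
    xi = np.asarray(xi, dtype=float)
    tau = np.asarray(tau, dtype=float)
    u = xi**2 / 6.0 - 1.0 / 18.0 - c1 * oblate_q0(xi) + c2
    w = -1.0 / 9.0 + c3 * oblate_p2(xi) + c4 * oblate_q2(xi)
    return u + w * (3.0 * tau**2 - 1.0) / 2.0


def boundary_bracket(shape: Shape | str, r_o: float, r_n: float, f: float) -> float:
    """Dimensionless outer-boundary value Pi at the semi-minor vertex.

    The consumption rate satisfies ``a = D p_o / (f^2 * boundary_bracket)``;
    this is the quantity the OCR estimators invert.  For the prolate system
    the semi-minor vertex lies in the equatorial plane (tau = 0); for the
    oblate system it is the pole on the symmetry axis (tau = 1).
    """
    shape = Shape(shape)
    if f <= 0:
        raise ValueError("boundary_bracket needs f > 0; use the sphere branch")
    if shape == Shape.PROLATE:
        return float(_prolate_unit(r_o / f, 0.0, r_n / f))
    if shape == Shape.OBLATE:
        xi_o = np.sqrt((r_o / f) ** 2 - 1.0)
        xi_n = np.sqrt((r_n / f) ** 2 - 1.0)
        return float(_oblate_unit(xi_o, 1.0, xi_n))
    raise ValueError("bracket is defined for prolate/oblate shells")


def _sphere_pressure(r, r_n: float, r_o: float, params: OxygenModelParams):
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        val = params.a / (6.0 * params.D) * (r**2 + 2.0 * r_n**3 / np.where(r > 0, r, np.inf) - 3.0 * r_n**2)
    return np.where(r <= r_n, 0.0, val)


def pressure(geom: SpheroidGeometry, params: OxygenModelParams, r: float,
             theta: float, clamp: bool = True) -> float:
    """Oxygen partial pressure (mmHg) at polar point ``(r, theta)``.

    ``theta`` is measured from the symmetry axis.  Inside the anoxic core the
    analytic expression loses physical meaning; by the anoxia definition the
    value is clamped to 0 there (use :func:`profile`/:func:`contour_map` to
    retain the anoxic flag).  Points outside the outer shell evaluate the
    analytic continuation of the field, which is what the sphericity-error
    metrics integrate over the circumscribing sphere; those metrics pass
    ``clamp=False`` so the raw continuation (which may dip below zero at
    extreme eccentricity) is measured rather than its physical truncation.
    """
    if r < 0:
        raise ValueError("r must be non-negative")
    if not 0.0 <= theta <= np.pi:
        raise ValueError("theta must lie in [0, pi]")
    if params.a is None:
        raise ValueError("params.a is required to evaluate the field")
    if geom.shape == Shape.SPHERE or geom.f == 0.0:
        val = float(_sphere_pressure(r, geom.r_n, geom.r_o, params))
        return max(val, 0.0) if clamp else val
    coords = to_spheroidal(r, theta, geom.f, geom.shape)
    if geom.shape == Shape.PROLATE:
        if coords.sigma <= geom.r_n / geom.f:
            return 0.0
        unit = _prolate_unit(coords.sigma, coords.tau, geom.r_n / geom.f)
    else:
        xi_n = np.sqrt((geom.r_n / geom.f) ** 2 - 1.0)
        if coords.sigma <= xi_n:
            return 0.0
        unit = _oblate_unit(coords.sigma, coords.tau, xi_n)
    val = params.a * geom.f**2 / params.D * float(unit)
    return max(val, 0.0) if clamp else val


def minimum_ocr_for_anoxia(r_o: float, params: OxygenModelParams) -> float:
    """Smallest consumption rate producing an anoxic core at this size.

    Below ``6 D p_o / r_o^2`` the whole spheroid stays oxygenated (the
    threshold is the sphere value; under the confocal inner-eccentricity
    convention the anoxic shell shrinks through the spherical limit).
    """
    return 6.0 * params.D * params.p_o / r_o**2


def _ocr_given_geometry(shape: Shape, r_o: float, r_n: float, f: float,
                        params: OxygenModelParams) -> float:
    if f == 0.0 or shape == Shape.SPHERE:
        return 6.0 * params.D * params.p_o * r_o / ((r_o - r_n) ** 2 * (r_o + 2.0 * r_n))
    return params.D * params.p_o / (f**2 * boundary_bracket(shape, r_o, r_n, f))


def solve_anoxic_geometry(
    shape: Shape | str,
    r_o: float,
    e: float,
    params: OxygenModelParams,
    convention: str = "inner",
) -> SpheroidGeometry:
    """Find the anoxic shell for a given consumption rate (free boundary).

    Parameters
    ----------
    shape : sphere / prolate / oblate.
    r_o : outer semi-major axis, metres.
    e : eccentricity.  With ``convention="inner"`` (default) this is the
        anoxic-shell eccentricity and ``f = e * r_n`` is updated during the
        solve; with ``convention="outer"`` the focal length is pinned by the
        outer shell, ``f = e * r_o``.
    params : must carry the consumption rate ``a``.

    Raises
    ------
    FullyOxygenatedError
        when ``a`` is at or below the threshold for an anoxic core.
    """
    shape = Shape(shape)
    if params.a is None:
        raise ValueError("params.a is required")
    if not 0.0 <= e < 1.0:
        raise ValueError("eccentricity must be in [0, 1)")
    if convention not in ("inner", "outer"):
        raise ValueError("convention must be 'inner' or 'outer'")
    a = params.a

    if shape == Shape.SPHERE or e == 0.0:
        if a <= minimum_ocr_for_anoxia(r_o, params):
            raise FullyOxygenatedError(
                f"a = {a} mmHg/s <= threshold {minimum_ocr_for_anoxia(r_o, params):.4g};"
                " no anoxic core forms"
            )
        g = lambda r_n: _ocr_given_geometry(Shape.SPHERE, r_o, r_n, 0.0, params) - a
        r_n = brentq(g, 1e-12 * r_o, r_o * (1.0 - 1e-12), xtol=1e-15, rtol=8.9e-16)
        return SpheroidGeometry(Shape.SPHERE, r_o, r_n, 0.0)

    # the boundary bracket vanishes quadratically as r_n -> r_o (both inner
    # conditions are homogeneous there), so the upper end stops 1e-6 short of
    # r_o: the bracket is ~5e-11 there, still above roundoff, and the OCR it
    # represents is ~1e12 x physiological
    if convention == "inner":
        lo, hi = 1e-9 * r_o, r_o * (1.0 - 1e-6)
        geom_f = lambda r_n: e * r_n
    else:
        f = e * r_o
        lo, hi = f * (1.0 + 1e-9), r_o * (1.0 - 1e-6)
        geom_f = lambda r_n: f

    def g(r_n):
        return _ocr_given_geometry(shape, r_o, r_n, geom_f(r_n), params) - a

    if g(lo) >= 0.0:
        raise FullyOxygenatedError(
            f"a = {a} mmHg/s is below the anoxia threshold for this geometry"
        )
    if g(hi) <= 0.0:
        raise ValueError("consumption rate too large: anoxic shell reaches the surface")
    r_n = brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16)
    return SpheroidGeometry(shape, r_o, r_n, geom_f(r_n))


def profile(geom: SpheroidGeometry, params: OxygenModelParams, axis: str = "major",
            n: int = 100) -> list[PressureSample]:
    """Radial oxygen profile along the semi-major or semi-minor axis.

    Samples run from the anoxic boundary on that axis out to the outer
    surface.  For the prolate system the major axis is the symmetry axis
    (theta = 0) and the minor axis is equatorial (theta = pi/2); for the
    oblate system the roles are swapped.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if axis not in ("major", "minor"):
        raise ValueError("axis must be 'major' or 'minor'")
    if geom.shape == Shape.SPHERE:
        theta = 0.0
        start, stop = geom.r_n, geom.r_o
    else:
        major_is_axis = geom.shape == Shape.PROLATE
        on_axis = (axis == "major") == major_is_axis
        theta = 0.0 if on_axis else np.pi / 2.0
        start, stop = (geom.r_n, geom.r_o) if axis == "major" else (geom.b_n, geom.b_o)
    rs = np.linspace(start, stop, n)
    out = []
    for r in rs:
        p = pressure(geom, params, float(r), theta)
        out.append(PressureSample(float(r), theta, p, p <= 0.0))
    return out


@dataclass
class PressureField:
    """Meridional-plane pressure map.  ``rho`` is the distance from the
    symmetry axis, ``z`` the coordinate along it (metres); ``P`` in mmHg is
    NaN outside the outer shell and 0 in the anoxic core."""

    rho: np.ndarray
    z: np.ndarray
    P: np.ndarray
    geom: SpheroidGeometry

    def to_dataframe(self):
        import pandas as pd

        rr = np.hypot(self.rho, self.z)
        th = np.arctan2(self.rho, self.z)
        return pd.DataFrame(
            {
                "r_um": rr.ravel() * 1e6,
                "theta_rad": th.ravel(),
                "P_mmHg": self.P.ravel(),
            }
        )


def contour_map(geom: SpheroidGeometry, params: OxygenModelParams,
                n: int = 201) -> PressureField:
    """Oxygen map over a meridional quarter-plane (axisymmetry + mirror
    symmetry make the quarter plane complete).  Iso-pressure contours are
    near-confocal ellipses; the anoxic core reports 0 and points outside the
    spheroid NaN."""
    if geom.shape == Shape.SPHERE:
        ext_rho = ext_z = geom.r_o
    elif geom.shape == Shape.PROLATE:
        ext_rho, ext_z = geom.b_o, geom.r_o
    else:
        ext_rho, ext_z = geom.r_o, geom.b_o
    rho = np.linspace(0.0, ext_rho, n)
    z = np.linspace(0.0, ext_z, n)
    RHO, Z = np.meshgrid(rho, z, indexing="ij")
    P = np.full_like(RHO, np.nan)
    # outer-shell membership test in cartesian form
    if geom.shape == Shape.PROLATE:
        inside = (RHO / geom.b_o) ** 2 + (Z / geom.r_o) ** 2 <= 1.0
    elif geom.shape == Shape.OBLATE:
        inside = (RHO / geom.r_o) ** 2 + (Z / geom.b_o) ** 2 <= 1.0
    else:
        inside = RHO**2 + Z**2 <= geom.r_o**2
    rr = np.hypot(RHO, Z)
    th = np.arctan2(RHO, Z)
    it = np.nditer(inside, flags=["multi_index"])
    for ok in it:
        if ok:
            idx = it.multi_index
            P[idx] = pressure(geom, params, float(rr[idx]), float(th[idx]))
    return PressureField(RHO, Z, P, geom)
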