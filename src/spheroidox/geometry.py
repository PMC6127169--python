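"""Spheroid geometry, spheroidal coordinates and section-ellipse QC tests.

Conventions used throughout the package
---------------------------------------
* The polar angle ``theta`` is measured from the rotation (symmetry) axis.
* A *prolate* spheroid has its semi-major axis along the rotation axis
  (rugby ball); an *oblate* spheroid has its semi-major axes in the
  equatorial plane (discus).  Both are azimuthally symmetric, so every
  computation lives in a meridional half-plane.
* Internal lengths are metres; the imaging/CLI layers speak micrometres.
  The diffusion constant is quoted in m^2 s^-1 and the consumption-to-
  diffusion ratio spans ~1e9 mmHg m^-2, so a single internal unit avoids
  the main class of numerical bugs.

Confocality is the central geometric invariant: the ellipsoidal shells of a
true (undeformed, centrally sectioned) spheroid share one focal length
``f = e_c * r_c``, so the fitted inner (anoxic) and outer ellipses of a
section must satisfy ``e_o * r_o ~= e_n * r_n``.  Shearing the section or
cutting off the central axis breaks confocality and/or concentricity, which
is what the QC checks below detect.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

import numpy as np

__all__ = [
    "Shape",
    "SpheroidGeometry",
    "SpheroidalCoords",
    "SectionEllipse",
    "ConfocalityResult",
    "focal_length",
    "to_spheroidal",
    "from_spheroidal",
    "confocality_check",
    "concentricity_check",
    "shear_section",
]

#: fitted eccentricities below this are treated as circles; the confocality
#: ratio is ill-conditioned when both focal lengths are ~0
CIRCLE_ECCENTRICITY = 0.05


class Shape(str, Enum):
    SPHERE = "sphere"
    PROLATE = "prolate"
    OBLATE = "oblate"


@dataclass(frozen=True)
class SpheroidGeometry:
    """Confocal inner/outer ellipsoidal shells of one spheroid.

    Parameters
    ----------
    shape : Shape
    r_o, r_n : float
        Outer and anoxic (inner) semi-major axis lengths in metres.
    f : float
        Common focal length of the confocal shells in metres.  ``f = 0``
        if and only if the spheroid is a sphere.
    """

    shape: Shape
    r_o: float
    r_n: float
    f: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.f < self.r_n <= self.r_o) and not (
            self.r_n == 0.0 and self.f == 0.0 and self.r_o > 0.0
        ):
            raise ValueError(
                f"need 0 <= f < r_n <= r_o, got f={self.f}, r_n={self.r_n}, r_o={self.r_o}"
            )
        if self.shape == Shape.SPHERE and self.f != 0.0:
            raise ValueError("a sphere has no focus (f must be 0)")
        if self.shape != Shape.SPHERE and self.f == 0.0:
            object.__setattr__(self, "shape", Shape.SPHERE)

    @classmethod
    def from_microns(cls, shape, r_o_um, r_n_um, f_um=0.0) -> "SpheroidGeometry":
        return cls(Shape(shape), r_o_um * 1e-6, r_n_um * 1e-6, f_um * 1e-6)

    @property
    def e_o(self) -> float:
        """Eccentricity of the outer shell."""
        return self.f / self.r_o

    @property
    def e_n(self) -> float:
        """Eccentricity of the anoxic shell."""
        return self.f / self.r_n if self.r_n > 0 else 0.0

    @property
    def b_o(self) -> float:
        """Semi-minor axis of the outer shell (metres)."""
        return float(np.sqrt(self.r_o**2 - self.f**2))

    @property
    def b_n(self) -> float:
        """Semi-minor axis of the anoxic shell (metres)."""
        return float(np.sqrt(self.r_n**2 - self.f**2))


class SpheroidalCoords(NamedTuple):
    """Point in prolate/oblate spheroidal coordinates.

    ``sigma`` is the radial coordinate (>= 1 prolate, >= 0 oblate); surfaces
    of constant sigma are spheroids confocal with the focal length used in
    the transform.  ``tau`` in [-1, 1] is the angular coordinate (tau = +-1
    on the symmetry axis, 0 in the equatorial plane).
    """

    sigma: float
    tau: float
    kind: Shape


def focal_length(e_c: float, r_c: float) -> float:
    """Focal length of an ellipsoidal shell with eccentricity/semi-major axis.

    All confocal shells of one spheroid share this value, which is the basis
    of the confocality QC test.
    """
    if not 0.0 <= e_c < 1.0:
        raise ValueError(f"eccentricity must be in [0, 1), got {e_c}")
    if r_c <= 0.0:
        raise ValueError(f"semi-major axis must be positive, got {r_c}")
    return e_c * r_c


def to_spheroidal(r, theta, f: float, kind: Shape | str) -> SpheroidalCoords:
    """Map polar (r, theta) in a meridional plane to spheroidal coordinates.

    ``theta`` is the polar angle from the symmetry axis.  For the prolate
    system the foci sit on the symmetry axis at distance ``f`` from the
    centre; for the oblate system the focal ring intersects the meridional
    plane at distance ``f`` from the axis.
    """
    kind = Shape(kind)
    if f <= 0.0:
        raise ValueError("f = 0 is degenerate; use the spherical branch")
    if r < 0.0:
        raise ValueError("r must be non-negative")
    z = r * np.cos(theta)
    rho = r * np.sin(theta)
    if kind == Shape.PROLATE:
        d1 = np.hypot(rho, z - f)
        d2 = np.hypot(rho, z + f)
        sigma = (d1 + d2) / (2.0 * f)
        tau = (d2 - d1) / (2.0 * f)
    elif kind == Shape.OBLATE:
        # xi^2 solves f^2 X^2 + (f^2 - r^2) X - z^2 = 0; the rationalised
        # root below is stable on both sides of the focal disc
        p = rho * rho + z * z - f * f
        disc = np.sqrt(p * p + 4.0 * f * f * z * z)
        if p >= 0.0:
            X = (p + disc) / (2.0 * f * f)
        else:
            X = (2.0 * z * z) / (disc - p) if disc > p else 0.0
        sigma = np.sqrt(X)
        if sigma > 0.0:
            tau = z / (f * sigma)
        else:
            # on the focal disc plane: tau^2 = 1 - (rho/f)^2
            tau = np.sqrt(max(1.0 - (rho / f) ** 2, 0.0))
        tau = float(np.clip(tau, -1.0, 1.0))
    else:
        raise ValueError("kind must be prolate or oblate")
    return SpheroidalCoords(float(sigma), float(tau), kind)


def from_spheroidal(coords: SpheroidalCoords, f: float):
    """Inverse of :func:`to_spheroidal`; returns ``(r, theta)``."""
    sigma, tau, kind = coords
    if kind == Shape.PROLATE:
        z = f * sigma * tau
        rho = f * np.sqrt(max(sigma**2 - 1.0, 0.0) * max(1.0 - tau**2, 0.0))
    else:
        z = f * sigma * tau
        rho = f * np.sqrt((sigma**2 + 1.0) * max(1.0 - tau**2, 0.0))
    r = np.hypot(rho, z)
    theta = np.arctan2(rho, z)
    return float(r), float(theta)


@dataclass(frozen=True)
class SectionEllipse:
    """Ellipse fitted to a 2-D spheroid section, in micrometres.

    ``phi`` is the major-axis orientation in radians, normalised to [0, pi).
    """

    cx: float
    cy: float
    a2d: float
    b2d: float
    phi: float = 0.0

    def __post_init__(self):
        if not self.a2d >= self.b2d > 0.0:
            raise ValueError(f"need a2d >= b2d > 0, got a2d={self.a2d}, b2d={self.b2d}")
        object.__setattr__(self, "phi", float(self.phi) % np.pi)

    @property
    def eccentricity(self) -> float:
        return float(np.sqrt(1.0 - (self.b2d / self.a2d) ** 2))

    @property
    def focal_length_um(self) -> float:
        return self.eccentricity * self.a2d

    @property
    def center(self):
        return np.array([self.cx, self.cy])


class ConfocalityResult(NamedTuple):
    passes: bool
    rel_error: float


def confocality_check(
    outer: SectionEllipse,
    inner: SectionEllipse,
    rel_tol: float = 0.05,
    circle_eps: float = CIRCLE_ECCENTRICITY,
) -> ConfocalityResult:
    """Test whether two fitted section ellipses are confocal.

    The relative error is ``|f_outer - f_inner| / max(f_outer, f_inner)``.
    When both ellipses are near-circular (eccentricity < ``circle_eps``) the
    focal lengths are ~0 and the ratio is ill-conditioned, so the pair is
    accepted as a (trivially confocal) sphere section.
    """
    if outer.eccentricity < circle_eps and inner.eccentricity < circle_eps:
        return ConfocalityResult(True, 0.0)
    f_out = outer.focal_length_um
    f_in = inner.focal_length_um
    denom = max(f_out, f_in)
    rel_error = abs(f_out - f_in) / denom if denom > 0 else 0.0
    return ConfocalityResult(rel_error <= rel_tol, float(rel_error))


def concentricity_check(
    outer: SectionEllipse, inner: SectionEllipse, center_tol_um: float
) -> bool:
    """True when the two fitted centres coincide within ``center_tol_um``."""
    return float(np.hypot(outer.cx - inner.cx, outer.cy - inner.cy)) <= center_tol_um


def shear_section(r_n_um: float, r_o_um: float, shear: float):
    """Section ellipses of a sheared (warped) spherical spheroid.

    Sectioning artefacts can stretch a fixed spheroid along one axis.  Two
    concentric circles of radii ``r_n`` and ``r_o`` stretched by ``shear``
    become ellipses of *equal eccentricity* ``sqrt(1 - 1/shear^2)`` (for
    shear > 1), hence of *unequal* focal length whenever ``r_n != r_o`` —
    a sheared spheroid never satisfies confocality unless it is a perfect
    circle or the shells coincide.

    Returns ``(outer, inner)`` section ellipses in micrometres.
    """
    if not 0.0 < r_n_um <= r_o_um:
        raise ValueError("need 0 < r_n <= r_o")
    if shear <= 0.0:
        raise ValueError("shear must be positive")

    def stretched(r):
        ax, ay = r * shear, r
        a, b = (ax, ay) if ax >= ay else (ay, ax)
        phi = 0.0 if ax >= ay else np.pi / 2
        if a == b:
            phi = 0.0
        return SectionEllipse(0.0, 0.0, a, b, phi)

    return stretched(r_o_um), stretched(r_n_um)
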