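"""Section-image analysis: segmentation, ellipse fits and the QC decision.

The workflow mirrors how dual-stained spheroid sections are analysed: a
bright viable rim (proliferation stain) surrounds a darker anoxic core
(hypoxia stain).  From a single 2-D section the pipeline

1. segments the section and fits least-squares ellipses to the outer
   boundary and the core boundary,
2. runs the geometric QC tests — confocality (e_o r_o ~= e_n r_n) and
   concentricity — that distinguish a genuine ellipsoidal spheroid from a
   sheared (warped) spheroid or an off-centre cut,
3. classifies the section: near-circular sections take the spherical OCR
   path; eccentric sections passing QC take the ellipsoidal path (combined
   estimator by default, since a single section cannot reveal prolate vs
   oblate); QC failures are discarded with no OCR.

A synthetic-section generator renders the same scene from a known
``SpheroidGeometry``, including shear and oblique off-centre cuts, so the
whole pipeline is testable end-to-end against analytic ground truth: any
plane section of an ellipsoid is an ellipse whose centre and axes follow
from the quadric/plane intersection in closed form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import gaussian, threshold_multiotsu

from .geometry import (
    SectionEllipse,
    Shape,
    SpheroidGeometry,
    confocality_check,
    concentricity_check,
)
from .ocr import OCREstimate, OCRMethod, estimate_ocr_with_uncertainty
from .oxygen import OxygenModelParams

__all__ = [
    "SyntheticSectionSpec",
    "SectionGroundTruth",
    "SectionFit",
    "SectionQCReport",
    "QCThresholds",
    "Decision",
    "NoSpheroidError",
    "MultipleComponentsError",
    "render_section",
    "segment_and_fit",
    "analyze_section",
    "plane_section_of_spheroid",
]


class NoSpheroidError(ValueError):
    """The image contains no usable spheroid section."""


class MultipleComponentsError(ValueError):
    """More than one candidate spheroid section found."""


class Decision(str, Enum):
    SPHERE = "sphere"
    ELLIPSOID = "ellipsoid"
    DISCARD = "discard"


# ---------------------------------------------------------------------------
# analytic plane sections

def plane_section_of_spheroid(semi_axes, normal, offset, basis=None):
    """Ellipse of intersection between an axis-aligned ellipsoid and a plane.

    Parameters
    ----------
    semi_axes : (ax, ay, az) of the ellipsoid x^2/ax^2 + ... = 1, metres or um.
    normal : plane unit normal; plane is {x : normal . x = offset}.
    offset : signed plane offset from the centre, same unit as semi_axes.
    basis : optional (u, v) orthonormal in-plane basis; supply the same basis
        for two confocal shells so their in-plane centres are comparable.

    Returns
    -------
    (center2, a, b, phi) of the section ellipse in the (u, v) plane frame, or
    None when the plane misses the ellipsoid.  ``phi`` is the angle of the
    major axis from u.
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    A = np.diag(1.0 / np.asarray(semi_axes, dtype=float) ** 2)
    if basis is None:
        seed = np.array([0.0, 0.0, 1.0])
        if abs(n @ seed) > 0.9:
            seed = np.array([1.0, 0.0, 0.0])
        u = seed - (seed @ n) * n
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
    else:
        u, v = (np.asarray(b, dtype=float) for b in basis)
    p0 = offset * n
    Q = np.array([[u @ A @ u, u @ A @ v], [v @ A @ u, v @ A @ v]])
    bvec = np.array([u @ A @ p0, v @ A @ p0])
    c = p0 @ A @ p0 - 1.0
    center2 = -np.linalg.solve(Q, bvec)
    c_eff = c + bvec @ center2  # value of the quadric at the ellipse centre
    if c_eff >= 0.0:
        return None
    M = Q / (-c_eff)  # (w - w0)^T M (w - w0) = 1
    return _ellipse_from_matrix(center2, M)


def _ellipse_from_matrix(center2, M):
    evals, evecs = np.linalg.eigh(M)
    axes = 1.0 / np.sqrt(evals)  # ascending evals -> descending axes
    a, b = float(axes[0]), float(axes[1])
    major = evecs[:, 0]
    if b > a:  # pragma: no cover - eigh sorts ascending, axes descending
        a, b = b, a
        major = evecs[:, 1]
    phi = float(np.arctan2(major[1], major[0])) % np.pi
    return np.asarray(center2, dtype=float), a, b, phi


def _apply_shear(center2, a, b, phi, shear):
    """Stretch the section by ``shear`` along the in-plane u axis."""
    if shear == 1.0:
        return center2, a, b, phi
    S = np.diag([shear, 1.0])
    # centered conic matrix of the unsheared ellipse
    R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    M = R @ np.diag([1.0 / a**2, 1.0 / b**2]) @ R.T
    Sinv = np.diag([1.0 / shear, 1.0])
    M2 = Sinv.T @ M @ Sinv
    return _ellipse_from_matrix(S @ np.asarray(center2), (M2 + M2.T) / 2.0)


@dataclass(frozen=True)
class SyntheticSectionSpec:
    """Recipe for a synthetic dual-stained spheroid section image.

    The rendered scene emulates a proliferation/hypoxia double stain:
    ``levels`` are the (background, anoxic core, viable rim) intensities in
    [0, 1].  ``shear`` stretches the section in-plane (sectioning artefact);
    ``cut_offset_um`` displaces the cutting plane off the spheroid centre
    along its normal, and ``cut_tilt_rad`` tilts that normal away from the
    meridional-plane normal (an oblique off-centre cut is what breaks the
    concentricity of the two section ellipses; an axis-parallel offset cut
    of confocal shells stays concentric and only breaks confocality).
    """

    geom: SpheroidGeometry
    pixel_size_um: float = 1.0
    image_size: int | None = None
    noise_sigma: float = 0.0
    shear: float = 1.0
    cut_offset_um: float = 0.0
    cut_tilt_rad: float = np.pi / 4.0
    levels: tuple = (0.05, 0.35, 0.75)
    rng_seed: int = 0

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.shear <= 0:
            raise ValueError("shear must be positive")


@dataclass(frozen=True)
class SectionGroundTruth:
    outer: SectionEllipse
    inner: SectionEllipse | None


def _section_ellipses(spec: SyntheticSectionSpec):
    """Ground-truth section ellipses (um, image frame before recentring)."""
    g = spec.geom
    r_um, b_um = g.r_o * 1e6, g.b_o * 1e6
    rn_um, bn_um = g.r_n * 1e6, g.b_n * 1e6
    if g.shape == Shape.OBLATE:
        axes_o = (r_um, r_um, b_um)
        axes_n = (rn_um, rn_um, bn_um)
    else:  # sphere renders via the prolate layout with equal axes
        axes_o = (b_um, b_um, r_um)
        axes_n = (bn_um, bn_um, rn_um)
    # central section plane is y = 0; the off-centre cut tilts the normal
    # towards the symmetry axis z and displaces the plane along it
    t = spec.cut_tilt_rad if spec.cut_offset_um != 0.0 else 0.0
    n = np.array([0.0, np.cos(t), np.sin(t)])
    # in-plane basis: u is the projection of the symmetry axis (prolate) or
    # the equatorial x axis (oblate) so the major axis lies near u
    seed = np.array([0.0, 0.0, 1.0]) if g.shape != Shape.OBLATE else np.array([1.0, 0.0, 0.0])
    u = seed - (seed @ n) * n
    u = u / np.linalg.norm(u)
    v = np.cross(n, u)
    out = plane_section_of_spheroid(axes_o, n, spec.cut_offset_um, basis=(u, v))
    if out is None:
        raise ValueError("cutting plane misses the spheroid")
    inn = (
        plane_section_of_spheroid(axes_n, n, spec.cut_offset_um, basis=(u, v))
        if g.r_n > 0
        else None
    )
    out = _apply_shear(*out, spec.shear)
    ellipses = [SectionEllipse(out[0][0], out[0][1], out[1], out[2], out[3])]
    if inn is not None:
        inn = _apply_shear(*inn, spec.shear)
        ellipses.append(SectionEllipse(inn[0][0], inn[0][1], inn[1], inn[2], inn[3]))
    else:
        ellipses.append(None)
    return ellipses


def render_section(spec: SyntheticSectionSpec):
    """Render a synthetic section image.

    Returns ``(image, truth)``: a float image in [0, 1] (y = row * pixel,
    x = col * pixel) and the analytic ground-truth ellipse pair in the same
    micrometre frame.  Deterministic for a given ``rng_seed``.
    """
    outer, inner = _section_ellipses(spec)
    px = spec.pixel_size_um
    size = spec.image_size or int(np.ceil(2.4 * outer.a2d / px))
    # recentre so the outer ellipse sits mid-image
    cx_img, cy_img = size * px / 2.0, size * px / 2.0
    dx, dy = cx_img - outer.cx, cy_img - outer.cy

    def shift(e: SectionEllipse | None):
        if e is None:
            return None
        return SectionEllipse(e.cx + dx, e.cy + dy, e.a2d, e.b2d, e.phi)

    outer, inner = shift(outer), shift(inner)

    xs = (np.arange(size) + 0.5) * px
    X, Y = np.meshgrid(xs, xs)  # X along columns, Y along rows

    def inside(e: SectionEllipse):
        ct, st = np.cos(e.phi), np.sin(e.phi)
        xr = (X - e.cx) * ct + (Y - e.cy) * st
        yr = -(X - e.cx) * st + (Y - e.cy) * ct
        return (xr / e.a2d) ** 2 + (yr / e.b2d) ** 2 <= 1.0

    bg, core, rim = spec.levels
    img = np.full((size, size), bg, dtype=float)
    img[inside(outer)] = rim
    if inner is not None:
        img[inside(inner)] = core
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.rng_seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0), SectionGroundTruth(outer, inner)


# ---------------------------------------------------------------------------
# segmentation and conic fitting

@dataclass(frozen=True)
class SectionFit:
    outer: SectionEllipse
    inner: SectionEllipse | None
    outer_rms_um: float = 0.0
    inner_rms_um: float = 0.0


def _fit_ellipse(contour_rc, pixel_size_um):
    xy = np.column_stack([contour_rc[:, 1], contour_rc[:, 0]]) * pixel_size_um
    try:
        model = measure.EllipseModel.from_estimate(xy)
        if not model:
            raise NoSpheroidError("ellipse fit failed")
        xc, yc = model.center
        a, b = model.axis_lengths
        phi = model.theta
    except AttributeError:  # scikit-image < 0.26
        model = measure.EllipseModel()
        if not model.estimate(xy):
            raise NoSpheroidError("ellipse fit failed")
        xc, yc, a, b, phi = model.params
    if b > a:
        a, b = b, a
        phi += np.pi / 2.0
    res = model.residuals(xy)
    rms = float(np.sqrt(np.mean(res**2)))
    return SectionEllipse(float(xc), float(yc), float(a), float(b), float(phi)), rms


def _closed_contours(image, level):
    out = []
    for c in measure.find_contours(image, level):
        if np.allclose(c[0], c[-1]):
            out.append(c)
    return out


def _contour_area(c):
    x, y = c[:, 1], c[:, 0]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def segment_and_fit(
    image,
    pixel_size_um: float,
    smooth_sigma_px: float = 2.0,
    min_area_frac: float = 0.005,
    min_core_px: int = 64,
) -> SectionFit:
    """Segment one spheroid section and fit outer/core ellipses.

    Otsu-style three-class thresholding on a smoothed copy separates
    background, core and rim; ellipses are fit by direct least squares to
    the sub-pixel iso-intensity contours at the two thresholds.  The outer
    ellipse is the largest closed contour at the background/rim threshold;
    the core is the smallest sufficiently large closed contour at the
    core/rim threshold.  All lengths are reported in micrometres
    (x = column * pixel, y = row * pixel).

    Raises :class:`NoSpheroidError` on a blank image and
    :class:`MultipleComponentsError` when several comparably sized sections
    are present.  A missing core is not an error: the spheroid may simply be
    fully oxygenated; ``inner`` is None then.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if img.max() > 1.0:
        img = img / img.max()
    sm = gaussian(img, sigma=smooth_sigma_px, preserve_range=True)
    if np.ptp(sm) < 0.05:
        raise NoSpheroidError("no spheroid found (flat image)")
    try:
        t0, t1 = threshold_multiotsu(sm, classes=3)
    except ValueError as exc:
        raise NoSpheroidError("no spheroid found") from exc

    # contour at the midpoint of the class means, not at the Otsu threshold:
    # for a smoothed step edge the midpoint level crosses at the true edge
    # position, removing the systematic outward bias of the raw threshold
    m_bg = float(sm[sm <= t0].mean())
    m_core = float(sm[(sm > t0) & (sm <= t1)].mean()) if np.any((sm > t0) & (sm <= t1)) else t1
    m_rim = float(sm[sm > t1].mean())
    level_outer = 0.5 * (m_bg + m_rim)
    level_inner = 0.5 * (m_core + m_rim)

    fg = sm > t0
    labels, nlab = ndimage.label(fg)
    if nlab == 0:
        raise NoSpheroidError("no spheroid found")
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, nlab + 1))
    order = np.argsort(areas)[::-1]
    if areas[order[0]] < min_area_frac * img.size:
        raise NoSpheroidError("no spheroid found (largest component too small)")
    if nlab > 1 and areas[order[1]] > 0.1 * areas[order[0]]:
        raise MultipleComponentsError("multiple spheroid sections in image")

    outer_contours = _closed_contours(sm, level_outer)
    if not outer_contours:
        raise NoSpheroidError("outer boundary not closed within the image")
    outer_c = max(outer_contours, key=_contour_area)
    outer, outer_rms = _fit_ellipse(outer_c, pixel_size_um)

    inner = None
    inner_rms = 0.0
    candidates = [
        c for c in _closed_contours(sm, level_inner)
        if min_core_px <= _contour_area(c) < 0.9 * _contour_area(outer_c)
    ]
    if candidates:
        inner_c = min(candidates, key=_contour_area)
        inner, inner_rms = _fit_ellipse(inner_c, pixel_size_um)
    return SectionFit(outer, inner, outer_rms, inner_rms)


# ---------------------------------------------------------------------------
# decision pipeline

@dataclass(frozen=True)
class QCThresholds:
    """QC thresholds of the section-analysis decision.

    ``e_threshold = 0.3`` is where the sphericity error of OCR estimates
    stops being acceptable; ``confocality_rel_tol = 0.05`` accepts genuine
    ellipsoids measured with ordinary image-analysis uncertainty;
    concentricity is judged in pixels (scaled by the pixel size).
    """

    e_threshold: float = 0.3
    confocality_rel_tol: float = 0.05
    concentricity_tol_px: float = 3.0


@dataclass
class SectionQCReport:
    outer: SectionEllipse
    inner: SectionEllipse | None
    confocality_rel_error: float
    confocality_passed: bool
    concentric: bool
    decision: Decision
    ocr: OCREstimate | None
    ocr_by_method: dict = field(default_factory=dict)
    fully_oxygenated: bool = False

    def to_dict(self):
        def ell(e):
            if e is None:
                return None
            return {"cx_um": e.cx, "cy_um": e.cy, "a_um": e.a2d, "b_um": e.b2d,
                    "phi_rad": e.phi, "eccentricity": e.eccentricity,
                    "focal_length_um": e.focal_length_um}

        return {
            "outer": ell(self.outer),
            "inner": ell(self.inner),
            "confocality_rel_error": self.confocality_rel_error,
            "confocality_passed": self.confocality_passed,
            "concentric": self.concentric,
            "decision": self.decision.value,
            "fully_oxygenated": self.fully_oxygenated,
            "ocr": None if self.ocr is None else {
                "a_mmHg_per_s": self.ocr.a,
                "sigma_mmHg_per_s": self.ocr.sigma_a,
                "method": self.ocr.method.value,
            },
            "ocr_by_method": {
                k: {"a_mmHg_per_s": v.a, "sigma_mmHg_per_s": v.sigma_a}
                for k, v in self.ocr_by_method.items()
            },
        }

    def to_json(self, **kwargs):
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def analyze_section(
    image,
    pixel_size_um: float,
    params: OxygenModelParams | None = None,
    thresholds: QCThresholds | None = None,
) -> SectionQCReport:
    """Full decision pipeline on one section image.

    Near-circular sections (outer eccentricity below the threshold) are
    treated as spheres.  Eccentric sections must pass both confocality and
    concentricity to be analysed as ellipsoids; otherwise the section is a
    warped spheroid or an off-centre cut and is discarded.  A 2-D section
    cannot distinguish prolate from oblate, so the ellipsoidal report
    carries all three estimates with the combined form as the headline.
    """
    params = params or OxygenModelParams()
    thr = thresholds or QCThresholds()
    fit = segment_and_fit(image, pixel_size_um)
    outer, inner = fit.outer, fit.inner

    if inner is None:
        # no stained core: fully oxygenated, nothing to invert
        decision = Decision.SPHERE if outer.eccentricity <= thr.e_threshold else Decision.ELLIPSOID
        return SectionQCReport(outer, None, 0.0, True, True, decision, None,
                               fully_oxygenated=True)

    conf = confocality_check(outer, inner, rel_tol=thr.confocality_rel_tol)
    conc = concentricity_check(outer, inner, thr.concentricity_tol_px * pixel_size_um)
    um = 1e-6
    sig_ro, sig_rn = fit.outer_rms_um * um, fit.inner_rms_um * um

    if outer.eccentricity <= thr.e_threshold:
        r_o = (outer.a2d + outer.b2d) / 2.0 * um
        r_n = (inner.a2d + inner.b2d) / 2.0 * um
        est = estimate_ocr_with_uncertainty(
            r_o, r_n, 0.0, params, OCRMethod.SPHERE, sigma_ro=sig_ro, sigma_rn=sig_rn
        )
        return SectionQCReport(outer, inner, conf.rel_error, conf.passes, conc,
                               Decision.SPHERE, est, {"sphere": est})

    if not (conf.passes and conc):
        return SectionQCReport(outer, inner, conf.rel_error, conf.passes, conc,
                               Decision.DISCARD, None)

    r_o, r_n = outer.a2d * um, inner.a2d * um
    f = (outer.focal_length_um + inner.focal_length_um) / 2.0 * um
    by_method = {}
    for m in (OCRMethod.PROLATE, OCRMethod.OBLATE, OCRMethod.COMBINED):
        by_method[m.value] = estimate_ocr_with_uncertainty(
            r_o, r_n, f, params, m, sigma_ro=sig_ro, sigma_rn=sig_rn
        )
    return SectionQCReport(outer, inner, conf.rel_error, conf.passes, conc,
                           Decision.ELLIPSOID, by_method["combined"], by_method)
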