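"""How wrong is the spherical assumption? RMSE metrics and scan drivers.

An eccentric spheroid nested inside its circumscribing sphere of radius r_o
does not present the external pressure p_o on that sphere: evaluating the
ellipsoidal field P(r_o, theta) and contrasting it with p_o gives a
root-mean-square error over the polar angle,

    RMSE = sqrt( mean_theta [ (p_o - P(r_o, theta))^2 ] ),

reported as a percentage of p_o.  Together with the sphere-assumption OCR
estimate (and its variance-formula uncertainty) this quantifies when a
spheroid may be analysed as a sphere: below e ~ 0.3 the error is a few
percent; beyond it both the RMSE and the OCR uncertainty grow explosively.

The scans solve the anoxic free boundary at a known true consumption rate
first, so every reported row corresponds to a physically consistent
spheroid, not just a geometric shell pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .geometry import Shape, SpheroidGeometry
from .ocr import (
    OCREstimate,
    OCRMethod,
    estimate_ocr,
    mean_of_shape_estimates,
    spherical_approx_estimate,
)
from .oxygen import OxygenModelParams, pressure, solve_anoxic_geometry

__all__ = [
    "SphericityErrorReport",
    "rmse_sphericity",
    "table2",
    "wrong_assumption_scan",
    "anoxic_radius_scan",
    "DEFAULT_ECCENTRICITIES",
]

DEFAULT_ECCENTRICITIES = tuple(np.round(np.arange(0.0, 0.91, 0.1), 2))


@dataclass(frozen=True)
class SphericityErrorReport:
    e: float
    rmse: float            # mmHg
    percent: float         # 100 * rmse / p_o
    ocr_approx: OCREstimate
    shape: Shape


def _surface_rmse(geom: SpheroidGeometry, params: OxygenModelParams,
                  weighting: str) -> float:
    """RMS of (p_o - P) on the circumscribing sphere r = r_o.

    ``weighting='uniform'`` averages over the polar angle, the default;
    ``weighting='area'`` weights by the sphere's area element sin(theta).
    Mirror symmetry lets the quadrature run on [0, pi/2].
    """
    p_o = params.p_o

    def dev2(th):
        return (p_o - pressure(geom, params, geom.r_o, th, clamp=False)) ** 2

    if weighting == "uniform":
        val, _ = quad(dev2, 0.0, np.pi / 2.0, epsabs=0.0, epsrel=1e-8, limit=200)
        return float(np.sqrt(val / (np.pi / 2.0)))
    if weighting == "area":
        val, _ = quad(lambda th: dev2(th) * np.sin(th), 0.0, np.pi / 2.0,
                      epsabs=0.0, epsrel=1e-8, limit=200)
        return float(np.sqrt(val))
    raise ValueError("weighting must be 'uniform' or 'area'")


def rmse_sphericity(
    shape: Shape | str,
    e: float,
    r_o: float,
    params: OxygenModelParams,
    weighting: str = "uniform",
    convention: str = "inner",
) -> SphericityErrorReport:
    """Sphericity error and sphere-assumption OCR for one eccentricity.

    The anoxic geometry is solved at the true consumption rate ``params.a``
    first; the report then carries the RMSE of the outer-sphere pressure and
    the spherical-approximation OCR estimate with its angular uncertainty.
    """
    shape = Shape(shape)
    if not 0.0 <= e < 1.0:
        raise ValueError("eccentricity must be in [0, 1)")
    if e == 0.0:
        geom = solve_anoxic_geometry(Shape.SPHERE, r_o, 0.0, params)
        ocr = spherical_approx_estimate(geom, params)
        return SphericityErrorReport(0.0, 0.0, 0.0, ocr, shape)
    geom = solve_anoxic_geometry(shape, r_o, e, params, convention=convention)
    rmse = _surface_rmse(geom, params, weighting)
    ocr = spherical_approx_estimate(geom, params)
    return SphericityErrorReport(e, rmse, 100.0 * rmse / params.p_o, ocr, shape)


def table2(
    e_list=None,
    r_o: float = 500e-6,
    params: OxygenModelParams | None = None,
    weighting: str = "uniform",
    convention: str = "inner",
) -> pd.DataFrame:
    """Sphericity-error table over an eccentricity grid, both shapes.

    Columns: e, rmse_prolate_pct, rmse_oblate_pct, ocr_prolate,
    ocr_prolate_sigma, ocr_oblate, ocr_oblate_sigma.
    """
    params = params or OxygenModelParams()
    e_list = DEFAULT_ECCENTRICITIES if e_list is None else e_list
    rows = []
    for e in e_list:
        rp = rmse_sphericity(Shape.PROLATE, e, r_o, params, weighting, convention)
        ro_ = rmse_sphericity(Shape.OBLATE, e, r_o, params, weighting, convention)
        rows.append(
            {
                "e": e,
                "rmse_prolate_pct": rp.percent,
                "rmse_oblate_pct": ro_.percent,
                "ocr_prolate": rp.ocr_approx.a,
                "ocr_prolate_sigma": rp.ocr_approx.sigma_a,
                "ocr_oblate": ro_.ocr_approx.a,
                "ocr_oblate_sigma": ro_.ocr_approx.sigma_a,
            }
        )
    return pd.DataFrame(rows)


def wrong_assumption_scan(
    e_list=None,
    r_o: float = 500e-6,
    params: OxygenModelParams | None = None,
    convention: str = "inner",
) -> pd.DataFrame:
    """OCR error when the prolate/oblate assumption is wrong.

    For each eccentricity the true spheroid is built under one shape at the
    true rate ``params.a``; the other shape's estimator (and the combined
    form) is then applied to the same shell geometry.
    """
    params = params or OxygenModelParams()
    e_list = DEFAULT_ECCENTRICITIES if e_list is None else e_list
    a_true = params.a
    rows = []
    for e in e_list:
        if e == 0.0:
            rows.append(
                {
                    "e": 0.0,
                    "ocr_prolate_as_oblate": a_true,
                    "ocr_oblate_as_prolate": a_true,
                    "ocr_combined_on_prolate": a_true,
                    "ocr_combined_on_oblate": a_true,
                    "err_prolate_as_oblate": 0.0,
                    "err_oblate_as_prolate": 0.0,
                    "err_combined_on_prolate": 0.0,
                    "err_combined_on_oblate": 0.0,
                }
            )
            continue
        gp = solve_anoxic_geometry(Shape.PROLATE, r_o, e, params, convention=convention)
        go = solve_anoxic_geometry(Shape.OBLATE, r_o, e, params, convention=convention)
        p_as_o = estimate_ocr(gp, params, OCRMethod.OBLATE).a
        o_as_p = estimate_ocr(go, params, OCRMethod.PROLATE).a
        comb_p = estimate_ocr(gp, params, OCRMethod.COMBINED).a
        comb_o = estimate_ocr(go, params, OCRMethod.COMBINED).a
        rows.append(
            {
                "e": e,
                "ocr_prolate_as_oblate": p_as_o,
                "ocr_oblate_as_prolate": o_as_p,
                "ocr_combined_on_prolate": comb_p,
                "ocr_combined_on_oblate": comb_o,
                "err_prolate_as_oblate": abs(p_as_o - a_true),
                "err_oblate_as_prolate": abs(o_as_p - a_true),
                "err_combined_on_prolate": abs(comb_p - a_true),
                "err_combined_on_oblate": abs(comb_o - a_true),
            }
        )
    return pd.DataFrame(rows)


def anoxic_radius_scan(
    e_list=None,
    r_o: float = 500e-6,
    params: OxygenModelParams | None = None,
    convention: str = "inner",
) -> pd.DataFrame:
    """Anoxic semi-axes of prolate vs oblate spheroids at fixed OCR.

    The two shapes agree closely (about a percent up to e ~ 0.9), which is
    why mis-identifying the solid barely affects OCR estimates.
    """
    params = params or OxygenModelParams()
    e_list = DEFAULT_ECCENTRICITIES if e_list is None else e_list
    rows = []
    for e in e_list:
        if e == 0.0:
            g = solve_anoxic_geometry(Shape.SPHERE, r_o, 0.0, params)
            rows.append(
                {
                    "e": 0.0,
                    "r_n_prolate_um": g.r_n * 1e6,
                    "r_n_oblate_um": g.r_n * 1e6,
                    "b_n_prolate_um": g.r_n * 1e6,
                    "b_n_oblate_um": g.r_n * 1e6,
                    "rel_diff_major": 0.0,
                }
            )
            continue
        gp = solve_anoxic_geometry(Shape.PROLATE, r_o, e, params, convention=convention)
        go = solve_anoxic_geometry(Shape.OBLATE, r_o, e, params, convention=convention)
        rows.append(
            {
                "e": e,
                "r_n_prolate_um": gp.r_n * 1e6,
                "r_n_oblate_um": go.r_n * 1e6,
                "b_n_prolate_um": gp.b_n * 1e6,
                "b_n_oblate_um": go.b_n * 1e6,
                "rel_diff_major": abs(gp.r_n - go.r_n) / gp.r_n,
            }
        )
    return pd.DataFrame(rows)
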