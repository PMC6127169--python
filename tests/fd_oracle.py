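"""Independent finite-difference oracle for the analytic oxygen fields.

Lives in the test tree on purpose: it shares no code with the package's
field implementation.  Two tools:

* an axisymmetric cylindrical-coordinate Laplacian stencil used to measure
  the pointwise residual ``|lap(P) - a/D|`` of a given field,
* Dirichlet solvers on boundary-fitted grids (polar for the sphere,
  prolate-spheroidal for ellipsoids) that impose P = 0 on the inner shell
  and P = p_o uniformly on the outer shell, then report how far the
  analytic field departs from that reference and how large the residual
  inner-boundary flux is.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


def axisymmetric_residual(field_fn, rho, z, h, a_over_D):
    """max/mean |discrete axisymmetric Laplacian - a/D| over given nodes.

    ``field_fn(rho, z)`` evaluates the field (mmHg); nodes with rho = 0 use
    the symmetry stencil 4 (P(h) - P(0)) / h^2 for the radial part.
    """
    rho = np.asarray(rho, dtype=float)
    z = np.asarray(z, dtype=float)
    lap = np.empty_like(rho)
    for k, (rh, zz) in enumerate(zip(rho.ravel(), z.ravel())):
        pzz = (field_fn(rh, zz + h) - 2 * field_fn(rh, zz) + field_fn(rh, zz - h)) / h**2
        if rh == 0.0:
            prr = 4.0 * (field_fn(h, zz) - field_fn(0.0, zz)) / h**2
        else:
            prr = (field_fn(rh + h, zz) - 2 * field_fn(rh, zz) + field_fn(rh - h, zz)) / h**2
            prr += (field_fn(rh + h, zz) - field_fn(rh - h, zz)) / (2 * h * rh)
        lap.ravel()[k] = prr + pzz
    resid = np.abs(lap - a_over_D)
    return float(resid.max()), float(resid.mean())


def solve_sphere_dirichlet(r_n, r_o, p_o, a_over_D, h):
    """Axisymmetric Dirichlet solve on a polar (r, theta) annulus grid.

    Imposes P(r_n) = 0, P(r_o) = p_o; mirror symmetry in theta at the axis
    and the equator.  Returns (r_nodes, theta_nodes, P) with P of shape
    (n_r, n_theta), plus the inner-boundary normal flux dP/dr at r_n
    estimated one-sidedly.
    """
    n_r = max(int(round((r_o - r_n) / h)) + 1, 5)
    r = np.linspace(r_n, r_o, n_r)
    hr = r[1] - r[0]
    n_t = 24
    # cell-centred theta in (0, pi/2): face coefficients sin(theta) vanish
    # nowhere interior; mirror symmetry closes both ends
    ht = (np.pi / 2) / n_t
    th = (np.arange(n_t) + 0.5) * ht

    ni = n_r - 2
    N = ni * n_t
    A = sp.lil_matrix((N, N))
    b = np.zeros(N)

    def idx(i, j):
        return (i - 1) * n_t + j

    for i in range(1, n_r - 1):
        ri = r[i]
        for j in range(n_t):
            k = idx(i, j)
            # radial part in conservative form: (1/r^2) d/dr (r^2 dP/dr)
            cm = (ri - hr / 2) ** 2 / (ri**2 * hr**2)
            cp = (ri + hr / 2) ** 2 / (ri**2 * hr**2)
            cc = -(cm + cp)
            # angular part: (1/r^2 sin) d/dth (sin d/dth), conservative faces
            sm_face = np.sin(th[j] - ht / 2)
            sp_face = np.sin(th[j] + ht / 2)
            denom = ri**2 * np.sin(th[j]) * ht**2
            am = sm_face / denom if j > 0 else 0.0       # mirror at axis
            ap = sp_face / denom if j < n_t - 1 else 0.0  # mirror at equator
            A[k, k] = cc - am - ap
            if j > 0:
                A[k, idx(i, j - 1)] = am
            if j < n_t - 1:
                A[k, idx(i, j + 1)] = ap
            if i > 1:
                A[k, idx(i - 1, j)] = cm
            else:
                b[k] -= cm * 0.0
            if i < n_r - 2:
                A[k, idx(i + 1, j)] = cp
            else:
                b[k] -= cp * p_o
            b[k] += a_over_D
    sol = spla.spsolve(A.tocsr(), b)
    P = np.zeros((n_r, n_t))
    P[1:-1, :] = sol.reshape(ni, n_t)
    P[-1, :] = p_o
    flux_inner = (-3 * P[0, :] + 4 * P[1, :] - P[2, :]) / (2 * hr)
    return r, th, P, float(np.mean(flux_inner))


def solve_prolate_dirichlet(sigma_n, sigma_o, f, p_o, a_over_D, n_sigma=80, n_tau=40):
    """Dirichlet solve of the Poisson problem in prolate spheroidal coords.

    d/ds[(s^2-1) dP/ds] + d/dt[(1-t^2) dP/dt] = (a f^2 / D)(s^2 - t^2),
    with P(sigma_n) = 0 and P(sigma_o) = p_o *uniformly*.  tau runs over
    [0, 1] cell-centred: the (1 - t^2) face coefficient vanishes at the pole
    face and mirror symmetry closes the equator face.  Returns
    (sigma_nodes, tau_centres, P, mean inner dP/dsigma).
    """
    s = np.linspace(sigma_n, sigma_o, n_sigma)
    hs = s[1] - s[0]
    htau = 1.0 / n_tau
    t = (np.arange(n_tau) + 0.5) * htau

    ni = n_sigma - 2
    N = ni * n_tau
    A = sp.lil_matrix((N, N))
    b = np.zeros(N)
    rhs_scale = f**2 * a_over_D

    def idx(i, j):
        return (i - 1) * n_tau + j

    for i in range(1, n_sigma - 1):
        si = s[i]
        csm = ((si - hs / 2) ** 2 - 1.0) / hs**2
        csp = ((si + hs / 2) ** 2 - 1.0) / hs**2
        for j in range(n_tau):
            k = idx(i, j)
            ctm = (1.0 - (t[j] - htau / 2) ** 2) / htau**2 if j > 0 else 0.0
            ctp = (1.0 - (t[j] + htau / 2) ** 2) / htau**2 if j < n_tau - 1 else 0.0
            A[k, k] = -(csm + csp + ctm + ctp)
            if j > 0:
                A[k, idx(i, j - 1)] = ctm
            if j < n_tau - 1:
                A[k, idx(i, j + 1)] = ctp
            if i > 1:
                A[k, idx(i - 1, j)] = csm
            if i < n_sigma - 2:
                A[k, idx(i + 1, j)] = csp
            else:
                b[k] -= csp * p_o
            b[k] += rhs_scale * (si**2 - t[j] ** 2)
    sol = spla.spsolve(A.tocsr(), b)
    P = np.zeros((n_sigma, n_tau))
    P[1:-1, :] = sol.reshape(ni, n_tau)
    P[-1, :] = p_o
    dP_inner = (-3 * P[0, :] + 4 * P[1, :] - P[2, :]) / (2 * hs)
    return s, t, P, float(np.mean(dP_inner))
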