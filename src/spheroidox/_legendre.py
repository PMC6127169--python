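"""Legendre functions of the second kind on the spheroidal domain.

The closed-form oxygen fields need Q0 and Q2 on (1, inf) for prolate
coordinates and their oblate analogues (arccot-based) on (0, inf).  The
textbook expressions, e.g. Q2(s) = P2(s) Q0(s) - 3s/2, cancel
catastrophically for large argument (Q2 ~ 2/(15 s^3) while P2*Q0 ~ 3s/2),
which is exactly the near-spherical regime the sphere-limit checks probe.
Above a switch point the functions are therefore evaluated from their
asymptotic series; below it from the closed forms.  Both branches agree to
~1e-13 relative at the switch.
"""

from __future__ import annotations

import numpy as np

_SWITCH = 4.0
_KMAX = 24  # series truncation; at s = 4 the tail is < 4^-51


def legendre_q0(s):
    """Q0(s) = arcoth(s) = log((s+1)/(s-1))/2 for s > 1."""
    s = np.asarray(s, dtype=float)
    out = np.empty_like(s)
    small = s < _SWITCH
    out[small] = 0.5 * np.log((s[small] + 1.0) / (s[small] - 1.0))
    t = 1.0 / s[~small]
    acc = np.zeros_like(t)
    for k in range(_KMAX, -1, -1):
        acc = acc * t * t + 1.0 / (2 * k + 1)
    out[~small] = t * acc
    return out if out.ndim else float(out)


def legendre_q2(s):
    """Q2(s) for s > 1, stable for large s (~ 2/(15 s^3))."""
    s = np.asarray(s, dtype=float)
    out = np.empty_like(s)
    small = s < _SWITCH
    ss = s[small]
    p2 = (3.0 * ss * ss - 1.0) / 2.0
    out[small] = p2 * 0.5 * np.log((ss + 1.0) / (ss - 1.0)) - 1.5 * ss
    t = 1.0 / s[~small]
    acc = np.zeros_like(t)
    for k in range(_KMAX, 0, -1):
        ck = 1.5 / (2 * k + 3) - 0.5 / (2 * k + 1)
        acc = acc * t * t + ck
    out[~small] = acc * t ** 3
    return out if out.ndim else float(out)


def legendre_q2_prime(s):
    """d/ds Q2(s)."""
    s = np.asarray(s, dtype=float)
    out = np.empty_like(s)
    small = s < _SWITCH
    ss = s[small]
    p2 = (3.0 * ss * ss - 1.0) / 2.0
    q0 = 0.5 * np.log((ss + 1.0) / (ss - 1.0))
    out[small] = 3.0 * ss * q0 - p2 / (ss * ss - 1.0) - 1.5
    t = 1.0 / s[~small]
    acc = np.zeros_like(t)
    for k in range(_KMAX, 0, -1):
        ck = -(2 * k + 1) * (1.5 / (2 * k + 3) - 0.5 / (2 * k + 1))
        acc = acc * t * t + ck
    out[~small] = acc * t ** 4
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Oblate analogues: radial functions of xi = sinh(u) >= 0.  The role of Q0 is
# played by arccot(xi); the degree-2 pair solves ((1+xi^2) y')' = 6 y.

def oblate_q0(x):
    """arccot(x), stable for large x (~ 1/x)."""
    x = np.asarray(x, dtype=float)
    return np.arctan2(1.0, x) if x.ndim else float(np.arctan2(1.0, x))


def oblate_p2(x):
    x = np.asarray(x, dtype=float)
    out = (3.0 * x * x + 1.0) / 2.0
    return out if out.ndim else float(out)


def oblate_q2(x):
    """q2(x) = p2(x) arccot(x) - 3x/2, stable for large x (~ 2/(15 x^3))."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < _SWITCH
    xs = x[small]
    out[small] = (3.0 * xs * xs + 1.0) / 2.0 * np.arctan2(1.0, xs) - 1.5 * xs
    t = 1.0 / x[~small]
    acc = np.zeros_like(t)
    for k in range(_KMAX, 0, -1):
        ck = (-1.0) ** (k + 1) * (1.5 / (2 * k + 3) - 0.5 / (2 * k + 1))
        acc = acc * t * t + ck
    out[~small] = acc * t ** 3
    return out if out.ndim else float(out)


def oblate_q2_prime(x):
    """d/dx q2(x)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < _SWITCH
    xs = x[small]
    p2 = (3.0 * xs * xs + 1.0) / 2.0
    out[small] = 3.0 * xs * np.arctan2(1.0, xs) - p2 / (1.0 + xs * xs) - 1.5
    t = 1.0 / x[~small]
    acc = np.zeros_like(t)
    for k in range(_KMAX, 0, -1):
        ck = (-1.0) ** k * (2 * k + 1) * (1.5 / (2 * k + 3) - 0.5 / (2 * k + 1))
        acc = acc * t * t + ck
    out[~small] = acc * t ** 4
    return out if out.ndim else float(out)
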