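"""Hayes correction factor for flat-punch indentation of a bonded cartilage layer.

Indentation of a thin elastic layer bonded to a rigid substrate (subchondral
bone) is stiffer than indentation of a half-space.  The classical correction
writes the load–displacement relation of a rigid, frictionless, plane-ended
cylindrical indenter of radius ``a`` on a layer of thickness ``h`` as

    E = P (1 - nu^2) / (2 a kappa w)

where ``P`` is load, ``w`` indentation depth and ``kappa(a/h, nu) >= 1`` the
aspect-ratio-dependent correction (``kappa -> 1`` as ``a/h -> 0``, the
Boussinesq half-space flat punch).

``kappa`` is obtained here by solving the mixed boundary-value problem of the
bonded layer exactly.  The surface normal compliance of a layer bonded to a
rigid base is, in Hankel space (``y = xi h``, ``k = 3 - 4 nu``),

    W(y) = (2 k sinh 2y - 4y) / (2 k cosh 2y + 4 y^2 + k^2 + 1)

which reduces to the half-space (W -> 1) for y -> infinity and to confined
uniaxial compression for y -> 0 (both limits are exact; the second fixes the
thin-layer asymptote ``kappa ~ (pi/2)(a/h)(1-nu)^2/(1-2 nu)``).  Splitting
``W = 1 + G`` and Abel-inverting the dual integral equations yields a
Fredholm equation of the second kind for the auxiliary density ``theta`` on
[0, 1],

    theta(s) + (2/pi) \int_0^1 K(s, u) theta(u) du = 2/pi,
    K(s, u) = (tau/2) [C(tau |s-u|) + C(tau (s+u))],
    C(b)    = \int_0^inf G(y) cos(b y) dy,        tau = a/h,

solved by Nystrom quadrature; then ``kappa = (pi/2) \int_0^1 theta``.

The solved values are cached on a grid (a/h in [0, 2] step 0.1; nu in
{0.2, 0.3, 0.4, 0.5}) and queried by bilinear interpolation, with no
extrapolation outside the grid.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = ["hayes_kappa", "hayes_table", "AH_GRID", "NU_GRID"]

AH_GRID = np.round(np.linspace(0.0, 2.0, 21), 3)
NU_GRID = np.array([0.2, 0.3, 0.4, 0.5])


def _layer_compliance(y: np.ndarray, nu: float) -> np.ndarray:
    """Normalized surface compliance W(y) of a bonded layer; W(inf)=1, W(0)=0."""
    k = 3.0 - 4.0 * nu
    num = 2.0 * k * np.sinh(2.0 * y) - 4.0 * y
    den = 2.0 * k * np.cosh(2.0 * y) + 4.0 * y * y + k * k + 1.0
    return num / den


def _kappa_solve(tau: float, nu: float, n_nodes: int = 48) -> float:
    """Solve the contact integral equation for a single (a/h, nu)."""
    if tau == 0.0:
        return 1.0
    # G = W - 1 decays like exp(-2y); the cosine transform is smooth in b.
    y = np.linspace(0.0, 30.0, 6001)
    g = _layer_compliance(y, nu) - 1.0
    bgrid = np.linspace(0.0, 2.0 * tau, 400)
    cvals = np.trapezoid(g[None, :] * np.cos(np.outer(bgrid, y)), y, axis=1)

    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    s = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    b_minus = tau * np.abs(s[:, None] - s[None, :])
    b_plus = tau * (s[:, None] + s[None, :])
    kern = 0.5 * tau * (
        np.interp(b_minus, bgrid, cvals) + np.interp(b_plus, bgrid, cvals)
    )
    a_mat = np.eye(n_nodes) + (2.0 / np.pi) * kern * w[None, :]
    theta = np.linalg.solve(a_mat, np.full(n_nodes, 2.0 / np.pi))
    return float(np.pi / 2.0 * np.sum(w * theta))


@lru_cache(maxsize=1)
def hayes_table() -> np.ndarray:
    """kappa on the (AH_GRID, NU_GRID) grid, shape (len(AH_GRID), len(NU_GRID))."""
    table = np.empty((AH_GRID.size, NU_GRID.size))
    for j, nu in enumerate(NU_GRID):
        for i, ah in enumerate(AH_GRID):
            table[i, j] = _kappa_solve(float(ah), float(nu))
    return table


@lru_cache(maxsize=1)
def _interpolator() -> RegularGridInterpolator:
    return RegularGridInterpolator(
        (AH_GRID, NU_GRID), hayes_table(), method="linear", bounds_error=True
    )


def hayes_kappa(a_over_h: float, nu: float) -> float:
    """Correction factor kappa(a/h, nu), bilinear on the cached grid.

    Parameters
    ----------
    a_over_h : float
        Indenter radius over layer thickness; must lie in [0, 2]
        (no extrapolation — a scan outside this range is mis-set-up).
    nu : float
        Poisson's ratio, in [0.2, 0.5].
    """
    if not 0.0 <= a_over_h <= 2.0:
        raise ValueError(f"a_over_h={a_over_h} outside the tabulated range [0, 2]")
    if not NU_GRID[0] <= nu <= NU_GRID[-1]:
        raise ValueError(f"nu={nu} outside the tabulated range [0.2, 0.5]")
    return float(_interpolator()([a_over_h, nu])[0])
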