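"""Real spherical harmonics in the density-normalized (Hansen-Coppens) convention.

Two angular bases are provided:

* ``real_sph(l, m, vecs)`` -- orthonormal real spherical harmonics
  y_lm with the usual quantum normalization (integral of y_lm^2 over the
  sphere is 1).  ``m > 0`` selects the cos(m phi) combination, ``m < 0``
  the sin(|m| phi) one.

* ``density_sph(l, m, vecs)`` -- density-normalized functions d_lm used by
  the pseudo-atom model.  For l = 0, d_00 = 1/(4 pi) so that a monopole
  population of 1 carries exactly one electron.  For l >= 1 the
  normalization is the conventional charge-transfer one,
  integral of |d_lm| over the sphere = 2, so a population P_lm moves P_lm/2
  electrons from the negative to the positive lobe.

The density-normalization constants are computed once by piecewise
Gauss-Legendre quadrature between the zeros of the associated Legendre
functions (the integrand is analytic on each piece), which reproduces the
tabulated constants, e.g. d_10 = cos(theta)/pi.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq
from scipy.special import lpmv

LMAX = 4


def _assoc_legendre(l: int, m: int, u):
    """P_l^m(u) with the Condon-Shortley phase (scipy convention)."""
    return lpmv(m, l, u)


@lru_cache(maxsize=None)
def _ortho_norm(l: int, m: int) -> float:
    """Normalization constant of the orthonormal real harmonic y_lm."""
    m = abs(m)
    n = math.sqrt((2 * l + 1) / (4 * math.pi)
                  * math.factorial(l - m) / math.factorial(l + m))
    if m > 0:
        n *= math.sqrt(2.0)
    return n


@lru_cache(maxsize=None)
def _abs_theta_integral(l: int, m: int) -> float:
    """integral_0^pi |P_l^m(cos th)| sin th dth, exact by piecewise quadrature."""
    m = abs(m)

    def f(theta):
        return _assoc_legendre(l, m, math.cos(theta)) * math.sin(theta)

    # locate sign changes of P_l^m(cos theta) on (0, pi)
    thetas = np.linspace(1e-9, math.pi - 1e-9, 2001)
    vals = _assoc_legendre(l, m, np.cos(thetas))
    roots = [0.0]
    for i in range(len(thetas) - 1):
        if vals[i] == 0.0:
            roots.append(float(thetas[i]))
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(lambda t: _assoc_legendre(l, m, math.cos(t)),
                                thetas[i], thetas[i + 1], xtol=1e-15))
    roots.append(math.pi)
    nodes, weights = leggauss(64)
    total = 0.0
    for a, b in zip(roots[:-1], roots[1:]):
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        total += half * sum(w * abs(f(mid + half * x))
                            for x, w in zip(nodes, weights))
    return total


@lru_cache(maxsize=None)
def density_norm(l: int, m: int) -> float:
    """Constant C_lm such that d_lm = C_lm * y_lm (density normalization)."""
    if l == 0:
        return 1.0 / math.sqrt(4.0 * math.pi)   # d_00 = 1/(4 pi)
    m = abs(m)
    phi = 2.0 * math.pi if m == 0 else 4.0      # integral of |cos m phi|
    abs_integral = _ortho_norm(l, m) * _abs_theta_integral(l, m) * phi
    return 2.0 / abs_integral


def real_sph(l: int, m: int, vecs: np.ndarray) -> np.ndarray:
    """Orthonormal real spherical harmonic y_lm on an array of direction vectors.

    ``vecs`` has shape (..., 3) and need not be normalized; zero vectors map
    to the +z direction (the caller is expected to mask r = 0 separately).
    """
    v = np.asarray(vecs, dtype=float)
    r = np.linalg.norm(v, axis=-1)
    safe = np.where(r > 0, r, 1.0)
    x, y, z = v[..., 0] / safe, v[..., 1] / safe, v[..., 2] / safe
    z = np.where(r > 0, z, 1.0)
    cos_t = np.clip(z, -1.0, 1.0)
    out = _ortho_norm(l, m) * _assoc_legendre(l, abs(m), cos_t)
    if m > 0:
        out = out * np.cos(m * np.arctan2(y, x))
    elif m < 0:
        out = out * np.sin(-m * np.arctan2(y, x))
    return out


def density_sph(l: int, m: int, vecs: np.ndarray) -> np.ndarray:
    """Density-normalized real spherical harmonic d_lm (see module docstring)."""
    return density_norm(l, m) * real_sph(l, m, vecs)


def lm_keys(lmax: int, m_zero_only: bool = False, include_l0: bool = False):
    """Canonical ordered (l, m) key list for multipole populations."""
    keys = []
    lmin = 0 if include_l0 else 1
    for l in range(lmin, lmax + 1):
        if m_zero_only and l > 0:
            keys.append((l, 0))
        else:
            keys.extend((l, m) for m in range(-l, l + 1))
    return keys
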