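"""Static structure factors of pseudo-atom models.

A molecule sits in a large pseudo-cubic cell of edge ``a`` (Angstrom) and
static (thermally unsmeared) structure factors are evaluated on the integer
reciprocal lattice with the crystallographic convention

    F(H) = integral rho(r) exp(+2 pi i H . r_frac) dV,

at resolutions s = sin(theta)/lambda = |H| / (2 a) up to ``s_max``.  The
atomic radial transforms are Fourier-Bessel integrals of Slater functions,

    <j_l>(q) = integral N r^(n+2) exp(-zeta r) j_l(q r) dr,

computed in closed form (Rayleigh expansion of j_l, with a power series
around q = 0 where the closed form cancels) and cross-checked by fixed
Gauss-Legendre quadrature.  A grid-FFT numeric oracle provides an
independent route to F for any sampled density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import spherical_jn

from . import harmonics
from .errors import (AlignmentError, DegenerateInputError, ResolutionError,
                     ValidationError)
from .model import BOHR_PER_ANGSTROM, MoleculeModel

__all__ = ["HklSet", "StructureFactorSet", "generate_hkl",
           "slater_jl_transform", "structure_factors", "fft_oracle"]


# ----------------------------------------------------------------------------
# reciprocal lattice
# ----------------------------------------------------------------------------

@dataclass
class HklSet:
    """Integer reflections of a pseudo-cubic cell with 0 < s <= s_max."""

    a: float                       # cell edge, Angstrom
    s_max: float                   # resolution bound, 1/Angstrom
    hkl: np.ndarray                # (nrefl, 3) int
    friedel_unique: bool = False

    @property
    def s(self) -> np.ndarray:
        """sin(theta)/lambda per reflection, 1/Angstrom (cubic metric)."""
        return np.linalg.norm(self.hkl, axis=1) / (2.0 * self.a)

    @property
    def q_bohr(self) -> np.ndarray:
        """Scattering vector magnitude q = 4 pi s, bohr^-1."""
        return 4.0 * math.pi * self.s / BOHR_PER_ANGSTROM

    def __len__(self) -> int:
        return len(self.hkl)

    def same_lattice(self, other: "HklSet") -> bool:
        return (abs(self.a - other.a) < 1e-12
                and self.hkl.shape == other.hkl.shape
                and bool(np.all(self.hkl == other.hkl)))


@dataclass
class StructureFactorSet:
    """Complex static structure factors on an :class:`HklSet`."""

    hkl: HklSet
    F: np.ndarray                  # complex, electrons
    valence_only: bool = False

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=complex)
        if self.F.shape != (len(self.hkl),):
            raise ValidationError("F must have one value per reflection")

    def amplitudes(self) -> np.ndarray:
        return np.abs(self.F)


def generate_hkl(a: float, s_max: float, friedel_unique: bool = False) -> HklSet:
    """All integer triples with 0 < |H|/(2a) <= s_max, lexicographic order.

    The origin (s = 0) is strictly excluded; the upper bound is inclusive.
    ``friedel_unique`` keeps exactly one of each +-H pair (hemisphere with
    h > 0, or h = 0 and k > 0, or h = k = 0 and l > 0).
    """
    if a <= 0 or s_max <= 0:
        raise ValidationError("cell edge and s_max must be positive")
    hmax = int(math.floor(2.0 * a * s_max + 1e-12))
    rng = np.arange(-hmax, hmax + 1)
    h, k, l = np.meshgrid(rng, rng, rng, indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    n2 = (hkl ** 2).sum(axis=1)
    keep = (n2 > 0) & (n2 <= (2.0 * a * s_max) ** 2 * (1 + 1e-14))
    if friedel_unique:
        h0, k0, l0 = hkl[:, 0], hkl[:, 1], hkl[:, 2]
        keep &= (h0 > 0) | ((h0 == 0) & (k0 > 0)) | ((h0 == 0) & (k0 == 0) & (l0 > 0))
    return HklSet(a=a, s_max=s_max, hkl=hkl[keep], friedel_unique=friedel_unique)


# ----------------------------------------------------------------------------
# Fourier-Bessel transforms of Slater radial functions
# ----------------------------------------------------------------------------

# Rayleigh decomposition j_l(x) = sum_a c_a sin(x)/x^a + sum_b d_b cos(x)/x^b
_RAYLEIGH = {
    0: ({1: 1.0}, {}),
    1: ({2: 1.0}, {1: -1.0}),
    2: ({3: 3.0, 1: -1.0}, {2: -3.0}),
    3: ({4: 15.0, 2: -6.0}, {3: -15.0, 1: 1.0}),
    4: ({5: 105.0, 3: -45.0, 1: 1.0}, {4: -105.0, 2: 10.0}),
}

_GL200 = leggauss(200)


def _raw_transform_series(l, n, zeta, q):
    """sum_k (-1)^k q^(2k+l) (n+l+2k+2)! / (2^k k! (2l+2k+1)!! zeta^(n+l+2k+3)),
    the Taylor expansion of integral r^(n+2) e^(-zeta r) j_l(q r) dr about q=0.
    Converges for q < zeta; used for q < 0.6 zeta where the Rayleigh closed
    form loses digits to cancellation."""
    q = np.asarray(q, dtype=float)
    dfact = 1.0
    for i in range(1, 2 * l + 2, 2):
        dfact *= i
    term = q ** l * math.factorial(n + l + 2) / (dfact * zeta ** (n + l + 3))
    total = term.copy()
    for k in range(200):
        ratio = (-(q ** 2) / (2.0 * (k + 1) * (2 * l + 2 * k + 3))
                 * (n + l + 2 * k + 4) * (n + l + 2 * k + 3) / zeta ** 2)
        term = term * ratio
        total += term
        if np.all(np.abs(term) <= 1e-17 * (np.abs(total) + 1e-300)):
            break
    return total


def _raw_transform_rayleigh(l, n, zeta, q):
    """Closed form of integral r^(n+2) e^(-zeta r) j_l(q r) dr via the
    Rayleigh expansion; valid termwise when n >= l (all split integrals
    converge).  Uses integral r^m e^(-zeta r) e^(i q r) dr = m!/(zeta-iq)^(m+1)."""
    q = np.asarray(q, dtype=float)
    denom = zeta - 1j * q
    sin_c, cos_c = _RAYLEIGH[l]
    out = np.zeros(q.shape)
    for a, c in sin_c.items():
        m = n + 2 - a
        out = out + c * q ** (-a + 0.0) * np.imag(
            math.factorial(m) / denom ** (m + 1))
    for b, c in cos_c.items():
        m = n + 2 - b
        out = out + c * q ** (-b + 0.0) * np.real(
            math.factorial(m) / denom ** (m + 1))
    return out


def _raw_transform_quadrature(l, n, zeta, q):
    """200-point Gauss-Legendre on [0, 60/zeta] (independent check path,
    and the fallback when n < l makes the closed form inapplicable)."""
    q = np.asarray(q, dtype=float)
    nodes, weights = _GL200
    rmax = 60.0 / zeta
    r = 0.5 * rmax * (nodes + 1.0)
    w = 0.5 * rmax * weights
    integrand = (r ** (n + 2) * np.exp(-zeta * r))[None, :] \
        * spherical_jn(l, np.outer(q, r))
    return integrand @ w


def slater_raw_transform(l: int, n: int, zeta: float, q,
                         method: str = "auto") -> np.ndarray:
    """integral_0^inf r^(n+2) exp(-zeta r) j_l(q r) dr (unnormalized)."""
    if zeta <= 0:
        raise ValidationError("zeta must be positive")
    if l not in _RAYLEIGH:
        raise ValidationError(f"l={l} outside supported range 0..4")
    if n < 1 and l >= 1:
        raise ValidationError(f"n={n} < 1 with l={l} is not integrable at 0")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValidationError("q must be non-negative")
    scalar = q.ndim == 0
    q = np.atleast_1d(q)
    if method == "quadrature":
        out = _raw_transform_quadrature(l, n, zeta, q)
    else:
        out = np.empty_like(q)
        near = q < 0.6 * zeta
        if np.any(near):
            out[near] = _raw_transform_series(l, n, zeta, q[near])
        far = ~near
        if np.any(far):
            if n >= l:
                out[far] = _raw_transform_rayleigh(l, n, zeta, q[far])
            else:
                out[far] = _raw_transform_quadrature(l, n, zeta, q[far])
    return out[0] if scalar else out


def slater_jl_transform(l: int, n: int, zeta: float, q,
                        method: str = "auto") -> np.ndarray:
    """Normalized <j_l>(q) with N = zeta^(n+3)/(n+2)!; <j_0>(0) = 1."""
    norm = zeta ** (n + 3) / math.factorial(n + 2)
    return norm * slater_raw_transform(l, n, zeta, q, method=method)


def _spherical_form_factor(terms, q) -> np.ndarray:
    """f(q) = integral rho_sph(r) j_0(qr) 4 pi r^2 dr for Slater density terms."""
    out = np.zeros(np.shape(q))
    for t in terms:
        out = out + 4.0 * math.pi * t.coeff \
            * slater_raw_transform(0, t.n_power, t.zeta, q)
    return out


# ----------------------------------------------------------------------------
# analytic structure factors
# ----------------------------------------------------------------------------

class HklGeometryCache:
    """Per-(HklSet, model) geometry reused across refinement iterations:
    unique |q| values, per-atom phases, per-atom local-frame d_lm tables."""

    def __init__(self, hkl: HklSet, model: MoleculeModel):
        self.hkl = hkl
        q = hkl.q_bohr
        n2 = (hkl.hkl.astype(np.int64) ** 2).sum(axis=1)
        self._uniq_n2, self.inverse = np.unique(n2, return_inverse=True)
        a_bohr = hkl.a * BOHR_PER_ANGSTROM
        self.q_unique = 2.0 * math.pi * np.sqrt(self._uniq_n2.astype(float)) / a_bohr
        norms = np.linalg.norm(hkl.hkl, axis=1)
        self.dirs = hkl.hkl / norms[:, None]
        self._phases: dict[int, np.ndarray] = {}
        self._dlm: dict[int, dict[tuple[int, int], np.ndarray]] = {}
        self.model = model
        self.a = hkl.a
        del q

    def phase(self, atom_index: int) -> np.ndarray:
        if atom_index not in self._phases:
            x_frac = self.model.geometry.positions[atom_index] \
                / (self.a * BOHR_PER_ANGSTROM)
            self._phases[atom_index] = np.exp(
                2j * math.pi * (self.hkl.hkl @ x_frac))
        return self._phases[atom_index]

    def dlm(self, atom_index: int, l: int, m: int) -> np.ndarray:
        tab = self._dlm.setdefault(atom_index, {})
        if (l, m) not in tab:
            frame = self.model.pseudo_atoms[atom_index].frame
            local = self.dirs @ frame.matrix.T
            tab[(l, m)] = harmonics.density_sph(l, m, local)
        return tab[(l, m)]

    def expand(self, values_unique: np.ndarray) -> np.ndarray:
        return values_unique[self.inverse]


def atom_form_factors(cache: HklGeometryCache, atom, entry,
                      include_core: bool) -> np.ndarray:
    """Unphased complex atomic scattering contribution on the hkl set."""
    qu = cache.q_unique
    f = np.zeros(len(cache.hkl), dtype=complex)
    if include_core and atom.P_core and entry.core_terms:
        f += atom.P_core * cache.expand(_spherical_form_factor(entry.core_terms, qu))
    if entry.n_val > 0:
        # per-electron valence form factor (stored density integrates to n_val)
        f += (atom.P_val / entry.n_val) * cache.expand(
            _spherical_form_factor(entry.valence_terms, qu / atom.kappa))
    for (l, m), p in atom.P_lm.items():
        if p == 0.0:
            continue
        n_l, zeta_l = entry.deformation[l]
        jl = cache.expand(
            slater_jl_transform(l, n_l, zeta_l, qu / atom.kappa_prime))
        f = f + p * (4.0 * math.pi * (1j) ** l) * jl * cache.dlm(
            atom.geometry_index, l, m)
    return f


def structure_factors(model: MoleculeModel, hkl: HklSet,
                      include_core: bool = True,
                      cache: HklGeometryCache | None = None) -> StructureFactorSet:
    """Analytic F(H) of a pseudo-atom model.

    F(H) = sum_atoms exp(2 pi i H.x_frac) [P_core f_core(q) +
    P_val f_val(q/kappa) + sum_lm P_lm 4 pi i^l <j_l>(q/kappa') d_lm(H_local)].
    ``include_core=False`` gives valence-only structure factors.
    """
    if cache is None or cache.model is not model:
        cache = HklGeometryCache(hkl, model)
    F = np.zeros(len(hkl), dtype=complex)
    for atom in model.pseudo_atoms:
        entry = model.databank[atom.databank_element]
        F += cache.phase(atom.geometry_index) \
            * atom_form_factors(cache, atom, entry, include_core)
    return StructureFactorSet(hkl=hkl, F=F, valence_only=not include_core)


def gaussian_structure_factors(centers_bohr, amplitudes, sigmas_bohr,
                               hkl: HklSet) -> np.ndarray:
    """Exact F of a sum of normalized isotropic Gaussian blobs (electrons)."""
    a_bohr = hkl.a * BOHR_PER_ANGSTROM
    k = 2.0 * math.pi * np.linalg.norm(hkl.hkl, axis=1) / a_bohr
    F = np.zeros(len(hkl), dtype=complex)
    for c, amp, sig in zip(np.atleast_2d(centers_bohr), amplitudes, sigmas_bohr):
        phase = np.exp(2j * math.pi * (hkl.hkl @ (np.asarray(c) / a_bohr)))
        F += amp * phase * np.exp(-0.5 * (sig * k) ** 2)
    return F


# ----------------------------------------------------------------------------
# grid-FFT oracle
# ----------------------------------------------------------------------------

def fft_oracle(field, hkl: HklSet) -> StructureFactorSet:
    """Discrete Fourier transform of a sampled density, indexed at hkl.

    The field must periodically tile the unit cell: step * npoints = a
    (samples at origin + j*step, no duplicated endpoint).  Raises
    :class:`ResolutionError` when any index reaches the Nyquist limit.
    """
    spec = field.spec
    a_bohr = hkl.a * BOHR_PER_ANGSTROM
    if abs(spec.step * spec.npoints - a_bohr) > 1e-6:
        raise AlignmentError(
            f"field box (step*npoints = {spec.step * spec.npoints:.6f} bohr) "
            f"does not equal the cell edge {a_bohr:.6f} bohr")
    n = spec.npoints
    if np.max(np.abs(hkl.hkl)) >= n // 2:
        raise ResolutionError(
            f"max index {np.max(np.abs(hkl.hkl))} reaches the Nyquist limit "
            f"of a {n}^3 grid")
    values = np.asarray(field.values, dtype=float)
    if values.shape != (n, n, n):
        raise DegenerateInputError("field values are not npoints^3")
    transform = np.fft.ifftn(values) * n ** 3 * spec.step ** 3
    idx = np.mod(hkl.hkl, n)
    F = transform[idx[:, 0], idx[:, 1], idx[:, 2]]
    origin_frac = np.asarray(spec.origin, dtype=float) / a_bohr
    F = F * np.exp(2j * math.pi * (hkl.hkl @ origin_frac))
    return StructureFactorSet(hkl=hkl, F=F)


# ----------------------------------------------------------------------------
# structure-factor file I/O
# ----------------------------------------------------------------------------

def write_sf_file(sf: StructureFactorSet, path) -> None:
    lines = [f"# a={sf.hkl.a!r} s_max={sf.hkl.s_max!r} "
             f"valence_only={int(sf.valence_only)} "
             f"friedel_unique={int(sf.hkl.friedel_unique)}"]
    for (h, k, l), F in zip(sf.hkl.hkl, sf.F):
        lines.append(f"{h} {k} {l} {float(F.real)!r} {float(F.imag)!r}")
    from pathlib import Path as _P
    _P(path).write_text("\n".join(lines) + "\n")


def read_sf_file(path) -> StructureFactorSet:
    from pathlib import Path as _P
    from .errors import ParseError
    lines = _P(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ParseError(f"{path}: missing header line")
    meta = dict(tok.split("=") for tok in lines[0][1:].split())
    hkl_rows, F = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        t = line.split()
        if len(t) != 5:
            raise ParseError(f"{path}:{lineno}: expected 'h k l Freal Fimag'")
        hkl_rows.append([int(t[0]), int(t[1]), int(t[2])])
        F.append(complex(float(t[3]), float(t[4])))
    hkl = HklSet(a=float(meta["a"]), s_max=float(meta["s_max"]),
                 hkl=np.array(hkl_rows, dtype=int),
                 friedel_unique=bool(int(meta.get("friedel_unique", 0))))
    return StructureFactorSet(hkl=hkl, F=np.array(F),
                              valence_only=bool(int(meta.get("valence_only", 0))))
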