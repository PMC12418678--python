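"""Cubic grids, electron density and electrostatic potential fields.

Grids follow the Gaussian cube convention: isotropic step, x slowest /
z fastest, points at origin + j*step along each axis with ``npoints``
points per axis (so the edge length is step*(npoints-1)).

The electrostatic potential (a.u., hartree/e) of a pseudo-atom model is

    V(r) = sum_A Z_A / |r - R_A|  -  electron term,

where each atom's electron term is evaluated analytically per radial
component through the inside/outside multipole decomposition

    V_lm(r) = 4 pi/(2l+1) [ r^(-l-1) I< + r^l I> ] d_lm(Omega),
    I< = integral_0^r f(s) s^(l+2) ds,   I> = integral_r^inf f(s) s^(1-l) ds,

with incomplete-gamma closed forms for the Slater radial components.  For
grid work the per-atom radial potentials are tabulated on a dense
logarithmic mesh and linearly interpolated (relative error ~1e-6,
documented in the methods note); ``exact=True`` evaluates the closed
forms pointwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import quad
from scipy.special import gammainc, gammaincc

from . import harmonics
from .databank import deformation_norm
from .errors import ParseError, ValidationError
from .model import BOHR_PER_ANGSTROM, MoleculeGeometry, MoleculeModel

#: a.u. -> kcal/mol/e, applied only at the reporting layer
HARTREE_TO_KCALMOL = 627.5094740631

#: grid points closer to a nucleus than this (bohr) get the nuclear term
#: evaluated at this offset instead (deterministic singularity handling)
NUCLEAR_OFFSET = 1e-6


# ----------------------------------------------------------------------------
# grids
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Cubic grid: origin (bohr), isotropic step (bohr), points per axis."""

    origin: tuple[float, float, float]
    step: float
    npoints: int

    def __post_init__(self):
        if self.step <= 0:
            raise ValidationError("grid step must be positive")
        if self.npoints < 2:
            raise ValidationError("npoints must be >= 2")
        object.__setattr__(self, "origin",
                           tuple(float(v) for v in self.origin))

    @property
    def edge(self) -> float:
        """Edge length, bohr: step * (npoints - 1)."""
        return self.step * (self.npoints - 1)

    @property
    def npoints_total(self) -> int:
        return self.npoints ** 3

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.origin[i] + self.step * np.arange(self.npoints)
                     for i in range(3))

    def voxel_volume(self) -> float:
        return self.step ** 3

    @staticmethod
    def centered(center, edge: float, npoints: int) -> "GridSpec":
        step = edge / (npoints - 1)
        origin = tuple(np.asarray(center, dtype=float) - edge / 2.0)
        return GridSpec(origin, step, npoints)

    @staticmethod
    def cell_filling(a_angstrom: float, npoints: int,
                     origin=(0.0, 0.0, 0.0)) -> "GridSpec":
        """Grid that periodically tiles a cubic cell (step = a/npoints),
        as required by the FFT oracle."""
        a_bohr = a_angstrom * BOHR_PER_ANGSTROM
        return GridSpec(tuple(origin), a_bohr / npoints, npoints)


def make_grid(spec: GridSpec) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray], int]:
    """Axis coordinate arrays and total point count (lazy; no N^3 allocation)."""
    return spec.axes(), spec.npoints_total


def _iter_point_slabs(spec: GridSpec, max_points: int = 2_000_000):
    """Yield (x-slice, flat points array) slabs in grid order."""
    ax, ay, az = spec.axes()
    n = spec.npoints
    planes_per_slab = max(1, max_points // (n * n))
    yy, zz = np.meshgrid(ay, az, indexing="ij")
    for i0 in range(0, n, planes_per_slab):
        i1 = min(n, i0 + planes_per_slab)
        xs = ax[i0:i1]
        pts = np.empty(((i1 - i0), n, n, 3))
        pts[..., 0] = xs[:, None, None]
        pts[..., 1] = yy[None, :, :]
        pts[..., 2] = zz[None, :, :]
        yield slice(i0, i1), pts.reshape(-1, 3)


@dataclass
class ScalarField:
    """Scalar values on a :class:`GridSpec` (density e/bohr^3 or ESP a.u.)."""

    spec: GridSpec
    kind: str                       # "density" | "esp"
    values: np.ndarray              # (n, n, n), x slowest / z fastest
    provenance: str = "model"       # "model" | "iam" | "reference"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.spec.npoints
        if self.values.shape != (n, n, n):
            raise ValidationError(
                f"values shape {self.values.shape} != ({n}, {n}, {n})")

    def same_spec(self, other: "ScalarField") -> bool:
        a, b = self.spec, other.spec
        return (a.npoints == b.npoints and abs(a.step - b.step) < 1e-12
                and np.allclose(a.origin, b.origin, atol=1e-12))

    def integral(self) -> float:
        """Voxel-sum quadrature: sum(values) * step^3."""
        return float(self.values.sum() * self.spec.voxel_volume())


# ----------------------------------------------------------------------------
# density fields
# ----------------------------------------------------------------------------

def density_field(source, spec: GridSpec, include_core: bool = True,
                  provenance: str | None = None) -> ScalarField:
    """Pointwise density of a :class:`MoleculeModel` or synthetic reference."""
    n = spec.npoints
    values = np.empty((n, n, n))
    for sl, pts in _iter_point_slabs(spec):
        values[sl] = _source_density(source, pts, include_core).reshape(
            -1, n, n)
    if provenance is None:
        provenance = "reference" if hasattr(source, "bumps") else "model"
    return ScalarField(spec, "density", values, provenance)


def _source_density(source, pts, include_core):
    from .model import model_density
    if isinstance(source, MoleculeModel):
        return model_density(source, pts, include_core=include_core)
    return source.density(pts, include_core=include_core)


# ----------------------------------------------------------------------------
# electrostatic potential
# ----------------------------------------------------------------------------

def _slater_potential_terms(c: float, n: int, zeta: float, l: int, r):
    """Electron-term potential of the density component c r^n e^(-zeta r) d_lm:

    4 pi/(2l+1) [ r^(-l-1) integral_0^r c s^(n+l+2) e^(-zeta s) ds
                + r^l     integral_r^inf c s^(n+1-l) e^(-zeta s) ds ].
    Returned without the angular factor d_lm.
    """
    r = np.asarray(r, dtype=float)
    rs = np.where(r > 0, r, NUCLEAR_OFFSET)
    x = zeta * rs
    a_in = n + l + 3
    inner = gammainc(a_in, x) * math.factorial(a_in - 1) / zeta ** a_in
    m_out = n + 1 - l
    if m_out >= 0:
        outer = gammaincc(m_out + 1, x) * math.factorial(m_out) / zeta ** (m_out + 1)
    else:
        # rare n < l case: numeric upper integral, vectorized over the table
        outer = np.array([
            quad(lambda s, rv=rv: s ** m_out * math.exp(-zeta * s),
                 rv, 60.0 / zeta, limit=200)[0] for rv in np.atleast_1d(rs)
        ]).reshape(rs.shape)
    return (4.0 * math.pi / (2 * l + 1)) * c * (
        rs ** (-l - 1) * inner + rs ** l * outer)


class _RadialTable:
    """Dense log-mesh tabulation of a radial potential component."""

    __slots__ = ("r", "v")

    def __init__(self, func, rmax: float, npts: int = 4000):
        self.r = np.concatenate([[0.0], np.geomspace(1e-6, rmax, npts)])
        self.v = func(self.r)

    def __call__(self, r):
        return np.interp(r, self.r, self.v)


def _atom_esp(atom, entry, dvec, r, exact: bool, rmax: float):
    """Electron-term ESP contribution (positive sign) of one pseudo-atom."""
    out = np.zeros(r.shape)

    def spherical(rr):
        tot = np.zeros(np.shape(rr))
        if atom.P_core and entry.core_terms:
            for t in entry.core_terms:
                tot += _slater_potential_terms(
                    atom.P_core * t.coeff, t.n_power, t.zeta, 0, rr)
        k = atom.kappa
        if entry.n_val > 0:
            pv = atom.P_val / entry.n_val     # per-electron valence density
            for t in entry.valence_terms:
                # pv k^3 rho_val(k r): same Slater family, c' = c pv k^(n+3)
                tot += _slater_potential_terms(
                    pv * t.coeff * k ** (t.n_power + 3),
                    t.n_power, t.zeta * k, 0, rr)
        return tot

    if exact:
        out += spherical(r)
    else:
        out += _RadialTable(spherical, rmax)(r)

    active = [(lm, p) for lm, p in atom.P_lm.items() if p != 0.0]
    if active:
        local = atom.frame.to_local(dvec) if atom.frame is not None else dvec
        kp = atom.kappa_prime
        for (l, m), p in active:
            n_l, zeta_l = entry.deformation[l]
            c = p * deformation_norm(n_l, zeta_l) * kp ** (n_l + 3)

            def radial(rr, c=c, n_l=n_l, z=zeta_l * kp, l=l):
                return _slater_potential_terms(c, n_l, z, l, rr)

            rad = radial(r) if exact else _RadialTable(radial, rmax)(r)
            out += rad * harmonics.density_sph(l, m, local)
    return out


def esp_field(source, spec: GridSpec, exact: bool = False,
              provenance: str | None = None) -> ScalarField:
    """Electrostatic potential field (a.u.) of a model or synthetic reference."""
    model = source.model if hasattr(source, "model") else source
    if not isinstance(model, MoleculeModel):
        raise ValidationError("esp_field needs a MoleculeModel or a synthetic "
                              "reference wrapping one")
    geo = model.geometry
    corners = np.array(spec.origin)
    rmax = math.sqrt(3.0) * spec.edge + float(
        np.max(np.linalg.norm(geo.positions - corners, axis=1))) + 10.0

    n = spec.npoints
    values = np.empty((n, n, n))
    for sl, pts in _iter_point_slabs(spec, max_points=600_000):
        v = np.zeros(pts.shape[0])
        for atom in model.pseudo_atoms:
            entry = model.databank[atom.databank_element]
            dvec = pts - geo.positions[atom.geometry_index]
            r = np.linalg.norm(dvec, axis=1)
            rn = np.maximum(r, NUCLEAR_OFFSET)
            v += geo.nuclear_charges[atom.geometry_index] / rn
            v -= _atom_esp(atom, entry, dvec, r, exact, rmax)
        if hasattr(source, "bumps"):
            v += source.bump_esp(pts)
        values[sl] = v.reshape(-1, n, n)
    if provenance is None:
        provenance = "reference" if hasattr(source, "bumps") else "model"
    return ScalarField(spec, "esp", values, provenance)


def coulomb_esp_field(positions_bohr, charges, spec: GridSpec) -> ScalarField:
    """ESP of bare point charges (test/diagnostic helper)."""
    n = spec.npoints
    values = np.empty((n, n, n))
    positions = np.atleast_2d(np.asarray(positions_bohr, dtype=float))
    for sl, pts in _iter_point_slabs(spec):
        v = np.zeros(pts.shape[0])
        for pos, q in zip(positions, charges):
            r = np.maximum(np.linalg.norm(pts - pos, axis=1), NUCLEAR_OFFSET)
            v += q / r
        values[sl] = v.reshape(-1, n, n)
    return ScalarField(spec, "esp", values, "model")


def subtract(field_a: ScalarField, field_b: ScalarField) -> ScalarField:
    """Difference map a - b (deformation-map construction)."""
    if not field_a.same_spec(field_b):
        raise ValidationError("difference maps need identical grid specs")
    if field_a.kind != field_b.kind:
        raise ValidationError("difference maps need identical field kinds")
    return ScalarField(field_a.spec, field_a.kind,
                       field_a.values - field_b.values,
                       f"{field_a.provenance}-{field_b.provenance}")


# ----------------------------------------------------------------------------
# Gaussian cube I/O
# ----------------------------------------------------------------------------

def cube_write(field: ScalarField, path,
               geometry: MoleculeGeometry | None = None) -> None:
    """Write a Gaussian cube file (bohr, z fastest) plus a JSON sidecar.

    Values are written with 17 significant digits so a write -> read round
    trip is bit-identical.
    """
    path = Path(path)
    spec = field.spec
    lines = [f"mmfit cube kind={field.kind} provenance={field.provenance}",
             "generated by mmfit.fields.cube_write"]
    natoms = geometry.natoms if geometry is not None else 1
    ox, oy, oz = spec.origin
    lines.append(f"{natoms:5d} {ox: .10E} {oy: .10E} {oz: .10E}")
    for k in range(3):
        v = [0.0, 0.0, 0.0]
        v[k] = spec.step
        lines.append(f"{spec.npoints:5d} {v[0]: .10E} {v[1]: .10E} {v[2]: .10E}")
    if geometry is not None:
        for z, p in zip(geometry.nuclear_charges, geometry.positions):
            lines.append(f"{int(z):5d} {float(z): .10E} "
                         f"{p[0]: .10E} {p[1]: .10E} {p[2]: .10E}")
    else:
        lines.append(f"{1:5d} {0.0: .10E} {0.0: .10E} {0.0: .10E} {0.0: .10E}")
    flat = field.values.reshape(-1)      # C order = z fastest
    for i in range(0, flat.size, 6):
        lines.append(" ".join(f"{v: .16E}" for v in flat[i:i + 6]))
    path.write_text("\n".join(lines) + "\n")
    sidecar = {"kind": field.kind, "provenance": field.provenance,
               "origin_bohr": list(spec.origin), "step_bohr": spec.step,
               "npoints": spec.npoints}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1) + "\n")


def cube_read(path) -> ScalarField:
    """Read a Gaussian cube file written by :func:`cube_write` (or any cube
    with orthogonal, isotropic axes)."""
    path = Path(path)
    lines = path.read_text().split("\n")
    header = lines[0]
    kind = "density"
    provenance = "model"
    for tok in header.split():
        if tok.startswith("kind="):
            kind = tok[5:]
        elif tok.startswith("provenance="):
            provenance = tok[11:]
    try:
        t = lines[2].split()
        natoms = int(t[0])
        origin = tuple(float(v) for v in t[1:4])
        ns, steps = [], []
        for k in range(3):
            t = lines[3 + k].split()
            ns.append(int(t[0]))
            vec = np.array([float(v) for v in t[1:4]])
            if np.count_nonzero(vec) != 1 or vec[k] <= 0:
                raise ParseError(f"{path}: non-orthogonal or non-positive "
                                 f"cube axis {vec}")
            steps.append(vec[k])
    except (IndexError, ValueError):
        raise ParseError(f"{path}: malformed cube header") from None
    if len(set(ns)) != 1 or abs(steps[0] - steps[1]) > 1e-12 \
            or abs(steps[0] - steps[2]) > 1e-12:
        raise ParseError(f"{path}: only isotropic cubic grids are supported")
    n = ns[0]
    data_start = 6 + abs(natoms)
    flat = np.array(" ".join(lines[data_start:]).split(), dtype=float)
    if flat.size != n ** 3:
        raise ParseError(f"{path}: {flat.size} values found, header "
                         f"promises {n ** 3}")
    spec = GridSpec(origin, steps[0], n)
    return ScalarField(spec, kind, flat.reshape(n, n, n), provenance)
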