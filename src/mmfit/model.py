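"""Hansen-Coppens pseudo-atom molecules.

Each atom's electron density is

    rho_atom(r) = P_core rho_core(r) + P_val kappa^3 rho_val(kappa r)
                + sum_l kappa'^3 R_l(kappa' r) sum_m P_lm d_lm(theta, phi)

with r measured from the nucleus and the angular functions d_lm
(density-normalized real spherical harmonics, :mod:`mmfit.harmonics`)
oriented in the atom's local frame.  Populations P_val, P_lm and the
radial scaling parameters kappa (spherical valence) and kappa'
(deformation valence) are the refinable quantities; P_core stays fixed at
1 and core density never enters the refined (valence-only) structure
factors.

Constraint semantics follow charge-density practice: symmetry-equivalent
atoms may share populations (ties), chemically identical hydrogens share
kappa/kappa', and hydrogens carry only bond-oriented (m = 0) multipoles
up to quadrupole with the local z axis along the X-H bond.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import harmonics
from .databank import RadialDatabank, spherical_density
from .errors import (CapabilityError, ConstraintError, FrameError, ParseError,
                     ValidationError)

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR = 0.529177210903

_SYMBOL_TO_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "Mg": 12, "Cl": 17,
                "He": 2, "Li": 3, "B": 5, "F": 9, "Na": 11, "P": 15, "S": 16}


# ----------------------------------------------------------------------------
# geometry
# ----------------------------------------------------------------------------

@dataclass
class MoleculeGeometry:
    """Atom symbols, nuclear charges, Cartesian positions (bohr) and bonds."""

    symbols: list[str]
    positions: np.ndarray          # (natoms, 3), bohr
    bonds: list[tuple[int, int]] = field(default_factory=list)
    net_charge: int = 0
    nuclear_charges: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.symbols), 3):
            raise ValidationError("positions must be (natoms, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("positions must be finite")
        if self.nuclear_charges is None:
            try:
                self.nuclear_charges = np.array(
                    [_SYMBOL_TO_Z[s] for s in self.symbols], dtype=float)
            except KeyError as exc:
                raise ValidationError(f"unknown element symbol {exc}") from None
        self.nuclear_charges = np.asarray(self.nuclear_charges, dtype=float)
        n = len(self.symbols)
        self.bonds = [tuple(sorted((int(i), int(j)))) for i, j in self.bonds]
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValidationError(f"invalid bond ({i}, {j})")

    @property
    def natoms(self) -> int:
        return len(self.symbols)

    def neighbors(self, i: int) -> list[int]:
        out = [b if a == i else a for a, b in self.bonds if i in (a, b)]
        return sorted(out)

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)


def read_xyz(path) -> MoleculeGeometry:
    """Read XYZ (Angstrom); the comment line may hold a JSON extension record
    ``{"bonds": [[i, j], ...], "net_charge": q}``."""
    lines = Path(path).read_text().splitlines()
    try:
        natoms = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise ParseError(f"{path}:1: expected atom count") from None
    comment = lines[1] if len(lines) > 1 else ""
    bonds, charge = [], 0
    if comment.strip().startswith("{"):
        meta = json.loads(comment)
        bonds = [tuple(b) for b in meta.get("bonds", [])]
        charge = int(meta.get("net_charge", 0))
    symbols, pos = [], []
    for lineno, line in enumerate(lines[2:2 + natoms], start=3):
        tokens = line.split()
        if len(tokens) < 4:
            raise ParseError(f"{path}:{lineno}: expected 'symbol x y z'")
        symbols.append(tokens[0])
        pos.append([float(t) for t in tokens[1:4]])
    if len(symbols) != natoms:
        raise ParseError(f"{path}: header says {natoms} atoms, found {len(symbols)}")
    return MoleculeGeometry(symbols, np.array(pos) * BOHR_PER_ANGSTROM,
                            bonds=bonds, net_charge=charge)


def write_xyz(geometry: MoleculeGeometry, path) -> None:
    meta = json.dumps({"bonds": [list(b) for b in geometry.bonds],
                       "net_charge": geometry.net_charge})
    lines = [str(geometry.natoms), meta]
    for sym, p in zip(geometry.symbols, geometry.positions * ANGSTROM_PER_BOHR):
        lines.append(f"{sym} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------------
# local frames
# ----------------------------------------------------------------------------

@dataclass
class LocalFrame:
    """Right-handed orthonormal axes (rows x, y, z in global coordinates)."""

    matrix: np.ndarray              # (3, 3); rows are x, y, z axes
    origin_atom: int = -1

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-10):
            raise FrameError("frame axes are not orthonormal")
        self.matrix = m

    @property
    def handedness(self) -> int:
        return int(round(np.linalg.det(self.matrix)))

    def to_local(self, vecs: np.ndarray) -> np.ndarray:
        return np.asarray(vecs) @ self.matrix.T


@dataclass(frozen=True)
class FrameRules:
    """How local frames are derived from bonding."""

    h_bond_oriented: bool = True


def _orthonormal_completion(z: np.ndarray, x_hint: np.ndarray | None) -> np.ndarray:
    z = z / np.linalg.norm(z)
    if x_hint is None:
        # deterministic fallback: global axis least aligned with z
        k = int(np.argmin(np.abs(z)))
        x_hint = np.eye(3)[k]
    x = x_hint - np.dot(x_hint, z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-10:
        k = int(np.argmin(np.abs(z)))
        x = np.eye(3)[k] - z[k] * z
        nx = np.linalg.norm(x)
    x = x / nx
    y = np.cross(z, x)
    return np.vstack([x, y, z])


def build_local_frames(geometry: MoleculeGeometry,
                       rules: FrameRules = FrameRules()) -> list[LocalFrame]:
    """One frame per atom.  Hydrogen z points along the H -> neighbor bond
    (bond-oriented multipoles); heavy atoms take z toward their first bonded
    neighbor and x toward the second, Gram-Schmidt orthogonalized."""
    frames = []
    for i, sym in enumerate(geometry.symbols):
        nbrs = geometry.neighbors(i)
        if sym == "H" and rules.h_bond_oriented:
            if len(nbrs) != 1:
                raise FrameError(
                    f"atom {i} (H) must have exactly one bond for "
                    f"bond-oriented multipoles, has {len(nbrs)}")
            z = geometry.positions[nbrs[0]] - geometry.positions[i]
            frames.append(LocalFrame(_orthonormal_completion(z, None), i))
            continue
        if nbrs:
            z = geometry.positions[nbrs[0]] - geometry.positions[i]
            hint = None
            if len(nbrs) > 1:
                hint = geometry.positions[nbrs[1]] - geometry.positions[i]
            frames.append(LocalFrame(_orthonormal_completion(z, hint), i))
        else:
            frames.append(LocalFrame(np.eye(3), i))
    return frames


# ----------------------------------------------------------------------------
# pseudo-atoms, constraints, model
# ----------------------------------------------------------------------------

HEAVY_LMAX = 4      # hexadecapole truncation for non-hydrogen atoms
H_LMAX = 2          # quadrupole truncation for hydrogen


@dataclass
class PseudoAtom:
    """Hansen-Coppens parameters of one atom."""

    geometry_index: int
    databank_element: str
    P_val: float
    kappa: float = 1.0
    kappa_prime: float = 1.0
    P_lm: dict[tuple[int, int], float] = field(default_factory=dict)
    lmax_atom: int = HEAVY_LMAX
    frame: LocalFrame | None = None
    P_core: float = 1.0
    bond_oriented: bool = False     # hydrogen: m = 0 multipoles only

    def lm_keys(self) -> list[tuple[int, int]]:
        return harmonics.lm_keys(self.lmax_atom, m_zero_only=self.bond_oriented,
                                 include_l0=(0, 0) in self.P_lm)

    def copy(self) -> "PseudoAtom":
        return replace(self, P_lm=dict(self.P_lm))


ParamRef = tuple[int, object]       # (atom_index, "P_val" | "kappa" | "kappa_prime" | (l, m))


@dataclass
class ConstraintSet:
    """Ties (groups kept equal), fixed parameters, hydrogen conventions."""

    ties: list[list[ParamRef]] = field(default_factory=list)
    fixed: list[ParamRef] = field(default_factory=list)
    h_bond_oriented: bool = True
    shared_h_kappas: list[list[int]] = field(default_factory=list)

    def expanded_ties(self) -> list[list[ParamRef]]:
        """Ties plus the kappa/kappa' groups implied by shared_h_kappas."""
        groups = [list(g) for g in self.ties]
        for atoms in self.shared_h_kappas:
            if len(atoms) > 1:
                groups.append([(a, "kappa") for a in atoms])
                groups.append([(a, "kappa_prime") for a in atoms])
        seen = {}
        for gi, group in enumerate(groups):
            for ref in group:
                if ref in seen and seen[ref] != gi:
                    raise ConstraintError(f"parameter {ref} appears in two tie groups")
                seen[ref] = gi
        return groups


@dataclass
class MoleculeModel:
    """Geometry + pseudo-atoms + constraints + radial databank."""

    geometry: MoleculeGeometry
    pseudo_atoms: list[PseudoAtom]
    constraints: ConstraintSet
    databank: RadialDatabank

    def __post_init__(self):
        if len(self.pseudo_atoms) != self.geometry.natoms:
            raise ValidationError("one pseudo-atom per geometry atom required")
        for atom in self.pseudo_atoms:
            entry = self.databank[atom.databank_element]
            if atom.lmax_atom > max(entry.lmax_supported, 0):
                raise CapabilityError(
                    f"atom {atom.geometry_index} ({atom.databank_element}): "
                    f"lmax {atom.lmax_atom} exceeds databank support "
                    f"{entry.lmax_supported}")

    def copy(self) -> "MoleculeModel":
        return MoleculeModel(self.geometry,
                             [a.copy() for a in self.pseudo_atoms],
                             self.constraints, self.databank)


def build_model(geometry: MoleculeGeometry, databank: RadialDatabank,
                constraints: ConstraintSet | None = None,
                rules: FrameRules = FrameRules()) -> MoleculeModel:
    """Neutral spherical starting model (all multipoles zero, kappas 1)."""
    constraints = constraints or ConstraintSet(h_bond_oriented=rules.h_bond_oriented)
    frames = build_local_frames(geometry, rules)
    atoms = []
    for i, sym in enumerate(geometry.symbols):
        entry = databank[sym]
        is_h = sym == "H"
        lmax = H_LMAX if is_h else HEAVY_LMAX
        lmax = min(lmax, entry.lmax_supported)
        bond_oriented = is_h and constraints.h_bond_oriented
        keys = harmonics.lm_keys(lmax, m_zero_only=bond_oriented)
        atoms.append(PseudoAtom(
            geometry_index=i, databank_element=sym, P_val=entry.n_val,
            P_lm={k: 0.0 for k in keys}, lmax_atom=lmax, frame=frames[i],
            bond_oriented=bond_oriented))
    return MoleculeModel(geometry, atoms, constraints, databank)


# ----------------------------------------------------------------------------
# parameter packing
# ----------------------------------------------------------------------------

def _atom_param_refs(atom: PseudoAtom) -> list[ParamRef]:
    refs: list[ParamRef] = [(atom.geometry_index, "P_val"),
                            (atom.geometry_index, "kappa"),
                            (atom.geometry_index, "kappa_prime")]
    refs.extend((atom.geometry_index, key) for key in sorted(atom.P_lm))
    return refs


def _get_param(model: MoleculeModel, ref: ParamRef) -> float:
    atom = model.pseudo_atoms[ref[0]]
    if ref[1] == "P_val":
        return atom.P_val
    if ref[1] == "kappa":
        return atom.kappa
    if ref[1] == "kappa_prime":
        return atom.kappa_prime
    return atom.P_lm[ref[1]]


def _set_param(model: MoleculeModel, ref: ParamRef, value: float) -> None:
    atom = model.pseudo_atoms[ref[0]]
    if ref[1] == "P_val":
        atom.P_val = value
    elif ref[1] == "kappa":
        atom.kappa = value
    elif ref[1] == "kappa_prime":
        atom.kappa_prime = value
    else:
        atom.P_lm[ref[1]] = value


@dataclass
class ParameterPacking:
    """Mapping between the model and the flat refinable vector."""

    slot_refs: list[list[ParamRef]]     # per slot, all model refs it drives
    slot_names: list[str]

    @property
    def nslots(self) -> int:
        return len(self.slot_refs)

    def pack(self, model: MoleculeModel) -> np.ndarray:
        x = np.empty(self.nslots)
        for k, refs in enumerate(self.slot_refs):
            values = [_get_param(model, r) for r in refs]
            if max(values) - min(values) > 1e-12 * max(1.0, abs(values[0])):
                raise ConstraintError(
                    f"tied parameters {refs} hold unequal values {values}")
            x[k] = values[0]
        return x

    def unpack(self, model: MoleculeModel, x: np.ndarray) -> MoleculeModel:
        out = model.copy()
        for k, refs in enumerate(self.slot_refs):
            for r in refs:
                _set_param(out, r, float(x[k]))
        return out

    def is_kappa_slot(self, k: int) -> str | None:
        kind = self.slot_refs[k][0][1]
        return kind if kind in ("kappa", "kappa_prime") else None


def parameter_packing(model: MoleculeModel) -> ParameterPacking:
    """Canonical packing: atoms in order; per atom P_val, kappa, kappa',
    then P_lm sorted by (l, m).  Tied parameters occupy one slot (first
    occurrence); fixed parameters are excluded."""
    tie_groups = model.constraints.expanded_ties()
    ref_to_group = {}
    for gi, group in enumerate(tie_groups):
        for ref in group:
            ref_to_group[ref] = gi
    all_refs = {ref for atom in model.pseudo_atoms for ref in _atom_param_refs(atom)}
    for ref in list(ref_to_group) + list(model.constraints.fixed):
        if ref not in all_refs:
            raise ConstraintError(f"constraint references unknown parameter {ref}")
    fixed = set(model.constraints.fixed)

    slot_refs, slot_names, seen_groups = [], [], set()
    for atom in model.pseudo_atoms:
        for ref in _atom_param_refs(atom):
            if ref in fixed:
                continue
            gi = ref_to_group.get(ref)
            if gi is not None:
                if gi in seen_groups:
                    continue
                seen_groups.add(gi)
                group = [r for r in tie_groups[gi] if r not in fixed]
                slot_refs.append(group)
            else:
                slot_refs.append([ref])
            a, key = slot_refs[-1][0]
            name = key if isinstance(key, str) else f"P_{key[0]},{key[1]}"
            slot_names.append(f"atom{a}:{name}")
    return ParameterPacking(slot_refs, slot_names)


def parameter_vector(model: MoleculeModel) -> tuple[np.ndarray, ParameterPacking]:
    """Flat refinable vector and its packing (pack/unpack is the identity)."""
    packing = parameter_packing(model)
    return packing.pack(model), packing


# ----------------------------------------------------------------------------
# density evaluation
# ----------------------------------------------------------------------------

def atom_density(atom: PseudoAtom, model: MoleculeModel, points,
                 include_core: bool = True) -> np.ndarray:
    """Pseudo-atom density (e/bohr^3) at Cartesian points (bohr)."""
    entry = model.databank[atom.databank_element]
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = pts - model.geometry.positions[atom.geometry_index]
    r = np.linalg.norm(d, axis=-1)
    rho = np.zeros(r.shape)
    if include_core and atom.P_core and entry.core_terms:
        rho += atom.P_core * spherical_density(entry, "core", r)
    # the stored valence density integrates to n_val; P_val multiplies the
    # per-electron density so an IAM atom (P_val = n_val) carries n_val e
    if entry.n_val > 0:
        k = atom.kappa
        rho += (atom.P_val / entry.n_val) * k ** 3 \
            * spherical_density(entry, "valence", k * r)
    kp = atom.kappa_prime
    local = atom.frame.to_local(d) if atom.frame is not None else d
    for (l, m), p in atom.P_lm.items():
        if p == 0.0:
            continue
        from .databank import deformation_radial
        radial = kp ** 3 * deformation_radial(entry, l, kp * r)
        rho += p * radial * harmonics.density_sph(l, m, local)
    return rho if np.asarray(points).ndim > 1 else rho[0]


def model_density(model: MoleculeModel, points,
                  include_core: bool = True) -> np.ndarray:
    """Total model density: sum of atom densities."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rho = np.zeros(pts.shape[0])
    for atom in model.pseudo_atoms:
        rho += atom_density(atom, model, pts, include_core=include_core)
    return rho if np.asarray(points).ndim > 1 else rho[0]


def analytic_atom_charge(atom: PseudoAtom, model: MoleculeModel) -> float:
    """Electron count of one pseudo-atom.

    Only spherically symmetric terms survive integration: P_core n_core +
    P_val + P_00 (d_00 integrates to 1); all l >= 1 deformation terms vanish
    by spherical-harmonic orthogonality.
    """
    entry = model.databank[atom.databank_element]
    n = atom.P_core * entry.n_core + atom.P_val
    n += atom.P_lm.get((0, 0), 0.0)
    return float(n)


def molecule_electron_count(model: MoleculeModel) -> float:
    return sum(analytic_atom_charge(a, model) for a in model.pseudo_atoms)


def make_iam(model: MoleculeModel) -> MoleculeModel:
    """Independent atom model: multipoles (l >= 1) zeroed, monopole
    populations at free-atom values, kappas set to unity.  Idempotent."""
    out = model.copy()
    for atom in out.pseudo_atoms:
        entry = model.databank[atom.databank_element]
        atom.P_val = float(entry.n_val)
        atom.kappa = 1.0
        atom.kappa_prime = 1.0
        for key in atom.P_lm:
            atom.P_lm[key] = 0.0
    return out


# ----------------------------------------------------------------------------
# model parameter file I/O
# ----------------------------------------------------------------------------

def write_model_params(model: MoleculeModel, path) -> None:
    """Plain-text per-atom parameter records (frames as 9 matrix numbers)."""
    lines = ["# mmfit model parameters"]
    for atom in model.pseudo_atoms:
        fm = " ".join(repr(float(v)) for v in atom.frame.matrix.ravel())
        lines.append(f"ATOM {atom.geometry_index} {atom.databank_element} "
                     f"{float(atom.P_val)!r} {float(atom.kappa)!r} "
                     f"{float(atom.kappa_prime)!r} "
                     f"{atom.lmax_atom} {int(atom.bond_oriented)}")
        lines.append(f"FRAME {fm}")
        for (l, m), p in sorted(atom.P_lm.items()):
            lines.append(f"PLM {l} {m} {float(p)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_model_params(path, geometry: MoleculeGeometry,
                      databank: RadialDatabank,
                      constraints: ConstraintSet | None = None) -> MoleculeModel:
    atoms: list[PseudoAtom] = []
    current = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        try:
            if tokens[0] == "ATOM":
                current = PseudoAtom(
                    geometry_index=int(tokens[1]), databank_element=tokens[2],
                    P_val=float(tokens[3]), kappa=float(tokens[4]),
                    kappa_prime=float(tokens[5]), lmax_atom=int(tokens[6]),
                    bond_oriented=bool(int(tokens[7])), P_lm={})
                atoms.append(current)
            elif tokens[0] == "FRAME":
                m = np.array([float(t) for t in tokens[1:10]]).reshape(3, 3)
                current.frame = LocalFrame(m, current.geometry_index)
            elif tokens[0] == "PLM":
                current.P_lm[(int(tokens[1]), int(tokens[2]))] = float(tokens[3])
            else:
                raise ParseError(f"unknown record {tokens[0]!r}")
        except ParseError:
            raise
        except Exception as exc:
            raise ParseError(f"{path}:{lineno}: malformed line {raw!r} ({exc})") from None
    atoms.sort(key=lambda a: a.geometry_index)
    constraints = constraints or ConstraintSet()
    return MoleculeModel(geometry, atoms, constraints, databank)
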