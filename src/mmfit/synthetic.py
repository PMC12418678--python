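"""Seedable synthetic test cases standing in for DFT reference densities.

The real inputs of the pipeline this package implements are molecular
wavefunctions; here they are emulated by a *ground-truth multipole model*
(drawn around neutral spherical atoms with seeded perturbations) plus an
optional small non-multipole-representable deformation: for every bond, a
charge-neutral triple of Gaussians (+A at the bond midpoint, -A/2 on each
bonded atom).  With the bumps switched off the reference is exactly
representable, so refinement must recover the truth parameters; with them
on, a fitted model can approach but never reach the reference - the same
qualitative gap a multipole model shows against a real wavefunction.

Built-in geometries are idealized literature-typical structures (water,
ammonia, an alanine molecule, an octahedral hexaaqua-magnesium cation),
not database coordinates; their X-H bonds are normalized to standard
neutron-diffraction average lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .databank import load_databank
from .errors import ValidationError
from .fields import GridSpec, density_field, esp_field
from .model import (BOHR_PER_ANGSTROM, ConstraintSet, MoleculeGeometry,
                    MoleculeModel, build_model, model_density)
from .scattering import (HklSet, StructureFactorSet, gaussian_structure_factors,
                         generate_hkl, structure_factors)

__all__ = ["SyntheticSpec", "SyntheticReference", "SyntheticCase",
           "builtin_geometry", "normalize_xh_bonds", "sample_ground_truth",
           "add_nonrepresentable", "generate_case", "NEUTRON_XH_LENGTHS"]

#: average X-H bond lengths from neutron diffraction compilations, Angstrom
NEUTRON_XH_LENGTHS = {"C": 1.089, "N": 1.015, "O": 0.967}


# ----------------------------------------------------------------------------
# geometries
# ----------------------------------------------------------------------------

def normalize_xh_bonds(geometry: MoleculeGeometry,
                       target_lengths: dict[str, float] | None = None
                       ) -> MoleculeGeometry:
    """Move each H along its existing X->H direction to the target X-H
    length (Angstrom) for heavy-atom element X; heavy atoms untouched."""
    target_lengths = target_lengths or NEUTRON_XH_LENGTHS
    pos = geometry.positions.copy()
    for i, sym in enumerate(geometry.symbols):
        if sym != "H":
            continue
        nbrs = geometry.neighbors(i)
        if len(nbrs) != 1:
            raise ValidationError(
                f"H atom {i} has {len(nbrs)} bonds; X-H normalization "
                f"needs exactly one")
        x = nbrs[0]
        x_sym = geometry.symbols[x]
        if x_sym not in target_lengths:
            continue
        d = pos[i] - pos[x]
        d /= np.linalg.norm(d)
        pos[i] = pos[x] + d * target_lengths[x_sym] * BOHR_PER_ANGSTROM
    return MoleculeGeometry(list(geometry.symbols), pos,
                            bonds=list(geometry.bonds),
                            net_charge=geometry.net_charge)


def _geom(symbols, coords_angstrom, bonds, charge=0):
    return MoleculeGeometry(symbols,
                            np.asarray(coords_angstrom) * BOHR_PER_ANGSTROM,
                            bonds=bonds, net_charge=charge)


def _water() -> MoleculeGeometry:
    # O-H 0.9572 A, H-O-H 104.52 deg; X-H normalized below
    ang = math.radians(104.52) / 2
    r = 0.9572
    g = _geom(["O", "H", "H"],
              [[0.0, 0.0, 0.0],
               [r * math.sin(ang), 0.0, r * math.cos(ang)],
               [-r * math.sin(ang), 0.0, r * math.cos(ang)]],
              bonds=[(0, 1), (0, 2)])
    return normalize_xh_bonds(g)


def _ammonia() -> MoleculeGeometry:
    # N-H 1.012 A, H-N-H 106.7 deg pyramid
    r, theta = 1.012, math.radians(112.15)   # polar angle giving HNH ~106.7
    coords = [[0.0, 0.0, 0.0]]
    for k in range(3):
        phi = 2 * math.pi * k / 3
        coords.append([r * math.sin(theta) * math.cos(phi),
                       r * math.sin(theta) * math.sin(phi),
                       r * math.cos(theta)])
    g = _geom(["N", "H", "H", "H"], coords, bonds=[(0, 1), (0, 2), (0, 3)])
    return normalize_xh_bonds(g)


_ALANINE_COORDS = [
    ("C", -0.9688, -0.6793, -0.6601), ("C", -0.1617, 0.4851, -0.1015),
    ("N", -0.7838, 1.0070, 1.1315), ("C", 1.2668, 0.0194, 0.1877),
    ("O", 1.6979, -0.4008, 1.2513), ("O", 2.0628, 0.0635, -0.9005),
    ("H", -0.5110, -1.0642, -1.5780), ("H", -1.0190, -1.5109, 0.0523),
    ("H", -1.9925, -0.3721, -0.8997), ("H", -0.1211, 1.3048, -0.8267),
    ("H", -0.6044, 0.3450, 1.8905), ("H", -1.7944, 1.0517, 1.0184),
    ("H", 2.9292, -0.2493, -0.5652),
]
_ALANINE_BONDS = [(0, 1), (1, 2), (1, 3), (3, 4), (3, 5), (0, 6), (0, 7),
                  (0, 8), (1, 9), (2, 10), (2, 11), (5, 12)]


def _alanine() -> MoleculeGeometry:
    symbols = [s for s, *_ in _ALANINE_COORDS]
    coords = [c for _, *c in _ALANINE_COORDS]
    return normalize_xh_bonds(_geom(symbols, coords, bonds=_ALANINE_BONDS))


def _mg_hexaaqua() -> MoleculeGeometry:
    """Octahedral [Mg(H2O)6]2+ with congruent, symmetry-related waters."""
    d_mgo = 2.08           # Mg-O, Angstrom
    ang = math.radians(105.5) / 2
    r_oh = 0.967
    # template water on +z: O at (0,0,d), H's opening away from Mg in xz plane
    o = np.array([0.0, 0.0, d_mgo])
    h1 = o + np.array([r_oh * math.sin(ang), 0.0, r_oh * math.cos(ang)])
    h2 = o + np.array([-r_oh * math.sin(ang), 0.0, r_oh * math.cos(ang)])
    # rotations mapping +z to the six octahedral directions
    rots = [np.eye(3),
            np.diag([1.0, -1.0, -1.0]),                                  # -z
            np.array([[0, 0, 1.0], [0, 1, 0], [-1, 0, 0]]),              # +x
            np.array([[0, 0, -1.0], [0, 1, 0], [1, 0, 0]]),              # -x
            np.array([[1.0, 0, 0], [0, 0, 1], [0, -1, 0]]),              # +y
            np.array([[1.0, 0, 0], [0, 0, -1], [0, 1, 0]])]              # -y
    symbols = ["Mg"]
    coords = [np.zeros(3)]
    bonds = []
    for k, rot in enumerate(rots):
        io = len(symbols)
        symbols += ["O", "H", "H"]
        coords += [rot @ o, rot @ h1, rot @ h2]
        bonds += [(0, io), (io, io + 1), (io, io + 2)]
    g = MoleculeGeometry(symbols, np.array(coords) * BOHR_PER_ANGSTROM,
                         bonds=bonds, net_charge=2)
    return normalize_xh_bonds(g)


_BUILTIN_GEOMETRIES = {"water": _water, "ammonia": _ammonia,
                       "alanine": _alanine, "mg_hexaaqua": _mg_hexaaqua}

#: chemically-identical-hydrogen groups per built-in (indices into atoms)
_H_GROUPS = {
    "water": [[1, 2]],
    "ammonia": [[1, 2, 3]],
    "alanine": [[6, 7, 8], [9], [10, 11], [12]],
    "mg_hexaaqua": [[2, 3, 5, 6, 8, 9, 11, 12, 14, 15, 17, 18]],
}

#: symmetry-equivalent atom groups whose multipole populations are tied
_SYMMETRY_GROUPS = {
    "mg_hexaaqua": [[1, 4, 7, 10, 13, 16],
                    [2, 3, 5, 6, 8, 9, 11, 12, 14, 15, 17, 18]],
}


def builtin_geometry(name: str) -> MoleculeGeometry:
    try:
        return _BUILTIN_GEOMETRIES[name]()
    except KeyError:
        raise ValidationError(
            f"unknown built-in geometry {name!r}; "
            f"choose from {sorted(_BUILTIN_GEOMETRIES)}") from None


def default_constraints(name: str, geometry: MoleculeGeometry) -> ConstraintSet:
    """Hydrogen conventions plus the symmetry ties of the built-in."""
    ties = []
    for group in _SYMMETRY_GROUPS.get(name, []):
        ties.append([(i, "P_val") for i in group])
        # P_lm keys are identical within a group (same element & truncation)
        first = group[0]
        sym = geometry.symbols[first]
        from . import harmonics
        from .model import H_LMAX, HEAVY_LMAX
        lmax = H_LMAX if sym == "H" else HEAVY_LMAX
        for key in harmonics.lm_keys(lmax, m_zero_only=(sym == "H")):
            ties.append([(i, key) for i in group])
    return ConstraintSet(ties=ties, h_bond_oriented=True,
                         shared_h_kappas=_H_GROUPS.get(name, []))


# ----------------------------------------------------------------------------
# spec and ground-truth sampling
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """The stated world of one synthetic case."""

    geometry_name: str = "water"
    seed: int = 0
    dP_val: float = 0.2                 # max |delta P_val|, electrons
    dP_lm: float = 0.1                  # max |P_lm|, electrons
    kappa_range: tuple[float, float] = (0.85, 1.15)
    bump_amplitude: float = 0.05        # e per bump pair
    bump_width: float = 0.35            # Gaussian sigma, bohr
    nonrepresentable: bool = True
    databank: str = "synthetic"

    def __post_init__(self):
        lo, hi = self.kappa_range
        if not (0.5 < lo <= hi < 2.0):
            raise ValidationError("kappa_range must lie inside (0.5, 2.0)")
        if self.bump_amplitude < 0 or self.bump_width <= 0:
            raise ValidationError("bump amplitude/width must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def sample_ground_truth(spec: SyntheticSpec) -> MoleculeModel:
    """Seeded ground-truth multipole model respecting all constraints.

    P_val = n_val + U(-d, d) adjusted (per tie group, preserving ties) so
    the valence populations carry exactly the molecular net charge:
    sum(P_val - n_val) = -net_charge.  P_lm ~ U(-d, d) under the hydrogen
    truncation rules; kappas ~ U(kappa_range).  Per atom, the largest
    |P_lm| is kept above 0.3*d so kappa' always has signal to refine
    against (identifiability; see methods note).
    """
    geometry = builtin_geometry(spec.geometry_name)
    databank = load_databank(spec.databank)
    constraints = default_constraints(spec.geometry_name, geometry)
    model = build_model(geometry, databank, constraints)
    rng = spec.rng()

    from .model import parameter_packing
    packing = parameter_packing(model)
    x = packing.pack(model)
    lo, hi = spec.kappa_range

    pval_slots = []
    for slot, refs in enumerate(packing.slot_refs):
        kind = refs[0][1]
        if kind == "P_val":
            x[slot] += rng.uniform(-spec.dP_val, spec.dP_val)
            pval_slots.append((slot, len(refs)))
        elif kind in ("kappa", "kappa_prime"):
            x[slot] = rng.uniform(lo, hi)
        else:
            x[slot] = rng.uniform(-spec.dP_lm, spec.dP_lm)
    model = packing.unpack(model, x)

    # kappa'-identifiability: give every atom some aspherical signal
    for atom in model.pseudo_atoms:
        if not atom.P_lm:
            continue
        key = max(atom.P_lm, key=lambda k: abs(atom.P_lm[k]))
        if abs(atom.P_lm[key]) < 0.3 * spec.dP_lm:
            sign = 1.0 if atom.P_lm[key] >= 0 else -1.0
            atom.P_lm[key] = sign * 0.3 * spec.dP_lm
    x = packing.pack(model)

    # electroneutrality bookkeeping: sum(P_val - n_val) = -net_charge
    excess = sum((a.P_val - databank[a.databank_element].n_val)
                 for a in model.pseudo_atoms) + geometry.net_charge
    multiplicity = sum(m for _, m in pval_slots)
    for slot, _ in pval_slots:
        x[slot] -= excess / multiplicity
    return packing.unpack(model, x)


# ----------------------------------------------------------------------------
# non-representable reference
# ----------------------------------------------------------------------------

@dataclass
class SyntheticReference:
    """Ground-truth model density plus charge-neutral Gaussian bond bumps."""

    model: MoleculeModel
    bumps: list[tuple[np.ndarray, float, float]] = field(default_factory=list)
    # each bump: (center bohr, amplitude e, sigma bohr)

    @property
    def geometry(self) -> MoleculeGeometry:
        return self.model.geometry

    def density(self, points, include_core: bool = True) -> np.ndarray:
        rho = model_density(self.model, points, include_core=include_core)
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        add = np.zeros(pts.shape[0])
        for center, amp, sigma in self.bumps:
            r2 = ((pts - center) ** 2).sum(axis=1)
            add += amp / ((2 * math.pi) ** 1.5 * sigma ** 3) \
                * np.exp(-r2 / (2 * sigma ** 2))
        add = add.reshape(np.shape(rho))
        return rho + add

    def bump_esp(self, points) -> np.ndarray:
        """ESP of the (negative-charge) electron bumps: -sum q erf(.)/r."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        v = np.zeros(pts.shape[0])
        for center, amp, sigma in self.bumps:
            r = np.linalg.norm(pts - center, axis=1)
            r = np.maximum(r, 1e-12)
            v -= amp * erf_over_r(r, sigma)
        return v

    def bump_structure_factors(self, hkl: HklSet) -> np.ndarray:
        if not self.bumps:
            return np.zeros(len(hkl), dtype=complex)
        centers = [c for c, _, _ in self.bumps]
        amps = [a for _, a, _ in self.bumps]
        sigmas = [s for _, _, s in self.bumps]
        return gaussian_structure_factors(centers, amps, sigmas, hkl)


def erf_over_r(r, sigma):
    from scipy.special import erf
    return erf(r / (sigma * math.sqrt(2.0))) / r


def add_nonrepresentable(model: MoleculeModel,
                         spec: SyntheticSpec) -> SyntheticReference:
    """Per bond: +A Gaussian at the midpoint, -A/2 on each bonded atom.

    The added charge is analytically zero per bond, keeping every atom's
    neighborhood roughly neutral so the far-field ESP of truth and
    reference stay comparable.
    """
    bumps = []
    if spec.nonrepresentable and spec.bump_amplitude > 0:
        pos = model.geometry.positions
        for i, j in model.geometry.bonds:
            mid = 0.5 * (pos[i] + pos[j])
            a, w = spec.bump_amplitude, spec.bump_width
            bumps.append((mid.copy(), a, w))
            bumps.append((pos[i].copy(), -a / 2, w))
            bumps.append((pos[j].copy(), -a / 2, w))
    return SyntheticReference(model=model, bumps=bumps)


# ----------------------------------------------------------------------------
# full case assembly
# ----------------------------------------------------------------------------

@dataclass
class SyntheticCase:
    spec: SyntheticSpec
    truth_model: MoleculeModel
    reference: SyntheticReference
    F_target: StructureFactorSet
    density: object | None = None       # reference ScalarField
    esp: object | None = None           # reference ScalarField
    grid: GridSpec | None = None

    @property
    def case_id(self) -> str:
        return f"{self.spec.geometry_name}-seed{self.spec.seed}" \
               f"{'-bumped' if self.spec.nonrepresentable else ''}"


def default_case_grid(geometry: MoleculeGeometry, npoints: int = 96,
                      margin_angstrom: float = 6.0) -> GridSpec:
    """Centroid-centered cube with enough margin to hold the 1e-4 a.u.
    iso-density surface."""
    center = geometry.centroid()
    extent = 2 * float(np.max(np.linalg.norm(
        geometry.positions - center, axis=1)))
    edge = extent + 2 * margin_angstrom * BOHR_PER_ANGSTROM
    return GridSpec.centered(center, edge, npoints)


def generate_case(spec: SyntheticSpec, grid: GridSpec | None = None,
                  a: float = 30.0, s_max: float = 0.7,
                  friedel_unique: bool = True,
                  build_fields: bool = True,
                  grid_npoints: int = 96) -> SyntheticCase:
    """Assemble a fully reproducible case: truth model, reference density,
    valence-only F_target (analytic model part + exact Gaussian bump part)
    and reference density/ESP fields."""
    truth = sample_ground_truth(spec)
    reference = add_nonrepresentable(truth, spec)
    hkl = generate_hkl(a, s_max, friedel_unique=friedel_unique)
    sf = structure_factors(truth, hkl, include_core=False)
    F = sf.F + reference.bump_structure_factors(hkl)
    target = StructureFactorSet(hkl, F, valence_only=True)
    density = esp = None
    if grid is None and build_fields:
        grid = default_case_grid(truth.geometry, npoints=grid_npoints)
    if build_fields:
        density = density_field(reference, grid, include_core=True,
                                provenance="reference")
        esp = esp_field(reference, grid, provenance="reference")
    return SyntheticCase(spec=spec, truth_model=truth, reference=reference,
                         F_target=target, density=density, esp=esp, grid=grid)


# ----------------------------------------------------------------------------
# case bundle I/O
# ----------------------------------------------------------------------------

def save_case_bundle(case: SyntheticCase, directory) -> None:
    """Write a case as a directory of text artifacts: geometry (XYZ), truth
    model parameters, F_target, reference fields (cube) and a JSON manifest."""
    import dataclasses
    import json
    from pathlib import Path

    from .fields import cube_write
    from .model import write_model_params, write_xyz
    from .scattering import write_sf_file

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_xyz(case.truth_model.geometry, d / "geometry.xyz")
    write_model_params(case.truth_model, d / "truth_model.txt")
    write_sf_file(case.F_target, d / "f_target.txt")
    if case.density is not None:
        cube_write(case.density, d / "reference_density.cube",
                   geometry=case.truth_model.geometry)
    if case.esp is not None:
        cube_write(case.esp, d / "reference_esp.cube",
                   geometry=case.truth_model.geometry)
    manifest = dataclasses.asdict(case.spec)
    manifest["case_id"] = case.case_id
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")


def load_case_bundle(directory) -> SyntheticCase:
    """Rebuild a :class:`SyntheticCase` from a bundle directory.

    The truth model and reference are regenerated from the manifest spec
    (bit-reproducible); fields are read back from the cubes when present.
    """
    import json
    from pathlib import Path

    from .fields import cube_read
    from .scattering import read_sf_file

    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    manifest.pop("case_id", None)
    manifest["kappa_range"] = tuple(manifest["kappa_range"])
    spec = SyntheticSpec(**manifest)
    truth = sample_ground_truth(spec)
    reference = add_nonrepresentable(truth, spec)
    target = read_sf_file(d / "f_target.txt")
    density = esp = grid = None
    if (d / "reference_density.cube").exists():
        density = cube_read(d / "reference_density.cube")
        grid = density.spec
    if (d / "reference_esp.cube").exists():
        esp = cube_read(d / "reference_esp.cube")
    return SyntheticCase(spec=spec, truth_model=truth, reference=reference,
                         F_target=target, density=density, esp=esp, grid=grid)
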