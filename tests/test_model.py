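"""Pseudo-atom model: frames, parameter packing, density evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmfit.databank import spherical_density
from mmfit.errors import ConstraintError, FrameError
from mmfit.harmonics import density_sph
from mmfit.model import (ConstraintSet, FrameRules, MoleculeGeometry,
                         analytic_atom_charge, atom_density,
                         build_local_frames, build_model, make_iam,
                         model_density, molecule_electron_count,
                         parameter_vector, read_xyz, write_xyz)
from mmfit.synthetic import SyntheticSpec, sample_ground_truth


# ----------------------------------------------------------------------------
# local frames
# ----------------------------------------------------------------------------

def test_h_frame_points_along_bond():
    geo = MoleculeGeometry(["C", "H"], [[0, 0, 0], [0, 0, 1.9]],
                           bonds=[(0, 1)])
    frames = build_local_frames(geo)
    # z axis is the unit H -> neighbor vector
    np.testing.assert_allclose(frames[1].matrix[2], [0, 0, -1], atol=1e-12)


def test_frames_orthonormal_and_handed(water_geometry):
    for frame in build_local_frames(water_geometry):
        m = frame.matrix
        np.testing.assert_allclose(m @ m.T, np.eye(3), atol=1e-10)
        assert frame.handedness == 1


def test_isolated_h_raises():
    geo = MoleculeGeometry(["H"], [[0, 0, 0]])
    with pytest.raises(FrameError):
        build_local_frames(geo, FrameRules(h_bond_oriented=True))


# ----------------------------------------------------------------------------
# parameter packing
# ----------------------------------------------------------------------------

def test_h_bond_oriented_truncation(databank, water_geometry):
    model = build_model(water_geometry, databank)
    h = model.pseudo_atoms[1]
    assert set(h.P_lm) == {(1, 0), (2, 0)}      # no P_11+-, P_21+-, P_22+-
    x, packing = parameter_vector(model)
    h_slots = [n for n in packing.slot_names
               if n.startswith("atom1:") or n.startswith("atom2:")]
    assert not any("P_1,-1" in n or "P_1,1" in n or "P_2,2" in n
                   or "P_2,1" in n for n in h_slots)


def test_tied_parameters_share_one_slot(databank, water_geometry):
    ties = [[(1, "P_val"), (2, "P_val")]]
    model = build_model(water_geometry, databank,
                        ConstraintSet(ties=ties, h_bond_oriented=True))
    x, packing = parameter_vector(model)
    names = [n for n in packing.slot_names if "P_val" in n]
    assert len(names) == 2                       # O slot + one shared H slot
    # inconsistent tie values are rejected at pack time
    model.pseudo_atoms[1].P_val = 0.9
    with pytest.raises(ConstraintError):
        packing.pack(model)


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_pack_unpack_roundtrip(seed):
    """pack(unpack(x)) is the identity on random ground-truth models."""
    model = sample_ground_truth(SyntheticSpec(geometry_name="water",
                                              seed=seed,
                                              nonrepresentable=False))
    x, packing = parameter_vector(model)
    again = packing.unpack(model, x)
    np.testing.assert_array_equal(packing.pack(again), x)


# ----------------------------------------------------------------------------
# density evaluation
# ----------------------------------------------------------------------------

def test_spherical_reduction(single_o_model):
    """All P_lm = 0, kappa = 1, P_val = n_val: density is core + valence."""
    model = single_o_model
    entry = model.databank["O"]
    r = np.array([0.3, 1.0, 2.5])
    pts = np.stack([r, np.zeros_like(r), np.zeros_like(r)], axis=1)
    got = model_density(model, pts)
    want = (spherical_density(entry, "core", r)
            + spherical_density(entry, "valence", r))
    np.testing.assert_allclose(got, want, rtol=1e-12)


def test_kappa_cubed_scaling_at_nucleus(single_h_model):
    """Valence-only density at the nucleus scales as kappa^3."""
    m1 = single_h_model.copy()
    m2 = single_h_model.copy()
    m2.pseudo_atoms[0].kappa = 2.0
    origin = np.zeros(3)
    rho1 = atom_density(m1.pseudo_atoms[0], m1, origin, include_core=False)
    rho2 = atom_density(m2.pseudo_atoms[0], m2, origin, include_core=False)
    assert rho2 == pytest.approx(8.0 * rho1, rel=1e-12)


def test_dipole_term_antisymmetry(single_o_model):
    """With only P_10 on, rho(z) - rho(-z) = 2 kappa'^3 R_1 P_10 d_10."""
    from mmfit.databank import deformation_radial
    model = single_o_model.copy()
    atom = model.pseudo_atoms[0]
    atom.P_lm[(1, 0)] = 0.3
    z = 1.2
    up = atom_density(atom, model, np.array([0, 0, z]))
    dn = atom_density(atom, model, np.array([0, 0, -z]))
    entry = model.databank["O"]
    d10_up = density_sph(1, 0, np.array([0.0, 0.0, 1.0]))
    want = 2 * atom.kappa_prime ** 3 \
        * deformation_radial(entry, 1, atom.kappa_prime * z) * 0.3 * d10_up
    assert up - dn == pytest.approx(float(want), rel=1e-12)


def test_model_density_additivity(databank):
    geo = MoleculeGeometry(["H", "H"], [[0, 0, 0], [0, 0, 30.0]])
    model = build_model(geo, databank, ConstraintSet(h_bond_oriented=False),
                        FrameRules(h_bond_oriented=False))
    mid = np.array([0.0, 0.0, 15.0])
    total = model_density(model, mid)
    parts = sum(atom_density(a, model, mid) for a in model.pseudo_atoms)
    assert total == pytest.approx(parts, abs=1e-15)


def test_include_core_toggle(single_o_model):
    pts = np.array([[0.4, 0.0, 0.0], [1.5, 0.5, 0.0]])
    full = model_density(single_o_model, pts, include_core=True)
    noc = model_density(single_o_model, pts, include_core=False)
    entry = single_o_model.databank["O"]
    r = np.linalg.norm(pts, axis=1)
    np.testing.assert_allclose(full - noc,
                               spherical_density(entry, "core", r),
                               rtol=1e-9, atol=1e-15)


def test_analytic_atom_charge(single_o_model):
    model = single_o_model.copy()
    atom = model.pseudo_atoms[0]
    atom.P_val = 4.2
    entry = model.databank["O"]
    assert entry.n_core == 2
    assert analytic_atom_charge(atom, model) == pytest.approx(6.2)
    atom.P_lm[(2, 1)] = 0.3                     # l >= 1 integrates to zero
    assert analytic_atom_charge(atom, model) == pytest.approx(6.2)
    atom.P_lm[(0, 0)] = 0.1                     # monopole deformation adds
    assert analytic_atom_charge(atom, model) == pytest.approx(6.3)


def test_electron_count_matches_nuclear_charge():
    for name in ("water", "mg_hexaaqua"):
        model = sample_ground_truth(SyntheticSpec(geometry_name=name, seed=9))
        geo = model.geometry
        want = geo.nuclear_charges.sum() - geo.net_charge
        assert molecule_electron_count(model) == pytest.approx(want, abs=1e-10)


def test_frame_invariance_under_rotation():
    """Rotating geometry (frames follow) leaves densities at co-rotated
    points unchanged."""
    from scipy.spatial.transform import Rotation
    model = sample_ground_truth(SyntheticSpec(geometry_name="water", seed=4))
    R = Rotation.from_euler("zyx", [31.0, -57.0, 12.0], degrees=True).as_matrix()
    geo = model.geometry
    geo_rot = MoleculeGeometry(list(geo.symbols), geo.positions @ R.T,
                               bonds=list(geo.bonds),
                               net_charge=geo.net_charge)
    model_rot = model.copy()
    model_rot.geometry = geo_rot
    frames = build_local_frames(geo_rot)
    for atom, frame in zip(model_rot.pseudo_atoms, frames):
        atom.frame = frame
    rng = np.random.default_rng(0)
    pts = rng.normal(scale=2.0, size=(40, 3))
    rho = model_density(model, pts)
    rho_rot = model_density(model_rot, pts @ R.T)
    np.testing.assert_allclose(rho_rot, rho, atol=1e-10)


# ----------------------------------------------------------------------------
# IAM
# ----------------------------------------------------------------------------

def test_make_iam(databank, water_geometry):
    truth = sample_ground_truth(SyntheticSpec(geometry_name="water", seed=1))
    iam = make_iam(truth)
    for atom in iam.pseudo_atoms:
        assert atom.kappa == 1.0 and atom.kappa_prime == 1.0
        assert all(v == 0.0 for v in atom.P_lm.values())
        assert atom.P_val == databank[atom.databank_element].n_val
    # idempotent
    again = make_iam(iam)
    np.testing.assert_array_equal(parameter_vector(again)[0],
                                  parameter_vector(iam)[0])
    # spherically symmetric per atom: equal values at equal radii
    atom = iam.pseudo_atoms[0]
    dirs = np.array([[1, 0, 0], [0, 1, 0], [-0.5, 0.5, 1 / math.sqrt(2)]])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    rho = atom_density(atom, iam, 1.7 * dirs)
    assert np.ptp(rho) < 1e-12 * abs(rho[0])


# ----------------------------------------------------------------------------
# geometry I/O
# ----------------------------------------------------------------------------

def test_xyz_roundtrip(tmp_path, water_geometry):
    path = tmp_path / "water.xyz"
    write_xyz(water_geometry, path)
    again = read_xyz(path)
    assert again.symbols == water_geometry.symbols
    assert again.bonds == water_geometry.bonds
    assert again.net_charge == water_geometry.net_charge
    np.testing.assert_allclose(again.positions, water_geometry.positions,
                               atol=1e-9)
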