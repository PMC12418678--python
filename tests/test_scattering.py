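"""Reciprocal lattice, Slater Fourier-Bessel transforms, structure factors."""

import math

import numpy as np
import pytest

from mmfit.errors import ResolutionError, ValidationError
from mmfit.fields import GridSpec, ScalarField, density_field
from mmfit.model import (BOHR_PER_ANGSTROM, ConstraintSet, FrameRules,
                         MoleculeGeometry, build_local_frames, build_model)
from mmfit.scattering import (fft_oracle,
                              gaussian_structure_factors, generate_hkl,
                              read_sf_file, slater_jl_transform,
                              structure_factors, write_sf_file)
from mmfit.synthetic import SyntheticSpec, sample_ground_truth


# ----------------------------------------------------------------------------
# hkl generation
# ----------------------------------------------------------------------------

def test_hkl_range_and_metric():
    hkl = generate_hkl(30.0, 1.1)
    # brute-force maximum single index: 2*30*1.1 = 66
    assert hkl.hkl.max() == 66
    assert hkl.hkl.min() == -66
    # origin strictly excluded, upper bound inclusive
    n2 = (hkl.hkl ** 2).sum(axis=1)
    assert n2.min() >= 1
    assert math.sqrt(n2.max()) / 60.0 <= 1.1 + 1e-12
    # cubic metric: s(1,0,0) = 1/(2a)
    i = np.flatnonzero((hkl.hkl == [1, 0, 0]).all(axis=1))[0]
    assert hkl.s[i] == pytest.approx(1.0 / 60.0, rel=1e-14)


def test_hkl_friedel_hemisphere():
    full = generate_hkl(10.0, 0.4)
    hemi = generate_hkl(10.0, 0.4, friedel_unique=True)
    assert 2 * len(hemi) == len(full)
    keys = {tuple(row) for row in hemi.hkl}
    for row in hemi.hkl:
        assert tuple(-row) not in keys


def test_hkl_validation():
    with pytest.raises(ValidationError):
        generate_hkl(-1.0, 0.5)
    with pytest.raises(ValidationError):
        generate_hkl(10.0, 0.0)


# ----------------------------------------------------------------------------
# Slater transforms
# ----------------------------------------------------------------------------

def test_jl_limits():
    assert slater_jl_transform(0, 2, 3.0, 0.0) == pytest.approx(1.0, abs=1e-14)
    for l in (1, 2, 3, 4):
        assert slater_jl_transform(l, max(l, 1), 2.5, 0.0) == 0.0
    # closed form zeta^4/(zeta^2+q^2)^2 at q = zeta gives 1/4
    assert slater_jl_transform(0, 0, 2.0, 2.0) == pytest.approx(0.25, rel=1e-12)


@pytest.mark.parametrize("l,n", [(0, 0), (0, 2), (1, 1), (1, 2), (2, 2),
                                 (3, 3), (4, 4)])
def test_jl_closed_form_vs_quadrature(l, n):
    """The analytic path and the Gauss-Legendre path agree to 1e-10."""
    q = np.array([1e-4, 0.05, 0.4, 1.1, 2.9, 7.3])
    for zeta in (1.6, 3.0, 6.0):
        a = slater_jl_transform(l, n, zeta, q)
        b = slater_jl_transform(l, n, zeta, q, method="quadrature")
        np.testing.assert_allclose(a, b, atol=1e-10)


# ----------------------------------------------------------------------------
# analytic structure factors
# ----------------------------------------------------------------------------

def _iam_single_atom(databank, symbol="O", pos=(0.0, 0.0, 0.0)):
    geo = MoleculeGeometry([symbol], np.asarray(pos, dtype=float)[None, :])
    return build_model(geo, databank, ConstraintSet(h_bond_oriented=False),
                       FrameRules(h_bond_oriented=False))


def test_spherical_atom_at_origin_is_real(databank):
    model = _iam_single_atom(databank)
    hkl = generate_hkl(8.0, 0.4)
    F = structure_factors(model, hkl).F
    np.testing.assert_allclose(F.imag, 0.0, atol=1e-12)
    # equal |H| -> equal F (radial form factor only)
    n2 = (hkl.hkl ** 2).sum(axis=1)
    for group in np.unique(n2)[:5]:
        vals = F.real[n2 == group]
        assert np.ptp(vals) < 1e-12


def test_translation_shift_theorem(databank):
    hkl = generate_hkl(8.0, 0.35)
    t = np.array([0.7, -1.1, 0.4])          # bohr
    F0 = structure_factors(_iam_single_atom(databank), hkl).F
    Ft = structure_factors(_iam_single_atom(databank, pos=t), hkl).F
    a_bohr = 8.0 * BOHR_PER_ANGSTROM
    phase = np.exp(2j * math.pi * (hkl.hkl @ (t / a_bohr)))
    np.testing.assert_allclose(Ft, F0 * phase, atol=1e-10)


def test_linearity_of_structure_factors(databank):
    hkl = generate_hkl(8.0, 0.3)
    m1 = _iam_single_atom(databank, "O")
    m2 = _iam_single_atom(databank, "C", pos=(2.0, 0.5, -1.0))
    geo = MoleculeGeometry(["O", "C"], np.array([[0, 0, 0], [2.0, 0.5, -1.0]]))
    both = build_model(geo, databank, ConstraintSet(h_bond_oriented=False),
                       FrameRules(h_bond_oriented=False))
    F = structure_factors(both, hkl).F
    np.testing.assert_allclose(
        F, structure_factors(m1, hkl).F + structure_factors(m2, hkl).F,
        atol=1e-12)


def test_rotational_covariance():
    """A lattice rotation of the molecule permutes F; |F| is invariant."""
    model = sample_ground_truth(SyntheticSpec(geometry_name="water", seed=8))
    R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    geo = model.geometry
    geo_rot = MoleculeGeometry(list(geo.symbols), geo.positions @ R.T,
                               bonds=list(geo.bonds))
    model_rot = model.copy()
    model_rot.geometry = geo_rot
    for atom, frame in zip(model_rot.pseudo_atoms,
                           build_local_frames(geo_rot)):
        atom.frame = frame
    hkl = generate_hkl(8.0, 0.35)
    F = structure_factors(model, hkl, include_core=False).F
    F_rot = structure_factors(model_rot, hkl, include_core=False).F
    # match H of the original to R H of the rotated set
    index = {tuple(row): i for i, row in enumerate(hkl.hkl)}
    perm = [index[tuple(np.rint(R @ row).astype(int))] for row in hkl.hkl]
    np.testing.assert_allclose(np.abs(F_rot[perm]), np.abs(F), atol=1e-10)


def test_friedel_symmetry(databank):
    model = sample_ground_truth(SyntheticSpec(geometry_name="ammonia", seed=2))
    hkl = generate_hkl(8.0, 0.3)
    F = structure_factors(model, hkl, include_core=False).F
    index = {tuple(row): i for i, row in enumerate(hkl.hkl)}
    for i, row in enumerate(hkl.hkl[:500]):
        j = index[tuple(-row)]
        assert F[j] == pytest.approx(np.conj(F[i]), abs=1e-10)


# ----------------------------------------------------------------------------
# FFT oracle
# ----------------------------------------------------------------------------

def _cell_grid(a_angstrom, n, center):
    a_bohr = a_angstrom * BOHR_PER_ANGSTROM
    origin = np.asarray(center) - a_bohr / 2.0
    return GridSpec(tuple(origin), a_bohr / n, n)


def test_fft_oracle_constant_field():
    spec = _cell_grid(6.0, 32, (0, 0, 0))
    field = ScalarField(spec, "density", np.full((32, 32, 32), 3.7))
    hkl = generate_hkl(6.0, 0.3)
    F = fft_oracle(field, hkl).F
    np.testing.assert_allclose(F, 0.0, atol=1e-9)


def test_fft_oracle_friedel_and_nyquist():
    rng = np.random.default_rng(1)
    spec = _cell_grid(6.0, 32, (0, 0, 0))
    field = ScalarField(spec, "density", rng.random((32, 32, 32)))
    hkl = generate_hkl(6.0, 0.5)
    F = fft_oracle(field, hkl).F
    index = {tuple(row): i for i, row in enumerate(hkl.hkl)}
    for i, row in enumerate(hkl.hkl[:200]):
        assert F[index[tuple(-row)]] == pytest.approx(np.conj(F[i]),
                                                      abs=1e-12)
    with pytest.raises(ResolutionError):
        fft_oracle(field, generate_hkl(6.0, 1.6))


def test_fft_oracle_gaussian_closed_form():
    """Sampled Gaussian blob vs its analytic transform: rel err < 1e-6."""
    a, n = 10.0, 96
    center = np.array([0.4, -0.2, 0.1])
    spec = _cell_grid(a, n, (0, 0, 0))
    ax = spec.axes()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    sigma, amp = 0.9, 2.0
    r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
    rho = amp / ((2 * math.pi) ** 1.5 * sigma ** 3) * np.exp(-r2 / (2 * sigma ** 2))
    field = ScalarField(spec, "density", rho)
    hkl = generate_hkl(a, 0.5)
    F_fft = fft_oracle(field, hkl).F
    F_ref = gaussian_structure_factors([center], [amp], [sigma], hkl)
    sel = hkl.s <= 0.5
    err = np.abs(F_fft[sel] - F_ref[sel]) / np.abs(F_ref[sel])
    assert err.max() < 1e-6


def test_analytic_vs_fft_two_atom_toy(databank):
    """Valence-only analytic F vs the grid oracle: max |dF| < 1e-3 e, 96^3."""
    a = 10.0
    geo = MoleculeGeometry(["C", "O"], np.array([[0.0, 0.0, 0.0],
                                                 [2.1, 0.0, 0.0]]))
    model = build_model(geo, databank, ConstraintSet(h_bond_oriented=False),
                        FrameRules(h_bond_oriented=False))
    model.pseudo_atoms[0].P_lm[(1, 0)] = 0.15
    model.pseudo_atoms[1].P_lm[(2, 0)] = -0.1
    spec = _cell_grid(a, 96, geo.centroid())
    field = density_field(model, spec, include_core=False)
    hkl = generate_hkl(a, 0.5)
    F_ana = structure_factors(model, hkl, include_core=False).F
    F_fft = fft_oracle(field, hkl).F
    assert np.abs(F_ana - F_fft).max() < 1e-3


# ----------------------------------------------------------------------------
# file I/O
# ----------------------------------------------------------------------------

def test_sf_file_roundtrip(tmp_path):
    model = sample_ground_truth(SyntheticSpec(geometry_name="water", seed=6))
    hkl = generate_hkl(8.0, 0.25, friedel_unique=True)
    sf = structure_factors(model, hkl, include_core=False)
    path = tmp_path / "f.txt"
    write_sf_file(sf, path)
    again = read_sf_file(path)
    assert again.valence_only == sf.valence_only
    assert again.hkl.same_lattice(sf.hkl)
    np.testing.assert_array_equal(again.F, sf.F)
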