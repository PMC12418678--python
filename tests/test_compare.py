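"""Comparison statistics: Pearson CC, basins, surfaces, error metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import RegularGridInterpolator

from mmfit.compare import (ESCAPE_FLOOR, assign_basins, error_metrics,
                           extract_isosurface, integrate_basins, pearson_cc,
                           surface_average_esp)
from mmfit.errors import (AlignmentError, DegenerateInputError,
                          EmptySurfaceError)
from mmfit.fields import GridSpec, ScalarField, coulomb_esp_field
from mmfit.model import MoleculeGeometry


def _field(values, kind="esp", spec=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    spec = spec or GridSpec((0, 0, 0), 1.0, n)
    return ScalarField(spec, kind, values)


# ----------------------------------------------------------------------------
# Pearson CC
# ----------------------------------------------------------------------------

def test_pearson_identity_and_negation():
    rng = np.random.default_rng(0)
    a = _field(rng.normal(size=(4, 4, 4)))
    assert pearson_cc(a, a) == pytest.approx(1.0, abs=1e-14)
    neg = _field(-a.values)
    assert pearson_cc(a, neg) == pytest.approx(-1.0, abs=1e-14)


def test_pearson_hand_value():
    """{1,2,3} vs {1,2,4} -> 9/(2 sqrt(21)); tiling preserves correlation."""
    a = _field(np.tile([1.0, 2.0, 3.0], 9).reshape(3, 3, 3))
    b = _field(np.tile([1.0, 2.0, 4.0], 9).reshape(3, 3, 3))
    assert pearson_cc(a, b) == pytest.approx(9.0 / (2.0 * math.sqrt(21.0)),
                                             rel=1e-12)


def test_pearson_affine_invariance():
    rng = np.random.default_rng(3)
    base = rng.normal(size=(6, 6, 6)) * 1e-2
    other = base + 0.3 * rng.normal(size=base.shape) * 1e-2
    a, b = _field(base), _field(other)
    cc = pearson_cc(a, b)
    for scale, shift in [(2.5, 3.0), (1e3, -7.0), (0.04, 123.0)]:
        cc2 = pearson_cc(_field(scale * base + shift), b)
        assert cc2 == pytest.approx(cc, abs=1e-12)


def test_pearson_errors():
    a = _field(np.random.default_rng(0).normal(size=(3, 3, 3)))
    with pytest.raises(DegenerateInputError):
        pearson_cc(a, _field(np.full((3, 3, 3), 2.0)))
    with pytest.raises(AlignmentError):
        pearson_cc(a, _field(np.zeros((4, 4, 4))))


def test_pearson_matches_numpy_oracle():
    rng = np.random.default_rng(7)
    a = _field(rng.normal(size=(5, 5, 5)))
    b = _field(rng.normal(size=(5, 5, 5)))
    want = np.corrcoef(a.values.ravel(), b.values.ravel())[0, 1]
    assert pearson_cc(a, b) == pytest.approx(want, abs=1e-13)


# ----------------------------------------------------------------------------
# error metrics
# ----------------------------------------------------------------------------

def test_error_metrics_hand_values():
    """Residuals {1, -1, 2}: ME = 2/3, MAE = 4/3, RMSE = sqrt 2."""
    me, mae, rmse = error_metrics([2.0, 0.0, 3.0], [1.0, 1.0, 1.0])
    assert me == pytest.approx(2.0 / 3.0, rel=1e-12)
    assert mae == pytest.approx(4.0 / 3.0, rel=1e-12)
    assert rmse == pytest.approx(math.sqrt(2.0), rel=1e-12)
    assert error_metrics([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0, 0.0)
    with pytest.raises(AlignmentError):
        error_metrics([1.0], [1.0, 2.0])


@settings(max_examples=200, deadline=None)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30),
       st.integers(0, 2 ** 31 - 1))
def test_error_metrics_inequality(values, seed):
    """|ME| <= MAE <= RMSE always (Jensen / Cauchy-Schwarz)."""
    ref = np.random.default_rng(seed).uniform(-1e6, 1e6, size=len(values))
    me, mae, rmse = error_metrics(values, ref)
    assert abs(me) <= mae + 1e-9 * mae
    assert mae <= rmse + 1e-9 * rmse


# ----------------------------------------------------------------------------
# basins
# ----------------------------------------------------------------------------

def _gaussians(spec, blobs):
    ax = spec.axes()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    rho = np.zeros(X.shape)
    for (cx, cy, cz), amp, w in blobs:
        rho += amp * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2
                              + (Z - cz) ** 2) / w)
    return ScalarField(spec, "density", rho, "reference")


def test_single_attractor_covers_everything():
    spec = GridSpec.centered((0, 0, 0), 10.0, 32)
    f = _gaussians(spec, [((0.0, 0.0, 0.0), 2.0, 1.2)])
    geo = MoleculeGeometry(["O"], np.zeros((1, 3)))
    bm = assign_basins(f, geo)
    assert bm.nbasins == 1
    above = f.values >= ESCAPE_FLOOR
    assert np.all(bm.labels[above] == 0)


def test_symmetric_diatomic_mirror_labels():
    spec = GridSpec.centered((0, 0, 0), 12.0, 48)
    blobs = [((-1.5, 0, 0), 1.0, 1.0), ((1.5, 0, 0), 1.0, 1.0)]
    f = _gaussians(spec, blobs)
    geo = MoleculeGeometry(["N", "N"], np.array([[-1.5, 0, 0], [1.5, 0, 0]]))
    bm = assign_basins(f, geo)
    assert bm.nbasins == 2
    mirrored = bm.labels[::-1, :, :]
    swap = {0: 1, 1: 0, -1: -1}
    remapped = np.vectorize(swap.get)(mirrored)
    agreement = np.mean(remapped == bm.labels)
    assert agreement > 0.999          # midplane voxels may tie-break either way
    pops = integrate_basins(bm, f, f)
    assert pops.N[0] == pytest.approx(pops.N[1], abs=1e-10)
    np.testing.assert_allclose(pops.delta, 0.0, atol=1e-14)


def test_basins_match_trajectory_oracle():
    """Near-grid assignment vs explicit steepest-ascent ODE trajectories."""
    spec = GridSpec.centered((0, 0, 0), 12.0, 48)
    blobs = [((-1.2, 0, 0), 2.0, 0.8), ((1.5, 0.3, 0), 1.0, 1.4)]
    f = _gaussians(spec, blobs)
    geo = MoleculeGeometry(["O", "C"],
                           np.array([[-1.2, 0, 0], [1.5, 0.3, 0]]))
    bm = assign_basins(f, geo)
    assert bm.nbasins == 2

    # independent oracle: fixed-step RK4 ascent on the interpolated gradient
    ax = spec.axes()
    grads = np.gradient(f.values, spec.step)
    interp = [RegularGridInterpolator(ax, g, bounds_error=False,
                                      fill_value=0.0) for g in grads]

    def gradient(p):
        return np.stack([gi(p) for gi in interp], axis=-1)

    mask = f.values > 1e-6
    idx = np.argwhere(mask)
    pts = np.stack([ax[0][idx[:, 0]], ax[1][idx[:, 1]], ax[2][idx[:, 2]]],
                   axis=1)
    centers = np.array([[-1.2, 0, 0], [1.5, 0.3, 0]], dtype=float)
    h = 0.4 * spec.step
    for _ in range(600):
        d2 = ((pts[:, None, :] - centers[None]) ** 2).sum(-1)
        if (d2.min(axis=1) < spec.step ** 2).all():
            break
        k1 = gradient(pts)
        k1 /= np.maximum(np.linalg.norm(k1, axis=1, keepdims=True), 1e-300)
        k2 = gradient(pts + 0.5 * h * k1)
        k2 /= np.maximum(np.linalg.norm(k2, axis=1, keepdims=True), 1e-300)
        pts = pts + h * k2
    oracle = np.argmin(((pts[:, None, :] - centers[None]) ** 2).sum(-1),
                       axis=1)
    got = bm.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
    agreement = np.mean(got == oracle)
    assert agreement >= 0.995


def test_unified_basin_conservation(water_case_bumped):
    case = water_case_bumped
    bm = assign_basins(case.density, case.truth_model.geometry)
    pops = integrate_basins(bm, case.density, case.density)
    # partition conservation: basin sums add up to the grid integral
    assert pops.N.sum() == pytest.approx(case.density.integral(), rel=1e-12)
    # unified-basin delta-N of a field against itself is identically zero
    np.testing.assert_array_equal(pops.delta, 0.0)


# ----------------------------------------------------------------------------
# iso-surfaces and surface ESP
# ----------------------------------------------------------------------------

@pytest.fixture(scope="module")
def gaussian_field_96():
    spec = GridSpec.centered((0, 0, 0), 8.0, 96)
    ax = spec.axes()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    return ScalarField(spec, "density", np.exp(-(X ** 2 + Y ** 2 + Z ** 2)),
                       "reference")


def test_gaussian_isosurface_radius_and_area(gaussian_field_96):
    """rho = exp(-r^2), level 0.1: radius sqrt(ln 10), area 4 pi r^2."""
    mesh = extract_isosurface(gaussian_field_96, 0.1)
    r = math.sqrt(math.log(10.0))
    radii = np.linalg.norm(mesh.vertices, axis=1)
    assert np.abs(radii - r).max() < 0.02
    assert mesh.total_area == pytest.approx(4 * math.pi * r * r, rel=0.02)


def test_isosurface_grid_convergence():
    areas = {}
    for n in (48, 96):
        spec = GridSpec.centered((0, 0, 0), 8.0, n)
        ax = spec.axes()
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        f = ScalarField(spec, "density", np.exp(-(X ** 2 + Y ** 2 + Z ** 2)))
        areas[n] = extract_isosurface(f, 0.1).total_area
    exact = 4 * math.pi * math.log(10.0)
    assert abs(areas[96] - exact) < abs(areas[48] - exact)


def test_isosurface_level_errors(gaussian_field_96):
    with pytest.raises(EmptySurfaceError):
        extract_isosurface(gaussian_field_96, 2.0)


def test_surface_average_constant_and_coulomb(gaussian_field_96):
    spec = gaussian_field_96.spec
    const = ScalarField(spec, "esp", np.full((96, 96, 96), 1.7))
    level = math.exp(-4.0)                      # sphere of radius 2 bohr
    mesh = extract_isosurface(gaussian_field_96, level)
    st_ = surface_average_esp(mesh, const)
    assert st_.v_mean == pytest.approx(1.7, rel=1e-12)
    assert st_.v_min == pytest.approx(1.7) and st_.v_max == pytest.approx(1.7)

    esp = coulomb_esp_field([[0.0, 0.0, 0.0]], [1.0], spec)
    st2 = surface_average_esp(mesh, esp)
    assert st2.v_mean == pytest.approx(0.5, rel=2e-3)
    # unweighted cross-check mode stays close on a smooth sphere
    st3 = surface_average_esp(mesh, esp, weighted=False)
    assert st3.v_mean == pytest.approx(st2.v_mean, rel=1e-2)


def test_surface_average_dipole_cancels(gaussian_field_96):
    """A central point dipole averages to ~zero over a centered sphere."""
    spec = gaussian_field_96.spec
    d = 0.05
    esp = coulomb_esp_field([[0, 0, d], [0, 0, -d]], [1.0, -1.0], spec)
    mesh = extract_isosurface(gaussian_field_96, math.exp(-4.0))
    st_ = surface_average_esp(mesh, esp)
    assert abs(st_.v_mean) < 1e-4
    assert st_.v_min <= st_.v_mean <= st_.v_max
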