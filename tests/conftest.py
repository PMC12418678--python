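"""Shared fixtures: databank, geometries, and desk-scale synthetic cases.

Expensive artifacts (cases with grids, refinements) are session-scoped so
the unit suite and the acceptance suite reuse them where the scenario is
identical.
"""

import numpy as np
import pytest

from mmfit.databank import load_databank
from mmfit.model import ConstraintSet, FrameRules, MoleculeGeometry, build_model
from mmfit.synthetic import SyntheticSpec, builtin_geometry, generate_case


@pytest.fixture(scope="session")
def databank():
    return load_databank("synthetic")


@pytest.fixture(scope="session")
def water_geometry():
    return builtin_geometry("water")


@pytest.fixture(scope="session")
def single_o_model(databank):
    """One isolated neutral oxygen (no bonds, identity frame)."""
    geo = MoleculeGeometry(["O"], np.zeros((1, 3)))
    return build_model(geo, databank, ConstraintSet(h_bond_oriented=False),
                       FrameRules(h_bond_oriented=False))


@pytest.fixture(scope="session")
def single_h_model():
    """Hydrogenic test atom: rho_val = exp(-2r)/pi."""
    db = load_databank("hydrogenic-test")
    geo = MoleculeGeometry(["H"], np.zeros((1, 3)))
    return build_model(geo, db, ConstraintSet(h_bond_oriented=False),
                       FrameRules(h_bond_oriented=False))


@pytest.fixture(scope="session")
def water_case_small():
    """Exactly-representable water case at desk scale (a=15 A, s<=0.5)."""
    spec = SyntheticSpec(geometry_name="water", seed=3, nonrepresentable=False)
    return generate_case(spec, a=15.0, s_max=0.5, build_fields=False)


@pytest.fixture(scope="session")
def water_case_bumped():
    """Perturbed water case with reference fields on a 96^3 grid."""
    spec = SyntheticSpec(geometry_name="water", seed=5, nonrepresentable=True)
    return generate_case(spec, a=15.0, s_max=0.5, grid_npoints=96)
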