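"""Shared fixtures: reference study conditions and reusable solves.

The reference conditions are a 0.15 mol/L 1:1 salt at 298 K next to a
surface charged at -0.25 As/m^2, with water at 55 mol/L, p0 = 3.1 Debye
and n = 1.33 (zero-field permittivity 78.5).  Expensive solves are
session-scoped so property and acceptance tests share them.
"""

import numpy as np
import pytest

from langevinpb import (
    CylinderGeometry,
    ElectrolyteModel,
    GridSpec,
    SurfaceCharge,
    debye_length,
    solve_cylinder,
    solve_planar,
)

RADII_NM = (0.5, 1.0, 2.5, 5.0)


@pytest.fixture(scope="session")
def model():
    return ElectrolyteModel()


@pytest.fixture(scope="session")
def sigma_ref():
    return SurfaceCharge(-0.25)


@pytest.fixture(scope="session")
def lam(model):
    return debye_length(model)


@pytest.fixture(scope="session")
def planar_ref(model, sigma_ref):
    """Planar modified-LPB solve at the reference conditions."""
    return solve_planar(model, sigma_ref)


@pytest.fixture(scope="session")
def cylinder_ref(model, sigma_ref):
    """Cylindrical solves at the four reference radii, keyed by R in nm."""
    return {
        R: solve_cylinder(model, sigma_ref, CylinderGeometry.from_nm(R))
        for R in RADII_NM
    }


@pytest.fixture(scope="session")
def cylinder_20nm(model, sigma_ref):
    """Large-radius cylinder used for the planar-limit comparison."""
    return solve_cylinder(
        model, sigma_ref, CylinderGeometry.from_nm(20.0), GridSpec(n_points=2048)
    )


def monotone(arr, direction=1, rel_tol=1e-6):
    """Monotonicity up to a small relative wiggle (roundoff in flat tails)."""
    arr = np.asarray(arr, dtype=float)
    slack = rel_tol * np.max(np.abs(arr))
    d = np.diff(arr) * direction
    return bool(np.all(d >= -slack))
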