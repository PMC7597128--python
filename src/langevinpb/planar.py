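"""Modified LPB equation on a half-space next to a uniformly charged plane.

The problem solved is

    d/dx [ eps0 * eps_r(E) * phi'(x) ] = 2*e0*n0*sinh(beta*e0*phi(x)),
    eps0 * eps_r(E(0)) * phi'(0) = -sigma        (flux at the wall),
    phi -> 0 far from the wall,

with eps_r(E) the Langevin-saturating permittivity.  The wall condition is
the outward-normal flux form of the surface boundary condition; it is
implicit (eps_r depends on |phi'| at the wall) and is resolved
self-consistently by the Picard loop of the shared engine.
"""

from __future__ import annotations

import numpy as np

from .physics import ElectrolyteModel, SurfaceCharge
from .profiles import SolutionProfile
from .solver import (
    GridSpec,
    LPBClosure,
    SolverOptions,
    build_profile,
    make_grid,
    solve_reduced,
)

__all__ = ["solve_planar", "check_electroneutrality_planar"]


def solve_planar(
    model: ElectrolyteModel,
    sigma: SurfaceCharge,
    grid: GridSpec = GridSpec(),
    opts: SolverOptions = SolverOptions(),
) -> SolutionProfile:
    """Solve the planar modified LPB problem; coord = distance from the wall."""
    closure = LPBClosure(model)
    length = grid.resolve_length(model)
    x = make_grid(length, grid.n_points, grid.grading, fine_at_start=True)
    result = solve_reduced(closure, "planar", sigma.sigma, x, opts)
    return build_profile(closure, result, "planar", sigma)


def check_electroneutrality_planar(profile: SolutionProfile) -> float:
    """Relative error of the integral charge balance |int(rho_free) + sigma|/|sigma|.

    The diffuse-layer charge per unit area must cancel the surface charge.
    For sigma = 0 the absolute integral is returned, scaled by the natural
    charge-per-area unit e0*n0*lambda_D.
    """
    if profile.geometry != "planar":
        raise ValueError("expected a planar profile")
    if not profile.converged:
        raise RuntimeError("electroneutrality check requires a converged profile")
    total = float(np.trapezoid(profile.rho_free, profile.coord))
    sigma = profile.sigma.sigma
    if sigma == 0.0:
        from .physics import debye_length

        scale = profile.model.constants.e0 * profile.model.n0 * debye_length(profile.model)
        return abs(total) / scale
    return abs(total + sigma) / abs(sigma)
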