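"""Langevin-Wicke-Eigen (steric) generalization with asymmetric ion sizes.

Water and hydrated ions share a lattice of site density ns; a hydrated
cation (anion) occupies alpha_plus (alpha_minus) sites, a water molecule
one site.  The excluded-volume denominator

    DA(phi, E) = alpha+ n0 e^(-beta e0 phi) + alpha- n0 e^(+beta e0 phi)
                 + n0w * sinh(u)/u,            u = beta*gamma*p0*E,

(with n0w = ns - (alpha+ + alpha-) n0 the bulk water density and
sinh(u)/u the orientational average of the dipole Boltzmann weight)
saturates the counterion density at ns/alpha+ and depletes water where
counterions crowd, which lowers the permittivity near the wall beyond the
pure Langevin saturation.  The planar field equation becomes

    d/dx[eps0 eps_r(x) phi'] = 2 e0 ns n0 sinh(beta e0 phi)/DA(phi, E),
    eps_r = n^2 + (n0w ns p0/eps0)((2+n^2)/3) F(u)/(DA E),  F(u) = L(u) sinh(u)/u,

equivalently eps_r = n^2 + (p0/eps0)((2+n^2)/3) n_w(x) L(u)/E with the
local water density n_w(x) = ns n0w (sinh u/u)/DA, so the model reduces to
the modified LPB form with the local in place of the bulk water density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import mol_per_L_to_per_m3
from .physics import (
    ElectrolyteModel,
    SurfaceCharge,
    _check_finite,
    _reduced_potential,
    langevin,
    langevin_ratio,
)
from .profiles import SolutionProfile
from .solver import (
    Closure,
    GridSpec,
    SolverOptions,
    build_profile,
    make_grid,
    solve_reduced,
)

__all__ = [
    "StericParams",
    "f_function",
    "steric_denominator",
    "steric_permittivity",
    "solve_steric_planar",
]

_SINH_GUARD = 700.0


@dataclass(frozen=True)
class StericParams:
    """Lattice-statistics parameters of the Wicke-Eigen extension.

    alpha_plus/alpha_minus: lattice sites per hydrated cation/anion (>= 1);
    ns: lattice site number density, 1/m^3 (default 55 mol/L, pure water).
    """

    alpha_plus: float = 1.0
    alpha_minus: float = 1.0
    ns: float = mol_per_L_to_per_m3(55.0)

    def __post_init__(self) -> None:
        if not (self.alpha_plus >= 1.0 and self.alpha_minus >= 1.0):
            raise ValueError("alpha_plus and alpha_minus must be >= 1")
        if not self.ns > 0:
            raise ValueError("lattice site density ns must be positive")

    def bulk_water_density(self, model: ElectrolyteModel) -> float:
        """n0w = ns - (alpha+ + alpha-)*n0; must be positive (dilute salt)."""
        n0w = self.ns - (self.alpha_plus + self.alpha_minus) * model.n0
        if not n0w > 0:
            raise ValueError(
                "bulk water density n0w = ns - (alpha+ + alpha-)*n0 is not "
                "positive; the lattice holds no water at this salt level"
            )
        return n0w


def _sinhc(u):
    """sinh(u)/u with its limit 1 at u = 0; overflow-guarded."""
    arr = np.asarray(u, dtype=float)
    if np.any(np.abs(arr) > _SINH_GUARD):
        raise OverflowError("dipole energy u exceeds the sinh overflow guard (700)")
    return np.where(arr == 0.0, 1.0, np.sinh(np.where(arr == 0.0, 1.0, arr)) / np.where(arr == 0.0, 1.0, arr))


def f_function(u):
    """F(u) = L(u)*sinh(u)/u; F(0) = 0, F(u) ~ u/3 for small u."""
    arr = _check_finite(u)
    return langevin(arr) * _sinhc(arr)


def steric_denominator(phi, E, model: ElectrolyteModel, steric: StericParams):
    """Excluded-volume denominator DA(phi, E), 1/m^3.

    At phi = 0, E = 0 it equals (alpha+ + alpha-)*n0 + n0w = ns, normalizing
    the bulk densities.
    """
    psi = _reduced_potential(phi, model)
    E = _check_finite(E, "E")
    if np.any(np.asarray(E) < 0):
        raise ValueError("field magnitude E must be non-negative")
    u = model.beta * model.gamma * model.p0 * np.asarray(E, dtype=float)
    n0w = steric.bulk_water_density(model)
    return (
        steric.alpha_plus * model.n0 * np.exp(-psi)
        + steric.alpha_minus * model.n0 * np.exp(psi)
        + n0w * _sinhc(u)
    )


def steric_permittivity(phi, E, model: ElectrolyteModel, steric: StericParams):
    """Steric relative permittivity, regular at E = 0.

    Written via F(u)/u = (L(u)/u)*(sinh(u)/u), so the E -> 0 limit is the
    Onsager formula with the local water density ns*n0w/DA(phi, 0) in place
    of nw.
    """
    E = _check_finite(E, "E")
    if np.any(np.asarray(E) < 0):
        raise ValueError("field magnitude E must be non-negative")
    bgp = model.beta * model.gamma * model.p0
    u = bgp * np.asarray(E, dtype=float)
    c = (2.0 + model.n**2) / 3.0
    n0w = steric.bulk_water_density(model)
    DA = steric_denominator(phi, E, model, steric)
    return model.n**2 + (n0w * steric.ns * model.p0 / model.constants.eps0) * c * bgp * (
        langevin_ratio(u) * _sinhc(u) / DA
    )


class StericClosure(Closure):
    """Langevin-Wicke-Eigen constitutive closure for the shared engine."""

    def __init__(self, model: ElectrolyteModel, steric: StericParams):
        self.model = model
        self.steric = steric
        self.steric.bulk_water_density(model)  # validate early

    def eps(self, phi, E):
        return steric_permittivity(phi, E, self.model, self.steric)

    def rhs(self, psi, E):
        phi = np.asarray(psi, dtype=float) / (self.model.beta * self.model.constants.e0)
        DA = steric_denominator(phi, E, self.model, self.steric)
        return self.steric.ns * np.sinh(psi) / DA

    def rhs_dpsi(self, psi, E):
        m = self.model
        phi = np.asarray(psi, dtype=float) / (m.beta * m.constants.e0)
        DA = steric_denominator(phi, E, m, self.steric)
        dDA = (
            -self.steric.alpha_plus * m.n0 * np.exp(-np.asarray(psi, dtype=float))
            + self.steric.alpha_minus * m.n0 * np.exp(np.asarray(psi, dtype=float))
        )
        return self.steric.ns * (np.cosh(psi) * DA - np.sinh(psi) * dDA) / DA**2

    def ion_densities(self, phi, E):
        m = self.model
        psi = _reduced_potential(phi, m)
        DA = steric_denominator(phi, E, m, self.steric)
        n_plus = self.steric.ns * m.n0 * np.exp(-psi) / DA
        n_minus = self.steric.ns * m.n0 * np.exp(psi) / DA
        return n_plus, n_minus


def solve_steric_planar(
    model: ElectrolyteModel,
    sigma: SurfaceCharge,
    steric: StericParams = StericParams(),
    grid: GridSpec = GridSpec(),
    opts: SolverOptions = SolverOptions(),
) -> SolutionProfile:
    """Solve the planar Langevin-Wicke-Eigen problem.

    Same wall/bulk boundary structure as :func:`langevinpb.planar.solve_planar`
    but with the steric permittivity and the DA-saturated ion densities; the
    counterion density is bounded by ns/alpha+ everywhere.
    """
    closure = StericClosure(model, steric)
    if grid.domain_length == "auto":
        # size the domain with the steric zero-field permittivity, which can
        # differ substantially from the non-steric Onsager value
        from .physics import debye_length

        length = max(20.0 * debye_length(model, closure.eps_ref), 5.0e-9)
    else:
        length = float(grid.domain_length)
    x = make_grid(length, grid.n_points, grid.grading, fine_at_start=True)
    result = solve_reduced(closure, "planar", sigma.sigma, x, opts)
    return build_profile(closure, result, "planar", sigma)
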