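"""Constitutive physics of the Langevin Poisson-Boltzmann (LPB) model.

The electrolyte is a 1:1 salt of point-like ions in water whose molecules
carry a permanent dipole (external moment p0) embedded in a sphere of
permittivity n^2 (n = optical refractive index).  The dipole feels the
Kirkwood-Onsager cavity field, gamma*E with gamma = (3/2)(2+n^2)/3, and its
thermal-average alignment follows the Langevin function.  This yields a
relative permittivity that decreases with local field strength (dielectric
saturation):

    eps_r(E) = n^2 + (nw*p0/eps0) * ((2+n^2)/3) * L(beta*gamma*p0*E)/E

which at E -> 0 reduces to the Onsager zero-field value (78.5 for the
defaults p0 = 3.1 D, nw/NA = 55 mol/L, n = 1.33, T = 298 K) and at
E -> inf falls to the optical n^2.

All functions are pure, SI-consistent and numpy-vectorized; they are shared
by the planar, cylindrical and steric solvers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import CONSTANTS, PhysicalConstants, debye_to_Cm, mol_per_L_to_per_m3

__all__ = [
    "ElectrolyteModel",
    "SurfaceCharge",
    "langevin",
    "langevin_ratio",
    "cavity_factor",
    "onsager_permittivity",
    "field_permittivity",
    "mean_orientation",
    "orientational_polarization",
    "boltzmann_ion_densities",
    "free_charge_density",
    "debye_length",
]

#: series/closed-form switch point for the Langevin function.  The direct
#: coth(u) - 1/u evaluation loses digits to cancellation as ~eps_mach/u^2,
#: while the 9th-order Taylor series is accurate to ~u^10/(4e6); u = 1e-2
#: keeps both branches at machine accuracy, so L(u) and eps_r(E) stay
#: monotone to roundoff across the switch
_SERIES_SWITCH = 1.0e-2

#: largest |beta*e0*phi| accepted before exp() becomes meaningless
_EXP_GUARD = 700.0


def _check_finite(u, name: str = "u"):
    arr = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {u!r}")
    return arr


def langevin(u):
    """Langevin function L(u) = coth(u) - 1/u.

    Mean alignment <cos> of a classical dipole of reduced energy u at
    thermal equilibrium.  Odd, bounded by (-1, 1), L(u) ~ u/3 for small u.
    A 5-term Taylor series is used for |u| < 1e-4 to avoid catastrophic
    cancellation between coth(u) and 1/u.
    """
    arr = _check_finite(u)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.empty_like(arr)
    small = np.abs(arr) < _SERIES_SWITCH
    us = arr[small]
    u2 = us * us
    # L(u) = u/3 - u^3/45 + 2u^5/945 - u^7/4725 + 2u^9/93555 - ...
    out[small] = us * (
        1.0 / 3.0
        + u2 * (-1.0 / 45.0 + u2 * (2.0 / 945.0 + u2 * (-1.0 / 4725.0 + u2 * (2.0 / 93555.0))))
    )
    ub = arr[~small]
    with np.errstate(over="ignore"):
        out[~small] = 1.0 / np.tanh(ub) - 1.0 / ub
    return float(out[0]) if scalar else out


def langevin_ratio(u):
    """L(u)/u, extended by its limit 1/3 at u = 0.  Even in u.

    Needed to write eps_r(E) in a form regular at E = 0.
    """
    arr = _check_finite(u)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.empty_like(arr)
    small = np.abs(arr) < _SERIES_SWITCH
    u2 = arr[small] ** 2
    # L(u)/u = 1/3 - u^2/45 + 2u^4/945 - u^6/4725 + 2u^8/93555 - ...
    out[small] = (
        1.0 / 3.0
        + u2 * (-1.0 / 45.0 + u2 * (2.0 / 945.0 + u2 * (-1.0 / 4725.0 + u2 * (2.0 / 93555.0))))
    )
    ub = arr[~small]
    with np.errstate(over="ignore"):
        out[~small] = (1.0 / np.tanh(ub) - 1.0 / ub) / ub
    return float(out[0]) if scalar else out


def cavity_factor(n: float) -> float:
    """Cavity-field factor gamma = (3/2)*(2+n^2)/3 for refractive index n."""
    if not (np.isfinite(n) and n >= 1.0):
        raise ValueError(f"refractive index must be finite and >= 1, got {n!r}")
    return 1.5 * (2.0 + n * n) / 3.0


@dataclass(frozen=True)
class ElectrolyteModel:
    """Physical parameters of the electrolyte solution (strict SI).

    Use :meth:`from_concentrations` for the user-facing units
    (mol/L, Debye).  Derived read-only quantities: ``beta`` = 1/kT,
    ``gamma`` = cavity factor, ``eps_bulk`` = zero-field (Onsager)
    relative permittivity.
    """

    n0: float = mol_per_L_to_per_m3(0.15)   # bulk ion number density, 1/m^3
    T: float = 298.0                        # temperature, K
    p0: float = debye_to_Cm(3.1)            # external water dipole moment, C*m
    nw: float = mol_per_L_to_per_m3(55.0)   # water number density, 1/m^3
    n: float = 1.33                         # optical refractive index
    constants: PhysicalConstants = field(default=CONSTANTS, repr=False)

    def __post_init__(self) -> None:
        if not self.n0 > 0:
            raise ValueError("bulk ion density n0 must be positive")
        if not self.T > 0:
            raise ValueError("temperature must be positive")
        if not self.p0 >= 0:
            raise ValueError("dipole moment p0 must be non-negative")
        if not self.nw > 0:
            raise ValueError("water density nw must be positive")
        if not self.n >= 1:
            raise ValueError("refractive index must be >= 1")

    @classmethod
    def from_concentrations(
        cls,
        n0_mol_per_L: float = 0.15,
        T: float = 298.0,
        p0_debye: float = 3.1,
        nw_mol_per_L: float = 55.0,
        n: float = 1.33,
        constants: PhysicalConstants = CONSTANTS,
    ) -> "ElectrolyteModel":
        """Build a model from user-facing units (mol/L, Debye, K)."""
        return cls(
            n0=mol_per_L_to_per_m3(n0_mol_per_L, constants),
            T=T,
            p0=debye_to_Cm(p0_debye, constants),
            nw=mol_per_L_to_per_m3(nw_mol_per_L, constants),
            n=n,
            constants=constants,
        )

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/kT, 1/J."""
        return 1.0 / (self.constants.kB * self.T)

    @property
    def gamma(self) -> float:
        """Cavity-field factor (3/2)(2+n^2)/3."""
        return cavity_factor(self.n)

    @property
    def eps_bulk(self) -> float:
        """Zero-field (Onsager) relative permittivity."""
        return onsager_permittivity(self)


@dataclass(frozen=True)
class SurfaceCharge:
    """Uniform surface charge density sigma in As/m^2 (= C/m^2).

    A warning (not an error) is emitted beyond |sigma| = 0.3 As/m^2, the
    approximate range where the mean-field treatment remains justified.
    """

    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma):
            raise ValueError("surface charge density must be finite")
        if abs(self.sigma) > 0.3:
            warnings.warn(
                f"|sigma| = {abs(self.sigma):.3g} As/m^2 exceeds ~0.3 As/m^2; "
                "the mean-field model validity is strained",
                stacklevel=2,
            )


def onsager_permittivity(model: ElectrolyteModel) -> float:
    """Zero-field relative permittivity n^2 + nw*p0^2*beta/(2*eps0)*((2+n^2)/3)^2."""
    c = (2.0 + model.n**2) / 3.0
    return model.n**2 + model.nw * model.p0**2 * model.beta / (2.0 * model.constants.eps0) * c * c


def field_permittivity(E, model: ElectrolyteModel):
    """Field-dependent relative permittivity eps_r(E).

    Written via L(u)/u so that E = 0 is regular; strictly decreasing in E,
    from the Onsager value at E = 0 down to n^2 at saturation.
    """
    E = _check_finite(E, "E")
    if np.any(E < 0):
        raise ValueError("field magnitude E must be non-negative")
    bgp = model.beta * model.gamma * model.p0
    c = (2.0 + model.n**2) / 3.0
    u = bgp * E
    return model.n**2 + (model.nw * model.p0 / model.constants.eps0) * c * langevin_ratio(u) * bgp


def mean_orientation(E, model: ElectrolyteModel):
    """Thermal-average dipole orientation <cos w> = -L(beta*gamma*p0*E).

    In [-1, 0]: zero at E = 0, -1 at full saturation (dipoles anti-aligned
    with the potential gradient).
    """
    E = _check_finite(E, "E")
    if np.any(E < 0):
        raise ValueError("field magnitude E must be non-negative")
    return -langevin(model.beta * model.gamma * model.p0 * E)


def orientational_polarization(E, model: ElectrolyteModel):
    """Orientational polarization P(E) = -nw*p0*((2+n^2)/3)*L(beta*gamma*p0*E), C/m^2.

    Satisfies the factorization identity eps0*(eps_r(E) - n^2)*E = |P(E)|.
    """
    E = _check_finite(E, "E")
    if np.any(E < 0):
        raise ValueError("field magnitude E must be non-negative")
    c = (2.0 + model.n**2) / 3.0
    return -model.nw * model.p0 * c * langevin(model.beta * model.gamma * model.p0 * E)


def _reduced_potential(phi, model: ElectrolyteModel):
    psi = np.asarray(phi, dtype=float) * model.beta * model.constants.e0
    if not np.all(np.isfinite(psi)):
        raise ValueError("potential must be finite")
    if np.any(np.abs(psi) > _EXP_GUARD):
        raise ValueError(
            "reduced potential |beta*e0*phi| exceeds 700; unphysical input "
            "(Boltzmann factor overflows double precision)"
        )
    return psi


def boltzmann_ion_densities(phi, model: ElectrolyteModel):
    """Boltzmann ion densities (n+, n-) = n0*exp(-+ beta*e0*phi), 1/m^3."""
    psi = _reduced_potential(phi, model)
    return model.n0 * np.exp(-psi), model.n0 * np.exp(psi)


def free_charge_density(phi, model: ElectrolyteModel):
    """Net ionic charge density rho_free = -2*e0*n0*sinh(beta*e0*phi), C/m^3."""
    psi = _reduced_potential(phi, model)
    return -2.0 * model.constants.e0 * model.n0 * np.sinh(psi)


def debye_length(model: ElectrolyteModel, eps_r: float | None = None) -> float:
    """Debye screening length sqrt(eps0*eps_r*kT/(2*e0^2*n0)), m.

    ``eps_r`` defaults to the model's zero-field (Onsager) permittivity.
    """
    if eps_r is None:
        eps_r = model.eps_bulk
    c = model.constants
    return math.sqrt(c.eps0 * eps_r * c.kB * model.T / (2.0 * c.e0**2 * model.n0))
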