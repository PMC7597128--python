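"""Physical constants and unit conversions.

Internally the package works in strict SI; user-facing quantities
(mol/L, Debye, nm, mV) are converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants used throughout the model (SI units)."""

    e0: float = 1.602176634e-19       # elementary charge, C
    eps0: float = 8.8541878128e-12    # vacuum permittivity, F/m
    kB: float = 1.380649e-23          # Boltzmann constant, J/K
    NA: float = 6.02214076e23         # Avogadro number, 1/mol
    debye: float = 3.336e-30          # 1 Debye in C*m

    def __post_init__(self) -> None:
        for name in ("e0", "eps0", "kB", "NA", "debye"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"physical constant {name!r} must be positive")


CONSTANTS = PhysicalConstants()


def mol_per_L_to_per_m3(c: float, constants: PhysicalConstants = CONSTANTS) -> float:
    """Convert a molar concentration (mol/L) to a number density (1/m^3)."""
    return c * 1.0e3 * constants.NA


def per_m3_to_mol_per_L(n: float, constants: PhysicalConstants = CONSTANTS) -> float:
    """Convert a number density (1/m^3) to a molar concentration (mol/L)."""
    return n / (1.0e3 * constants.NA)


def debye_to_Cm(p: float, constants: PhysicalConstants = CONSTANTS) -> float:
    """Convert a dipole moment from Debye to C*m."""
    return p * constants.debye


def Cm_to_debye(p: float, constants: PhysicalConstants = CONSTANTS) -> float:
    """Convert a dipole moment from C*m to Debye."""
    return p / constants.debye
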