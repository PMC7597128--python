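"""Solution container shared by the planar, cylindrical and steric solvers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .physics import ElectrolyteModel, SurfaceCharge


@dataclass
class SolutionProfile:
    """Co-located radial/axial profiles of one converged solve.

    Arrays share the coordinate grid ``coord`` (m, strictly increasing).
    For the planar geometry ``coord`` is the distance from the charged
    wall; for the cylinder it runs from the axis (r = 0) to the inner
    wall (r = R).
    """

    coord: np.ndarray          # position, m
    phi: np.ndarray            # electric potential, V
    E: np.ndarray              # field magnitude, V/m
    eps_r: np.ndarray          # relative permittivity
    rho_free: np.ndarray       # net ionic charge density, C/m^3
    n_plus: np.ndarray         # counter-/co-ion densities, 1/m^3
    n_minus: np.ndarray
    mean_cos: np.ndarray       # mean dipole orientation <cos w>
    converged: bool
    residual: float
    iterations: int
    geometry: str              # "planar" | "cylinder"
    model: ElectrolyteModel
    sigma: SurfaceCharge
    R: Optional[float] = None  # cylinder radius, m (None for planar)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.coord)
        for name in ("phi", "E", "eps_r", "rho_free", "n_plus", "n_minus", "mean_cos"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"profile array {name!r} length mismatch")
        if n >= 2 and not np.all(np.diff(self.coord) > 0):
            raise ValueError("coord must be strictly increasing")
        if self.geometry not in ("planar", "cylinder"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if np.any(np.abs(self.mean_cos) > 1.0):
            raise ValueError("mean dipole orientation must lie in [-1, 1]")

    @property
    def phi_wall(self) -> float:
        """Potential at the charged surface (V)."""
        return float(self.phi[0] if self.geometry == "planar" else self.phi[-1])

    @property
    def wall_index(self) -> int:
        return 0 if self.geometry == "planar" else len(self.coord) - 1
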