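"""Shared nonlinear boundary-value engine for the modified LPB equation.

The equation solved, in divergence form, is

    div[ eps0 * eps_r(phi, E) * grad(phi) ] = q(phi, E)

on a 1D planar half-space or an axisymmetric cylinder cross-section, with a
self-consistent flux boundary condition eps0*eps_r*dphi/dn_out = sigma at
the charged wall.  Internally the problem is reduced: psi = beta*e0*phi and
lengths are measured in Debye lengths of the zero-field permittivity, which
makes tolerances geometry- and parameter-independent.

Discretization: vertex-centred, flux-conservative finite volumes on an
optionally graded grid; the axis cell of the cylinder uses an exactly zero
inner-face flux, removing the 1/r singularity.  Nonlinearity: an outer
Picard iteration freezes the field-dependent coefficients (under-relaxed),
an inner damped Newton iteration solves the resulting semilinear Poisson-
Boltzmann step, and the surface charge is ramped geometrically
(continuation) from 1% of its target value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.linalg import solve_banded

from .physics import ElectrolyteModel, debye_length

__all__ = ["GridSpec", "SolverOptions", "ConvergenceError", "make_grid"]

#: cap on the largest/smallest cell-width ratio of a graded grid; beyond it
#: the boundary layer is resolved and further stretching only wastes nodes
_MAX_WIDTH_RATIO = 200.0


class ConvergenceError(RuntimeError):
    """Raised when the damped-Newton/Picard/continuation stack fails."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class GridSpec:
    """Discretization control.

    ``domain_length`` applies to the planar half-space only ("auto" =
    max(20 Debye lengths, 5 nm)); the cylinder domain is its radius.
    ``grading`` >= 1 concentrates nodes at the charged surface: cell widths
    grow geometrically away from the wall (capped at a 200x width ratio).
    """

    n_points: int = 1024
    domain_length: float | str = "auto"
    grading: float = 1.02

    def __post_init__(self) -> None:
        if self.n_points < 16:
            raise ValueError("n_points must be >= 16")
        if not (1.0 <= self.grading <= 1.3):
            raise ValueError("grading must lie in [1, 1.3]")
        if isinstance(self.domain_length, str):
            if self.domain_length != "auto":
                raise ValueError("domain_length must be a length in m or 'auto'")
        elif not self.domain_length > 0:
            raise ValueError("domain_length must be positive")

    def resolve_length(self, model: ElectrolyteModel) -> float:
        if self.domain_length == "auto":
            return max(20.0 * debye_length(model), 5.0e-9)
        return float(self.domain_length)


@dataclass(frozen=True)
class SolverOptions:
    """Newton/Picard/continuation controls.

    ``residual_tol`` is an infinity-norm tolerance on the reduced potential
    psi = beta*e0*phi: the Picard/Newton stack is converged when one more
    self-consistent update moves psi by less than this everywhere.  (The
    local PDE residual itself is reported on the profile but is not used as
    the stopping test, since dividing the discrete residual by cell volumes
    amplifies double-precision roundoff as 1/h^2 on fine grids.)
    """

    residual_tol: float = 1.0e-8
    max_newton_iters: int = 30
    min_damping: float = 1.0e-6
    continuation_steps: int = 10
    picard_relaxation: float = 0.5
    max_picard_iters: int = 500

    def __post_init__(self) -> None:
        if not self.residual_tol > 0:
            raise ValueError("residual_tol must be positive")
        if not self.min_damping >= 1.0e-6:
            raise ValueError("min_damping must be >= 1e-6")
        if not (0.0 < self.picard_relaxation <= 1.0):
            raise ValueError("picard_relaxation must lie in (0, 1]")
        if self.continuation_steps < 1:
            raise ValueError("continuation_steps must be >= 1")


def make_grid(length: float, n_points: int, grading: float, fine_at_start: bool) -> np.ndarray:
    """Nodes on [0, length], cell widths growing geometrically from the fine end."""
    n_cells = n_points - 1
    if grading <= 1.0:
        return np.linspace(0.0, length, n_points)
    i = np.arange(n_cells, dtype=float)
    i_cap = np.log(_MAX_WIDTH_RATIO) / np.log(grading)
    w = grading ** np.minimum(i, i_cap)
    if not fine_at_start:
        w = w[::-1]
    x = np.concatenate(([0.0], np.cumsum(w)))
    x *= length / x[-1]
    x[-1] = length
    return x


class Closure:
    """Constitutive closure: permittivity and ionic source as functions of
    the local potential (V) and field magnitude (V/m).  Subclasses supply
    the modified-LPB, constant-permittivity and steric variants."""

    model: ElectrolyteModel

    def eps(self, phi, E):
        raise NotImplementedError

    def rhs(self, psi, E):
        """Reduced source f such that the reduced equation reads
        d/dx[(eps_r/eps_ref) dpsi/dx] = f(psi, E)."""
        raise NotImplementedError

    def rhs_dpsi(self, psi, E):
        raise NotImplementedError

    def ion_densities(self, phi, E):
        from .physics import boltzmann_ion_densities

        return boltzmann_ion_densities(phi, self.model)

    @property
    def eps_ref(self) -> float:
        """Zero-field permittivity used for the nondimensionalization."""
        return float(self.eps(0.0, 0.0))


def build_profile(
    closure: Closure,
    result: SolveResult,
    geometry: str,
    sigma,
    R: Optional[float] = None,
):
    """Assemble a :class:`SolutionProfile` from a reduced solve result.

    Pointwise fields are reconstructed with the same constitutive closure
    used in the solve, so the profile is internally consistent
    (rho_free[i] = rho(phi[i]), eps_r[i] = eps(phi[i], E[i]), ...).
    """
    from .physics import mean_orientation
    from .profiles import SolutionProfile

    model = closure.model
    c = model.constants
    lam = result.lambda_ref
    coord = result.x * lam
    phi = result.psi / (model.beta * c.e0)
    E_scale = 1.0 / (model.beta * c.e0 * lam)
    E = _field_nodes(result.psi, result.x, E_scale)
    eps_r = np.asarray(closure.eps(phi, E), dtype=float)
    n_plus, n_minus = closure.ion_densities(phi, E)
    rho_free = c.e0 * (n_plus - n_minus)
    mean_cos = mean_orientation(E, model)
    return SolutionProfile(
        coord=coord,
        phi=phi,
        E=E,
        eps_r=eps_r,
        rho_free=rho_free,
        n_plus=np.asarray(n_plus, dtype=float),
        n_minus=np.asarray(n_minus, dtype=float),
        mean_cos=np.asarray(mean_cos, dtype=float),
        converged=result.converged,
        residual=result.residual,
        iterations=result.iterations,
        geometry=geometry,
        model=model,
        sigma=sigma,
        R=R,
        warnings=list(result.warnings),
    )


class LPBClosure(Closure):
    """Modified LPB: eps_r = eps_r(E) with Langevin saturation, ideal ions."""

    def __init__(self, model: ElectrolyteModel):
        self.model = model

    def eps(self, phi, E):
        from .physics import field_permittivity

        return field_permittivity(E, self.model)

    def rhs(self, psi, E):
        return np.sinh(psi)

    def rhs_dpsi(self, psi, E):
        return np.cosh(psi)


class ConstantEpsClosure(Closure):
    """Classical PB: permittivity frozen at a constant value."""

    def __init__(self, model: ElectrolyteModel, eps_const: float):
        if not eps_const >= 1.0:
            raise ValueError("eps_const must be >= 1")
        self.model = model
        self.eps_const = float(eps_const)

    def eps(self, phi, E):
        return np.broadcast_to(self.eps_const, np.shape(E)).copy() if np.ndim(E) else self.eps_const

    def rhs(self, psi, E):
        return np.sinh(psi)

    def rhs_dpsi(self, psi, E):
        return np.cosh(psi)


@dataclass
class SolveResult:
    x: np.ndarray          # reduced coordinates (Debye lengths)
    psi: np.ndarray        # reduced potential
    converged: bool
    residual: float
    iterations: int
    lambda_ref: float      # Debye length used in the reduction, m
    warnings: list


def _assemble(
    psi: np.ndarray,
    x: np.ndarray,
    a_face: np.ndarray,
    E_node: np.ndarray,
    closure: Closure,
    geometry: str,
    sig_red: float,
):
    """Residual vector and tridiagonal Jacobian bands of the FV equations.

    Returns (R, lower, diag, upper, W) over the *unknown* nodes: all nodes
    for the cylinder (pure flux BCs), nodes [0, N-2] for the planar case
    (Dirichlet psi = 0 at the outer boundary).
    """
    N = len(x)
    h = np.diff(x)
    if geometry == "planar":
        w_face = np.ones(N - 1)
        W = np.empty(N)
        W[0] = h[0] / 2.0
        W[1:-1] = (h[:-1] + h[1:]) / 2.0
        W[-1] = h[-1] / 2.0
    else:  # cylinder: weight r, faces at midpoints, axis face at r = 0
        r_face = (x[:-1] + x[1:]) / 2.0
        w_face = r_face
        edges = np.concatenate(([0.0], r_face, [x[-1]]))
        W = (edges[1:] ** 2 - edges[:-1] ** 2) / 2.0

    c = w_face * a_face / h
    flux = c * (psi[1:] - psi[:-1])          # face fluxes w*a*psi'
    f = closure.rhs(psi, E_node)
    fp = closure.rhs_dpsi(psi, E_node)

    R = np.empty(N)
    R[1:-1] = flux[1:] - flux[:-1] - W[1:-1] * f[1:-1]
    if geometry == "planar":
        # wall at node 0: incoming wall-face flux is exactly -sigma_reduced
        R[0] = flux[0] + sig_red - W[0] * f[0]
        R[-1] = 0.0
        n_eq = N - 1
    else:
        # axis at node 0: zero inner-face flux; wall at node N-1
        R[0] = flux[0] - W[0] * f[0]
        R[-1] = x[-1] * sig_red - flux[-1] - W[-1] * f[-1]
        n_eq = N

    lower = np.zeros(n_eq)
    diag = np.zeros(n_eq)
    upper = np.zeros(n_eq)
    diag[0] = -c[0] - W[0] * fp[0]
    if n_eq > 1:
        upper[1] = c[0]
    i = np.arange(1, n_eq - 1)
    if len(i):
        diag[i] = -c[i] - c[i - 1] - W[i] * fp[i]
        lower[i - 1] = c[i - 1]
        upper[i + 1] = c[i]
    if n_eq > 1:
        j = n_eq - 1
        if geometry == "cylinder":
            diag[j] = -c[j - 1] - W[j] * fp[j]
        else:
            diag[j] = -c[j] - c[j - 1] - W[j] * fp[j]
        lower[j - 1] = c[j - 1]
    return R[:n_eq], lower, diag, upper, W


def _field_faces(psi: np.ndarray, x: np.ndarray, E_scale: float):
    h = np.diff(x)
    dpsi = (psi[1:] - psi[:-1]) / h
    return np.abs(dpsi) * E_scale


def _field_nodes(psi: np.ndarray, x: np.ndarray, E_scale: float):
    return np.abs(np.gradient(psi, x, edge_order=2)) * E_scale


def _newton(
    psi: np.ndarray,
    x: np.ndarray,
    a_face: np.ndarray,
    E_node: np.ndarray,
    closure: Closure,
    geometry: str,
    sig_red: float,
    opts: SolverOptions,
    step_tol: float,
):
    """Damped Newton on the frozen-coefficient semilinear system.

    Iterates until the (damped) update moves psi by less than ``step_tol``
    in the infinity norm, backtracking the step until the 2-norm of the
    residual decreases (damping floored at ``opts.min_damping``).
    """
    n_iter = 0
    psi = psi.copy()
    R, lo, di, up, W = _assemble(psi, x, a_face, E_node, closure, geometry, sig_red)
    for _ in range(opts.max_newton_iters):
        n_eq = len(R)
        ab = np.vstack([up, di, lo])
        delta = solve_banded((1, 1), ab, -R)
        lam = 1.0
        res2 = float(np.linalg.norm(R))
        trial, Rt = psi, R
        while True:
            cand = psi.copy()
            cand[:n_eq] += lam * delta
            with np.errstate(over="raise"):
                try:
                    Rc, lo, di, up, W = _assemble(
                        cand, x, a_face, E_node, closure, geometry, sig_red
                    )
                    ok = float(np.linalg.norm(Rc)) < res2
                except FloatingPointError:
                    ok = False
                    Rc = None
            if ok:
                trial, Rt = cand, Rc
                break
            if lam <= opts.min_damping:
                if Rc is not None:
                    trial, Rt = cand, Rc
                break
            lam /= 2.0
        psi = trial
        R = Rt
        n_iter += 1
        if lam * float(np.max(np.abs(delta))) < step_tol:
            break
    return psi, n_iter


def solve_reduced(
    closure: Closure,
    geometry: Literal["planar", "cylinder"],
    sigma: float,
    x: np.ndarray,
    opts: SolverOptions,
) -> SolveResult:
    """Solve the reduced modified-LPB boundary-value problem.

    ``x`` are node coordinates in metres (0 = wall for planar, 0 = axis for
    cylinder); ``sigma`` is the wall charge in As/m^2.
    """
    model = closure.model
    eps_ref = closure.eps_ref
    lam = debye_length(model, eps_ref)
    xr = x / lam
    c = model.constants
    E_scale = 1.0 / (model.beta * c.e0 * lam)
    kTe = 1.0 / (model.beta * c.e0)
    sig_red_full = sigma * model.beta * c.e0 * lam / (c.eps0 * eps_ref)

    psi = np.zeros_like(xr)
    warnings_: list[str] = []
    total_newton = 0

    if sigma == 0.0:
        return SolveResult(xr, psi, True, 0.0, 0, lam, warnings_)

    # continuation: geometric ramp of sigma from 1% to 100% of target
    K = opts.continuation_steps
    if abs(sig_red_full) < 1.0 or K == 1:
        fractions = [1.0]
    else:
        fractions = [0.01 ** (1.0 - k / K) for k in range(1, K + 1)]

    converged = False
    dpsi = np.inf
    for frac in fractions:
        sig_red = sig_red_full * frac
        final = frac == fractions[-1]
        tol = opts.residual_tol if final else max(opts.residual_tol, 1.0e-5)

        a_face = None
        E_node_frozen = None
        relax = opts.picard_relaxation
        dpsi_prev = np.inf
        stalls = 0
        for picard in range(opts.max_picard_iters):
            E_face = _field_faces(psi, xr, E_scale)
            phi_face = (psi[:-1] + psi[1:]) / 2.0 * kTe
            a_target = np.asarray(closure.eps(phi_face, E_face), dtype=float) / eps_ref
            E_target = _field_nodes(psi, xr, E_scale)
            if a_face is None or picard == 0:
                a_face = a_target
                E_node_frozen = E_target
            else:
                a_face = a_face + relax * (a_target - a_face)
                E_node_frozen = E_node_frozen + relax * (E_target - E_node_frozen)

            prev = psi
            psi, n_it = _newton(
                psi, xr, a_face, E_node_frozen, closure, geometry, sig_red,
                opts, step_tol=0.02 * tol,
            )
            total_newton += n_it
            dpsi = float(np.max(np.abs(psi - prev)))
            if picard >= 1 and dpsi < tol:
                converged = final
                break
            # instability guard: if the fixed-point iteration starts growing
            # (oscillatory mode near the fixed point), under-relax harder
            if dpsi > 0.95 * dpsi_prev:
                stalls += 1
                if stalls >= 4:
                    relax = max(relax / 2.0, 0.05)
                    stalls = 0
            else:
                stalls = max(stalls - 1, 0)
            dpsi_prev = dpsi
        else:
            if final:
                raise ConvergenceError(
                    f"modified LPB solve did not converge: last psi update "
                    f"{dpsi:.3e} after {opts.max_picard_iters} Picard iterations "
                    f"(sigma = {sigma:.4g} As/m^2)",
                    dpsi,
                )

    residual = dpsi  # infinity-norm of the last self-consistent psi update

    if geometry == "planar":
        tail = abs(psi[-2])
        head = abs(psi[0])
        if head > 0 and tail > 1.0e-6 * head:
            warnings_.append(
                f"domain may be too short: |psi| at the outer boundary is "
                f"{tail / head:.2e} of the wall value"
            )
    return SolveResult(xr, psi, converged, residual, total_newton, lam, warnings_)
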