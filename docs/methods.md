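# Methods

## Model

`langevinpb` solves the mean-field electrostatics of a monovalent (1:1)
electrolyte next to a uniformly charged surface, with the water treated as
a dense gas of permanent point dipoles embedded in spheres of optical
permittivity n² (n = 1.33, the refractive index of water). Each dipole
feels the Kirkwood–Onsager cavity field, γE with γ = (3/2)(2+n²)/3, and
its thermal-average alignment follows the Langevin function
L(u) = coth u − 1/u. This produces a field-dependent relative permittivity

    εr(E) = n² + (nw p0/ε0) · ((2+n²)/3) · L(βγp0E)/E ,

which interpolates between the Onsager zero-field value

    εr(0) = n² + nw p0² β/(2ε0) · ((2+n²)/3)²  (= 78.5 for the defaults)

and the optical n² at full dipole saturation. Point ions follow Boltzmann
statistics, n± = n0 exp(∓βe0φ), and the potential obeys the divergence-form
("Langevin Poisson–Boltzmann") equation

    ∇·[ε0 εr(E) ∇φ] = 2 e0 n0 sinh(βe0φ),

with the implicit wall condition ε0 εr(E_s) ∂φ/∂n_out = σ (the wall
permittivity depends on the wall field itself) and φ → 0 in the bulk.
Two geometries are supported: a planar half-space, and an axisymmetric
cylinder of inner radius R with symmetry at the axis (φ'(0) = 0). Inside
narrow tubes the ion densities remain referenced to the external reservoir
concentrations n0 (grand-canonical closure): the tube interior need not
contain a neutral bulk point, which is precisely what makes the net charge
density at the axis of sub-nanometre tubes nonzero.

### Steric (Langevin–Wicke–Eigen) extension

In planar geometry the package also implements the lattice-statistics
generalization for finite ion size. Water and hydrated ions share a
lattice of site density ns (default 55 mol/L, pure water); a hydrated
cation/anion occupies α±/α∓ ≥ 1 sites. All densities are normalized by

    DA(φ,E) = α+ n0 e^(−βe0φ) + α− n0 e^(+βe0φ) + n0w · sinh(u)/u,
    u = βγp0E,   n0w = ns − (α+ + α−) n0,

where sinh(u)/u is the orientational average of the dipole Boltzmann
weight ⟨exp(−u cos ω)⟩. The counterion density ns n0 e^(−βe0φ)/DA is then
bounded by ns/α+ (steric saturation), and the permittivity becomes the
point-ion formula evaluated with the *local* water density
n_w(x) = ns n0w (sinh u/u)/DA — counterion crowding near the wall depletes
water and lowers εr beyond pure dielectric saturation. We note that the
final DA term is sometimes typeset ambiguously in the literature; the
sinh(u)/u reading used here is the only one that (a) equals the
orientational average it represents, (b) reduces εr to the local-water-
density form above, and (c) normalizes the bulk state, DA(0,0) = ns.

## Numerics

* **Reduction.** ψ = βe0φ, lengths in Debye lengths λ_D of the closure's
  zero-field permittivity. The reduced equation is
  d/dx[(εr/ε_ref) ψ'] = f(ψ,E) with f = sinh ψ (point ions) or
  (ns/DA) sinh ψ (steric), and the reduced wall flux is
  σ̃ = σ βe0 λ_D/(ε0 ε_ref). This keeps tolerances geometry- and
  parameter-independent.
* **Discretization.** Vertex-centred, flux-conservative finite volumes on
  an optionally graded grid (cell widths growing geometrically away from
  the wall, width ratio capped at 200×). The wall boundary condition
  enters as the exact wall-face flux −σ̃, so it is enforced in its
  self-consistent (implicit) form without evaluating εr at the wall
  separately; the cylinder axis cell uses an exactly zero inner-face flux,
  removing the 1/r singularity. Because the scheme is conservative, the
  integral charge balance holds to the outer-boundary truncation
  (~e^(−L/λ_D)) in the planar case and to discretization order in the
  cylinder. Observed convergence order for φ is ≈ 2 in both geometries.
* **Nonlinear solve.** Outer Picard iteration freezes the field-dependent
  coefficients εr(E) (and the field in DA), under-relaxed with factor 0.5;
  an inner damped Newton iteration (backtracking line search on the
  residual 2-norm, damping floored at 1e−6) solves each frozen semilinear
  step; the surface charge is ramped geometrically from 1% of its target
  over 10 continuation steps. If the Picard updates stop contracting — an
  oscillatory instability that appears for strongly steric cases such as
  α+ = 4 at σ = −0.25 As/m² — the relaxation factor is halved
  automatically (floor 0.05).
* **Convergence control.** `residual_tol` (default 1e−8) bounds the
  infinity-norm of one more self-consistent update of ψ. The pointwise PDE
  residual is not used as the stopping test because dividing the discrete
  residual by cell volumes amplifies double-precision roundoff as 1/h²;
  the achieved update norm is reported on the profile.
* **Langevin evaluation.** L(u) and L(u)/u switch to a 9th-order Taylor
  series for |u| < 1e−2; above that the closed form is at machine
  accuracy, below it the series is accurate to ~1e−26, so εr(E) stays
  monotone to roundoff across the switch.
* **Degenerate inputs.** σ = 0 returns the exact zero solution; Boltzmann
  factors are overflow-guarded at |βe0φ| = 700 and sinh at u = 700;
  non-finite inputs raise immediately.

## Default parameters

| quantity | default | units | rationale |
| --- | --- | --- | --- |
| n0 | 0.15 | mol/L | reference physiological-scale salt level of the study conditions |
| T | 298 | K | room temperature |
| p0 | 3.1 | Debye | external water dipole moment that reproduces εr(0) = 78.5 with the cavity field |
| nw | 55 | mol/L | pure-water concentration |
| n | 1.33 | — | optical refractive index of water |
| σ | −0.25 | As/m² | reference wall charge; a warning is issued beyond \|σ\| ≈ 0.3 As/m², where the mean-field picture is strained |
| ns | 55 | mol/L | lattice site density = pure water concentration |
| α± | 1 | — | one lattice site per hydrated ion unless set explicitly |
| grid | 1024 points, grading 1.02, planar length max(20 λ_D, 5 nm) | | resolves the saturated wall layer; doubling the domain changes the wall potential by < 1e−6 relative |

Problem sizes used by the validation and test suites: default solves use
1024 nodes; the Gouy–Chapman equivalence check uses 16384 graded nodes on
a 30 λ_D domain (sup-norm agreement ≤ 1e−6 for |σ| ≤ 0.05 As/m²); grid-
order studies use nested uniform grids of 257–8193 nodes. A default solve
takes ~0.1 s; the full test suite runs in seconds.

## What the oracles do and do not show

The independent references are (i) the analytic Gouy–Chapman/Grahame
solution of classical nonlinear PB, checked against the solver with the
permittivity frozen (isolating discretization error from the constitutive
closure); (ii) adaptive quadrature of the explicit orientation integral,
checked against the Langevin closed form to 1e−10; (iii) a
scipy.integrate.solve_bvp collocation solve of the expanded radial ODE,
checked against the cylindrical finite-volume solution (independent
discretization and nonlinear iteration); and (iv) conservation and
symmetry identities (electroneutrality, σ → −σ oddness, the factorization
identity ε0(εr−n²)E = |P|). These validate the implementation of the
stated model. They do not validate the model against real electrolytes:
water multi-layering at the wall, ion–ion and ion–water correlations,
dipole–dipole structural correlations (which would reduce the effective
3.1 D), Stern-layer specific adsorption and temperature-dependent water
density are all outside the closure, and the continuum picture itself is
strained for tube radii below ~0.25 nm and |σ| beyond ~0.3 As/m².

## Design choices made where the design was open

* The ⟨cos ω⟩ sign convention: the signed value −L(βγp0E) ∈ [−1, 0] is
  exposed (dipoles anti-aligned with the potential gradient at a negative
  wall); plotting its magnitude is a presentation choice.
* The four reference radii {0.5, 1.0, 2.5, 5.0} nm are interpreted as
  radii R (the radial coordinate satisfies r ≤ R).
* The steric model is planar-only; a cylindrical steric variant is out of
  scope.
* The point-like limit of the steric model is taken as ns → ∞ at fixed
  salt with the comparison point-ion model evaluated at the matched water
  density nw = ns: the lattice closure n0w = ns − (α++α−)n0 ties the water
  density to ns, so comparing against a fixed-nw model would conflate the
  vanishing steric effect with a change of dielectric strength.
* Bulk truncation (planar) is a Dirichlet φ = 0 at x_max with an
  a-posteriori warning if |φ(x_max)| > 1e−6 |φ(0)|.

## Known limitations

Half-space and infinite-cylinder geometries only (no end effects, no
plate–plate confinement); symmetric monovalent salt only; no Stern-layer
offset; profiles are stationary (no transport). Convergence for strongly
steric parameters (α+ ≳ 6 at |σ| = 0.25 As/m²) may require raising
`max_picard_iters` beyond the default 500.
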