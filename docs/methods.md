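# Methods

## Model

Blood in a large vessel segment Ω is treated as an incompressible
Newtonian fluid in steady Stokes flow (advective terms dropped):

    −ν Δv + ∇p = 0,   ∇·v = 0   in Ω,

with density 1 g/cm³ so the viscosity ν (default 0.04, CGS) acts
directly as the momentum coefficient.  The boundary ∂Ω = Γ_in ∪ Γ_w ∪
∪_i Γ_i carries a plug (uniform) inflow profile on Γ_in, no-slip on the
rigid wall Γ_w, and on each outlet Γ_i the resistive condition of the
coupled multidomain approach: the normal traction equals −λ_i n with a
scalar multiplier

    λ_i = R_i ∫_{Γ_i} v·n dΓ.

Two extra outlet boundary terms, +ν∫(w·n)(n·(∇v n)) − ν∫ w·(∇v n),
remove the tangential component of the viscous natural traction so the
outlet condition acts purely through the normal load (flag
`traction_correction`, default on; in the stated weak form the second
term appears without ν, which is dimensionally inconsistent, so ν is
included in both).

Steady Stokes is deliberately a *calibration* model: it captures the
resistance-dominated flow split and pressure level well enough to
identify the R_i, which are then intended for use in unsteady
(Navier–Stokes or 0D Windkessel) simulations.  Only total resistances
are identifiable from steady data; compliances and proximal/distal
splits come from literature rules (below).

## Optimal control formulation

Controls: R = (R_1 … R_imax), optionally an inlet scale u_in.  Cost:

    J = α_p/2 ∫_{Γp}(p − p_d)² dΓ / ∫_{Γp} p_d² dΓ
      + Σ_i α_i/2 (Q̂_i − Q_i)²/Q_i²
      [+ α_in/2 (Q̂_in − Q_in)²/Q_in²],

with Q̂ the computed fluxes and (p_d, Q_i, Q_in) the measurements; all
weights default to 1 so every normalised measurement contributes
equally.  Γp defaults to the inlet section and is configurable to any
tagged section.  The pressure mismatch is pointwise on Γp; because a
real cross-section's pressure is not exactly constant (entrance
effects), J has a small irreducible floor (~1e-9–1e-7 on the bundled
fixtures) even at the exact generating resistances.  The inlet-flow
term uses the inward-positive inlet flux, the only convention under
which a perfect fit is attainable.

Stationarity of the Lagrangian yields the optimality system: the state
equations; adjoint equations for an adjoint velocity z, pressure b and
per-outlet scalars t_i (t_i = −∫_{Γ_i} z·n); control equations
t_i·Q̂_i = 0; and auxiliary identities k_i = ∫_{Γ_i} v·n introduced so
the product-of-integrals term in the adjoint momentum equation becomes
linear.  With inlet control, the inlet Dirichlet condition is imposed
weakly by a multiplier field μ in the inlet velocity trace space, with
its own adjoint field ζ and the scalar condition ∫_{Γin} v_in·ζ = 0.

### One-shot solve and Picard lagging

The whole system is assembled as one sparse block matrix and solved
monolithically.  Two products of unknowns make it mildly nonlinear:
R_i·(outlet flux) in the multiplier state equation and t_i·(outlet
flux) in the control equation.  Both are bilinearised by lagging the
flux at the previous iterate Q̂^(m):

    λ_i − Q̂_i^(m) R_i = 0,        Q̂_i^(m) t_i = 0,

(the latter forces t = 0, which is exact at the optimum since Q̂_i ≠ 0),
with R^(m) frozen in the adjoint momentum term (inactive at t = 0).
Iteration: start from Ohm's-law resistances on the measurements,
re-solve, update Q̂, stop when successive R iterates change by less
than 1e-8 relative (max 50 iterations; 2–10 are typical).  Negative
intermediate or final resistances are not constrained, only flagged.

### Discretisation and linear algebra

Optimise-then-discretise with Taylor–Hood elements: continuous P2
vector velocity / P1 pressure on simplices (triangles or tetrahedra);
control and multiplier blocks are global scalars.  Volume integrals use
degree-2 simplex rules (exact for every assembled volume integrand),
facet integrals degree-4/5 rules (exact for the P2 trace mass); all
rules are unit-tested against the closed-form integrals of barycentric
monomials.  The plug inlet is imposed strongly with wall no-slip taking
precedence on the rim; the interpolant's lost rim flux is restored by
rescaling the free inlet dofs so the discrete inlet flux equals Q_in
exactly — this is what makes discrete mass conservation and synthetic-
data consistency sharp rather than O(h).

The monolithic system is solved by sparse LU (SuperLU).  Raw CGS units
leave the one-shot matrix near-singular — the constant-pressure mode
has curvature α_p/p_d² ≈ 1e-11 against O(1) constraint entries — so the
solve applies a physical block scaling (pressures in units of p_d,
flows in units of Q_in, adjoint blocks by α/(νQ_in) and α/Q_in)
followed by row max-norm equilibration; residuals then sit at ~1e-12.

Convergence diagnostics re-assemble the system with the *true* (not
lagged) products and report backward-error-style residual norms per
equation block, plus the dimensionless control gradient
dJ/d(log R_i) = −R_i t_i Q̂_i; the raw adjoint gradient dJ/dR_i =
−t_i Q̂_i is verified against central finite differences (agreement
~1e-10 relative on the tube fixture).

## 0D calibrators

* Mean arterial pressure: MAP = (P_sys + 2 P_diast)/3; mmHg→CGS with
  the fixed constant 1333.22 dyn·cm⁻²/mmHg.
* Murray's law: R_tot = p_d/Q_0 split as R_i = (Σ_j s_j/s_i) R_tot with
  s_i = Γ_i^(n/2) (areas for the conventional arch exponent n = 2); the
  parallel combination equals R_tot identically.
* Ohm's law: R_i = p_d/Q_i.
* Optimised Ohm: Nelder–Mead on J_ohm(R) = α_p(R_tot Q_0 − p_d)²/p_d² +
  Σ α_i(p_d/R_i − Q_i)²/Q_i², started at Ohm's law (relative
  tolerances 1e-10, ≤1e4 evaluations).  Published optimised values show
  loose convergence, so tests assert objective dominance, not point
  equality.
* Resistor junction: Q_i = Q_0 g_i/Σg_j, p = Q_0/Σg_j, g = 1/R.
* Windkessel splitting: R_p = 0.09 R, R_d = 0.91 R, total compliance
  0.001 cm⁵/dyn split proportionally to outlet area, distal pressure 0.

## Windkessel surrogate

The unsteady validation step replaces the 3D domain by a zero-resistance
junction feeding three-element Windkessel branches — a linear DAE
integrated with backward Euler (dt = T/1000 by default, dt ≤ T/200
enforced), the junction pressure solved simultaneously with the
capacitor states from one small constant-matrix system per step.
Because the network is linear and time-invariant, the capacitor states
are initialised on the exact periodic orbit computed harmonic by
harmonic from the waveform's Fourier coefficients; the customary five
simulated cycles then satisfy the periodic-convergence criterion with
large margin, and last-cycle mean flows match the pure-resistor split
of the mean inflow to ~1e-5 (averaging the capacitor ODE over a period
annihilates the compliance term).  An explicit initial-state argument
exposes the transient (time constant R_d·C) when needed.  Patient inlet
waveforms are not distributed; a truncated half-sine "physiological"
waveform generator with exact cycle mean stands in, so waveform-level
comparisons are property-based.

## WSS postprocessing

WSS vectors are the tangential part of the viscous traction
ν(∇v + ∇vᵀ)n evaluated per wall facet at the centroid from the adjacent
cell's P2 gradient.  TAWSS is the trapezoidal time average of |τ| over
one cycle; OSI = ½(1 − |∫τ dt|/∫|τ| dt), clipped to [0, 0.5] and masked
where ∫|τ| dt = 0.  Method comparisons use ε_r = |field − ref|/max(ref)
with the global maximum of the reference field as denominator.

## Synthetic data and what the fixtures do (not) show

`make_synthetic_case` forward-solves with known resistances, records
the section pressure as p_d and the outlet fluxes as measured flows,
then rescales all outlet flows uniformly so the stored net flow equals
a prescribed fraction (≤15%) of the inlet flow — the inlet kept exact,
matching how net flow is reported against the inlet measurement.
Optional per-outlet multiplicative jitter is seeded and off by default.
Fixture geometry: structured 2D channel / 3D disk-sectioned tube
(boundary vertices exactly on the circle; prisms split into tetrahedra
by the smallest-vertex-index rule for conformity) and a planar
transfinite multi-outlet manifold whose distal edge carries 2–6 outlet
segments separated by wall gaps.  The four-outlet default (radii 0.4,
0.25, 0.3, 0.8 cm, trunk 1.0 cm, edge length 0.1 cm → ~3100 triangles)
with truth resistances 7000/21000/16000/1700 dyn·s/cm⁵ and inlet flow
119.1 cm³/s mimics the flow fractions of an adult aortic arch (BCA,
LCC, LSUB, DAo).

Because measurements are generated by the same discretisation that the
estimator constrains, recovery on consistent data is essentially exact
(inverse-crime setting): passing tests demonstrate the correctness of
the optimality system and solver, not robustness to model error.  The
13%-violation cases probe the estimator's behaviour under genuinely
inconsistent data, where no model could fit; the observed error split
(dominant outlet absorbs the inconsistency; with inlet control the
recovered inlet drops ~9% and errors redistribute in proportion to the
flow fractions) follows the constrained least-squares prediction and
matches the published patient-data pattern qualitatively.  Real 4D-Flow
noise structure, segmentation error and unsteadiness are out of scope.

Problem sizes were chosen for interactive turnaround: 2D fixtures with
~1.5k–13k triangles (one-shot solves in seconds), a single coarse 3D
tube for the dimension-generic checks.

## Known limitations

* Steady Stokes only; no unsteady 3D solves, turbulence, non-Newtonian
  rheology or compliant walls.
* One scalar resistance per outlet; no per-branch compliance estimation.
* Average flow rates only; full waveforms cannot be assimilated.
* The planar arch fixture is a topological, not anatomical, analogue.
* Mesh I/O is Gmsh MSH 2.2 ASCII and ASCII VTU (vertex data); no
  HDF5-backed formats.
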