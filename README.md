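# vasocal

Automated calibration of resistance-type outlet boundary conditions for
patient-specific vascular flow simulations.

## The problem

Computational haemodynamics models of a vessel segment (e.g. the aortic
arch and its supra-aortic branches) truncate the rest of the circulation
into boundary conditions: a measured inflow at the inlet and, at each
outlet `Γ_i`, a resistive condition

```
p = R_i ∫_{Γ_i} v·n dΓ      on Γ_i,
```

which represents the downstream vascular bed as a lumped resistance
`R_i` (dyn·s/cm⁵).  Choosing the `R_i` to match non-invasive patient
data — a cuff mean arterial pressure `p_d` and 4D-Flow-MRI mean flow
rates `Q_in`, `Q_i` — is usually done by manual tuning.  `vasocal`
automates it by solving an **optimal control problem**: the `R_i` are
control variables, the constraint is the steady incompressible Stokes
system with multiplier-imposed resistive outlets, and the cost is the
normalised data mismatch

```
J = α_p/2 · ∫_{Γ_p}(p − p_d)² dΓ / ∫_{Γ_p} p_d² dΓ
  + Σ_i α_i/2 · (∫_{Γ_i} v·n dΓ − Q_i)² / Q_i².
```

Writing the Lagrangian with adjoint variables (z, b, t) and auxiliary
outlet fluxes `k_i = ∫_{Γ_i} v·n` and requiring ∇L = 0 yields a coupled
optimality system (state + adjoint + controls), which is discretised
with Taylor–Hood (P2/P1) finite elements and solved *in one shot* as a
single sparse system, with a short Picard iteration resolving the two
bilinear products.  An extension treats the inlet flow as uncertain
too, through a scalar control `u_in` on the inlet velocity profile
(`v = u_in·v_in`), with the inlet condition imposed weakly by a
Lagrange multiplier field.

For comparison and validation the package also implements the two
standard 0D calibrators — Murray's law (`R_i = Σ_j Γ_j / Γ_i · p_d/Q_0`)
and Ohm's law (`R_i = p_d/Q_i`, optionally refined by a derivative-free
simplex minimisation of the 0D analogue of J) — a pure-resistor
junction network, an unsteady three-element Windkessel (RCR) network
surrogate for pulsatile validation, and wall-shear-stress
postprocessing (WSS vectors, TAWSS, OSI, relative-difference maps).

Everything runs from parametric fixtures (straight tubes in 2D/3D, a
planar multi-outlet arch-like manifold) with synthetic measurement
generation, including a controlled mass-conservation violation
emulating the net-flow inconsistency of real 4D-Flow MRI data; no
external mesher or download is required.  Units are CGS throughout
(1 mmHg = 1333.22 dyn/cm²).

## Worked example

Calibrate a four-outlet arch-like fixture whose synthetic measurements
carry a 13% net-flow violation, with the inlet flow also controlled:

```python
import vasocal as vc

mesh = vc.make_branching_mesh([0.4, 0.25, 0.3, 0.8], trunk_radius=1.0,
                              target_edge_length=0.1)
R_true = vc.ResistanceSet([7000.0, 21000.0, 16000.0, 1700.0])
meas = vc.make_synthetic_case(mesh, R_true, Q_in=119.1,
                              violation_fraction=0.13)
fit = vc.solve_ocp(mesh, meas, control_inlet=True)
print(fit.summary())
```

```
Resistance estimation (adjoint optimal control, steady Stokes)
================================================================
outlets: 4   inlet control: True   Picard iterations: 3   converged: True
J = 6.042039e-03
pressure: target   106.21 mmHg   assimilated   106.21 mmHg (-0.0%)
inlet flow: measured   119.10 cm3/s   recovered   108.03 cm3/s (u_in = 0.9070)
----------------------------------------------------------------
outlet    R (dyn.s/cm5)     Q meas      Q fit    err %
    11           7937.1     17.596     17.838     1.37
    12          24028.2      5.866      5.893     0.46
    13          18281.2      7.699      7.745     0.60
    14           1849.5     72.456     76.553     5.65
```

The pressure target is met exactly; because the measured flows are
mutually inconsistent (13% of the inlet flow is missing from the outlet
measurements) a perfect fit is impossible, so the estimator lowers the
recovered inlet flow by ~9% (`u_in = 0.907`) and leaves small residual
errors, the largest on the dominant outlet.  Without `control_inlet`
the whole inconsistency is absorbed by the dominant outlet instead
(~20% error there, <5% elsewhere).  With mass-consistent measurements
(`violation_fraction=0`) the true resistances are recovered to well
below 1%.

A command-line interface mirrors the library:

```sh
vasocal make-fixture --kind branching --out arch.msh
vasocal estimate-ocp --case case.yaml --out result.json
vasocal network-forward --resistances 6837,21242,17591,1527 --q0 119.1 --out split.json
vasocal simulate-rcr --waveform wf.csv --branches rcr.json --cycles 5 --out means.json
```

## Layout

- `vasocal.meshing` — tagged parametric vessel meshes (tube 2D/3D, arch)
- `vasocal.fem` — Taylor–Hood P2/P1 assembly core
- `vasocal.stokes` — forward Stokes solver with resistive outlets
- `vasocal.estimator` — `ResistanceEstimator` / `ResistanceEstimationResults`
  (the one-shot adjoint optimal-control solver)
- `vasocal.lumped` — MAP, Murray, Ohm, 0D optimisation, RCR splitting
- `vasocal.windkessel` — junction-coupled Windkessel network surrogate
- `vasocal.wss` — WSS / TAWSS / OSI / relative-difference maps
- `vasocal.synthetic` — synthetic measurement generation
- `vasocal.io`, `vasocal.cli` — formats (MSH 2.2, VTU, YAML/JSON/CSV) and CLI

See `docs/methods.md` for the mathematical formulation, numerical
choices and limitations.
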