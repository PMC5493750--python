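# lanesim

Simulation, analysis and theory of **laning versus mingling in binary
mixtures of oppositely driven self-propelled particles**.

Push two crowds through each other and they usually refuse to mix: they
spontaneously organize into counter-propagating lanes. This package
implements a minimal active-matter model of that phenomenon — N
overdamped self-propelled particles, half driven toward +x and half
toward −x by a harmonic angular drive of strength H, interacting *only*
through pairwise repulsive torques of amplitude B — and the full analysis
stack around it:

- **Simulator** (`lanesim.dynamics`): forward-Euler integration of

  ```
  dr_i/dt = v0 p̂(θ_i)
  dθ_i/dt = −H sin(θ_i − Θ_i) − Σ_j B(r_ij) sin(θ_i − φ_ij)
  B(r)    = B (1 − r/(a_i + a_j))   for r < a_i + a_j, else 0
  ```

  in a periodic rectangle, with a sweep-and-prune neighbour search that
  is exactly equivalent to an all-pairs scan.
- **Observables** (`lanesim.observables`): the orientational order
  parameter W = ⟨sin²(θ_i − Θ_i)⟩ (zero in lanes, finite in the mingled
  liquid), its fluctuations and correlation time, density-difference
  fields with a lane/mingled classifier, orientational diffusivity ν_R,
  species-resolved pair correlations g_αβ(x, y), and scaling-collapse
  scoring.
- **Criticality** (`lanesim.criticality`): B-sweeps at fixed density and
  a validated estimator of the critical point B_c and the exponents β
  (order parameter), γ (fluctuations) and zν (correlation time).
- **Two-body scattering** (`lanesim.scattering`): deterministic
  collision experiments y_out(y_in; B), plus bound pairs that lock
  together and self-propel transverse to both drives.
- **Fluctuating hydrodynamics** (`lanesim.hydro`): kinetic-theory
  estimates of the coefficients of the linearized two-species density
  equations, the closed-form density-fluctuation spectrum

  ```
  S(q) = n_q (D_q² + v²q_x²) / [2 D_q (D_q² − D̃_q² + (v²−c²) q_x²)]
  ```

  which is non-analytic at q = 0 whenever the cross-species coupling
  current is on (different limits a ≠ b along and across the drive), its
  real-space consequence — pair correlations decaying as the universal
  x^(−3/2) law with transverse profiles collapsing in y/x^(1/2) — and a
  pseudo-spectral stochastic-field integrator with conserved noise that
  cross-checks the closed form mode by mode.

## Worked example

```python
import lanesim as ls
from lanesim.observables import delta_rho_samples

for B in (2.0, 5.0):
    params = ls.ModelParams.for_area_fraction(B, N=500, area_fraction=0.65)
    state = ls.init_random(500, params, seed=1)
    res = ls.simulate(state, params, steps=80_000, sample_every=2_000,
                      snapshot_every=8_000)
    fields, _ = delta_rho_samples(res.snapshots[-6:], params)
    label = ls.laning_classifier(fields).label
    print(B, round(res.W[len(res.W)//2:].mean(), 3), label)
```

prints

```
2.0 0.019 lane
5.0 0.235 mingled
```

At B = 2 the order parameter ⟨W⟩ ≈ 0.02 is at its finite-size floor —
every particle follows its preferred direction — and the
density-difference histogram is strongly bimodal: counter-propagating
lanes. At B = 5 repulsion wins, the populations stay mixed, ⟨W⟩ ≈ 0.2 and
the density fluctuations are Gaussian. The `examples/` directory has one
short narrative script per capability (phases, scattering, critical fit,
structure-factor theory, stochastic-field cross-check).

A thin command-line interface mirrors the library:

```bash
lanesim simulate --config run.yaml --out traj.xyz
lanesim analyze --traj traj.xyz --config run.yaml --what W,drho --out out/
lanesim sweep --B 2.6:4.2:0.2 --phi 1.1 --n 986 --out sweep/
lanesim fit-critical --sweep sweep/
lanesim scatter --B 2,3,5 --yin 0:1:0.025 --out deflection.csv
lanesim theory --params hydro.json --out theory/
```

Trajectories are extended-XYZ (species, x, y, θ in radians, radius per
row; time, box and parameters in the frame comment); every command writes
a `manifest.json` from which its outputs can be regenerated exactly.

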