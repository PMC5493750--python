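# Methods

## The microscopic model

`lanesim` simulates N overdamped self-propelled particles in a periodic
rectangle (aspect Lx = 2Ly elongated along the drive). Particle i carries a
position r_i, an orientation θ_i, a species label (right movers prefer
Θ = 0, left movers Θ = π; the two populations have equal size), and an
interaction radius a_i alternating between 1 and 1.4 to frustrate
crystallization. The dynamics acts on angles only:

    dr_i/dt = v0 p̂(θ_i),                         p̂(θ) = (cos θ, sin θ)
    dθ_i/dt = −H sin(θ_i − Θ_i) + Σ_j T_ij
    T_ij    = −B(r_ij) sin(θ_i − φ_ij),           φ_ij = arg(r_i − r_j)
    B(r)    = B (1 − r/(a_i + a_j))  for r < a_i + a_j, else 0

The pair torque derives from the angular energy U_ij = −B(r_ij) cos(θ_i −
φ_ij): interacting particles rotate toward pointing away from each other
("turning their backs"), with a kernel that decays linearly to zero at the
interaction range. There are no positional forces: every particle moves at
exactly v0 at all times, so all transport beyond ballistic streaming is
collision-generated. These functional forms are the single torque seam in
`dynamics.py`; everything else (kernels, the two-body integrator, the
kinetic theory) is required to match them.

Parameters and units: lengths in units of the small interaction radius,
time in units of it divided by the self-propulsion speed. Defaults H = 1
and v0 = 1, leaving the repulsion amplitude B and the density as the two
control parameters. Density is quoted both as number density ρ̄ = N/(LxLy)
and as interaction-disk area fraction φ̄ = π Σ a_i² /(LxLy) (= 4.65·ρ̄ for
the bidisperse mixture); both conventions appear in the literature on this
model class and the package always reports both.

Integration is forward Euler with dt = 1e−2 (two-body scattering uses
1e−3; the deflection curves are verified stable to <1% under dt halving).
Positions advance along the pre-step orientation and angles take the
torques of the pre-step configuration. Exactly coincident particles make
the centre-to-centre angle undefined; because the model has no excluded
volume to prevent this (and it is measure-zero under random initial
conditions), the integrator aborts with a `DegeneratePairError` rather
than regularizing.

Neighbour search is a sweep-and-prune broad phase: an insertion-sorted
x-order (nearly sorted between steps, so the re-sort is O(N)) is scanned
with a per-pair window a_i + a_j, then pruned by the transverse separation
and the exact minimum-image distance. Boxes narrower than twice the
largest pruning window fall back to an all-pairs scan to avoid wrap
double-counting. The production path is tested for exact pair-set equality
against the brute-force scan on random configurations up to N = 1000.

Reproducibility: one integer seed drives every stochastic operation
through `numpy.random.default_rng`; sweep runs derive child seeds from the
(seed, B-value bits, replicate) triple, so results are invariant under
reordering of the B list.

## Observables

**Order parameter.** W = ⟨sin²(θ_i − Θ_i)⟩_N. It vanishes iff every
particle points exactly along its preferred direction, is bounded by 1,
and is invariant under exchanging the species while rotating all
orientations by π. In the lane phase W averages to a small finite-size
floor (interface particles); in the mingled liquid it is O(0.2). Its
connected fluctuations in the disordered phase plateau at O(1/N), which
`w_fluctuations` subtracts using a large-B reference plateau.

**Correlation time.** τ_W integrates the normalized, mean-subtracted
autocorrelation with a self-consistent (Sokal) window: the first lag M ≥
5 τ(M). This truncates an exponential tail at the sub-percent level while
excluding the noise accumulated past the decay; on synthetic
exponentially correlated series it recovers the time scale within 10%. A
series whose autocorrelation neither reaches the window condition nor
crosses zero raises `NonStationaryError`.

**Density fields and the lane classifier.** Per-species counts on bins of
9.6 length units (four mean interaction ranges) give the density
difference Δρ with many particles per bin, so its histogram probes the
distribution shape rather than shot noise. The classifier fits one- and
two-component Gaussian mixtures to the pooled standardized Δρ values and
labels the state "lane" when BIC prefers two components *and* the peak
separation exceeds the mean component width; this operationalizes
"strongly bimodal" versus "Gaussian" fluctuations with a deterministic
rule (fixed mixture initialisation at ±1 standard score). The coarse bin
is load-bearing: at scales of only a few interaction ranges the mingled
liquid's genuine lane-precursor density correlations (the same physics
as its algebraic pair correlations) read as weak bimodality, so finer
bins misclassify the liquid. The lane state's narrow early lanes
conversely need a few hundred time units of coarsening before they are
bimodal at the coarse scale — classification runs use t ≈ 10³ at the
reference size. The D'Agostino–Pearson Gaussianity check on the mingled
state uses the same 9.6-unit bins. One more scale caveat: lane width
grows with the drive, so very weakly driven states form slender lanes
that a 9.6-unit bin averages away — classifying those requires a finer
`bin_size` matched to the expected width (exposed as a parameter on the
classifier helpers and `phase_diagram`).

**Orientational diffusivity.** ν_R is the early-time decay rate of the
connected orientation autocorrelation (⟨cos Δθ⟩ with the stationary
resultant m² = |⟨e^{iθ}⟩|² subtracted and renormalized), fitted
exponentially down to C = 0.6. Exactly frozen orientations return 0; when
the fluctuations are too narrow to define a decay (1 − m² < 0.05, the
lane phase) the measurement raises `LaneStateError` — it is undefined
there, matching the phenomenology that only the mingled liquid has
exponentially decorrelating orientations. In the mingled state at B = 5,
ν_R grows linearly with density with an intercept consistent with zero:
binary collisions set the orientational noise.

**Pair correlations.** Species-resolved g_αβ(x, y) on square bins
(default 0.5) from minimum-image displacements, normalized so a uniform
ideal gas gives 1 (verified on Poisson configurations and by a
hand-computed two-particle normalization). g_rl(x,y) = g_lr(−x,−y) holds
exactly by construction; g_rr ≈ g_ll within noise is a physical symmetry.
`scaling_collapse` rescales x-slices as (g−1)·x^{3/2} against y/x^{1/2}
and scores the collapse by the across-slice rms spread relative to the
master curve's rms; the estimator is validated on synthetic grids built
exactly as A·x^{−3/2} f(y/x^{1/2}) (spread at the interpolation floor)
and rejects null rescalings.

## Critical analysis

`run_sweep` relaxes each (B, replicate) run for a burn-in (default half
the total budget at desk scale) and measures W every 0.5 time units;
means, connected variances and τ_W carry batch-means standard errors.
`fit_critical` then:

1. estimates the ordered-phase noise floor from the lowest-B fifth of the
   sweep and subtracts it from ⟨W⟩ in quadrature;
2. finds the onset as the last B below which the signal is insignificant
   — a point counts as significant only when it clears the floor both
   statistically (2 s.e.) and by a factor of two, the factor guarding
   against the slow pre-critical drift of the finite-size floor that
   per-point error bars underestimate — then scans candidate B_c values
   on a fine grid below the onset, fitting log W vs log(B − B_c) with
   inverse log-variance weights and keeping the candidate with the
   smallest reduced residual (β is that slope);
3. fits γ and zν from the plateau-subtracted variance and from τ_W above
   B_c, in the same weighted log–log way (the variance plateau must come
   from a separate large-B reference — estimating it from the top of the
   sweep leaks the critical contribution into the subtraction and biases
   γ);
4. propagates one-s.d. errors by a parametric bootstrap (64 draws from
   the per-point errors, refitting everything including the floor).

The estimator is validated by parameter recovery: on synthetic sweeps
with known (B_c, β, γ, zν) and realistic noise (1% absolute on ⟨W⟩, 8%
relative on the variance and τ), all four parameters land within 2
reported s.d. in ≥18/20 seeded trials.

Scale note. The published critical point B_c ≈ 2.2 for this model class
belongs to boxes of Lx = 336 with N ≈ 5,500–7,900 and run lengths of many
correlation times — cluster-scale work. At the desk scale this package
targets (N ≈ 10³, runs of a few hundred time units), the lane state is
stabilized by the small transverse box and the transition sits higher, at
B ≈ 3.3–4 depending on density (and is further sensitive to the exact
angular-potential conventions, which shift the torque-balance scale by
O(1) factors). The package therefore demonstrates criticality at desk
scale via (i) the synthetic-recovery property of the estimator and (ii) a
coarse sweep over B ∈ [2.6, 4.2] at φ̄ = 1.1 that brackets the desk-scale
transition; sweeps at the published parameters are available through the
same API for cluster use.

## Two-body scattering

The Fig-3-style experiment places a right mover (θ_r = 0) at +y_in and a
left mover (θ_l = π − π/10, the tilt breaking the perfect head-on
symmetry) at −y_in in the unbounded plane, with the longitudinal offset
chosen so the pair sits exactly at contact at t = 0 (drive and torque act
from that moment). y_out is the signed asymptotic transverse position of
the right mover relative to the contact point (the pair midpoint at
t = 0), frozen once the separation exceeds twice the interaction range
and the drive has realigned the right mover to within 1e−3 rad.

Bound pairs: the pair torque can balance the drive whenever the kernel
B(r) ≥ H, giving configurations with both particles pointing along ±ŷ
that translate at exactly v0 transverse to both drives. The detector
declares a pair bound when the separation never exceeds the interaction
range while the pair centre travels 20 interaction ranges transversely —
long enough to exclude transient orbiting. In this reconstruction the
bound manifold is dynamically stable (launches perturbed by 0.01 rad stay
locked indefinitely) but is not entered from the contact-start deflection
grid; escaping near-bound orbits still carry particles many interaction
ranges sideways, which is the mechanism that makes collision-induced
transverse displacements unbounded by the torque range.

## Linearized fluctuating hydrodynamics

Deep in the mingled phase the only hydrodynamic variables are the two
conserved densities. Writing δρ_α for their fluctuations (α = R, L with
drive directions ±x̂):

    ∂t δρ_R = −v ∂x δρ_R + ∇·(D ∇δρ_R) + c ∂x δρ_L + ∇·(D̃ ∇δρ_L) + ∇·ξ_R
    ∂t δρ_L = +v ∂x δρ_L + ∇·(D ∇δρ_L) − c ∂x δρ_R + ∇·(D̃ ∇δρ_R) + ∇·ξ_L

with diagonal anisotropic tensors D = diag(Dx, Dy), D̃ = diag(D̃x, D̃y).
The coupling current has two microscopic origins: collisions with the
opposing stream suppress the longitudinal advection (coefficient c — the
denser the partners, the slower the drift) and a repulsion-induced
pressure drives a flux down the partner's density gradient (D̃). The
noise is conserved by construction — the divergence of a white vector
noise of variance 2Tx, 2Ty per component — so the q = 0 mass mode of each
species is strictly fixed.

**Kinetic-theory coefficient estimates.** `kinetic_coefficients` maps
microscopic parameters to this coefficient set under the simplified
strong-repulsion scattering rule (a collision realigns a particle along
the centre-to-centre axis regardless of incoming angles, valid for
B > 1; lower B raises `ClosureValidityError`): collision rate λ =
2 v0 b̄ ρ_partner (b̄ = 2.4 the mean interaction range), which is also the
collision-induced rotational diffusivity; a wrapped-Gaussian closure for
the orientational fluctuations with variance σ² = (π²/3)·λ/(λ + 2H)
balancing collisional randomization against the drive, giving the mean
drift v = v0 e^{−σ²/2}; adiabatic elimination of the fast velocity field
(relaxation rate γ = H + λ) turning orientational velocity fluctuations
into D (longitudinal from the cos θ variance, transverse from σ²); c from
differentiating the drift with respect to the partner density; and D̃ =
λ b̄²/8 from the per-collision transverse displacement. These are
order-of-magnitude estimates — the exact coefficient algebra is outside
this package's scope — and every claim tested downstream (exponents,
limits, conservation, stability) is deliberately coefficient-robust. All
rates are linear in the partner density and vanish with it, recovering
free advection–relaxation at zero density.

**Closed-form structure factor.** Solving the stationary 2×2 Lyapunov
problem per wavevector (derived symbolically, cross-checked in the tests
against an independent per-mode Lyapunov solve) gives

    S_auto(q) = n_q (D_q² + v² q_x²) / [ 2 D_q (D_q² − D̃_q² + (v² − c²) q_x²) ]

with D_q = Dx q_x² + Dy q_y², D̃_q likewise, n_q = 2(Tx q_x² + Ty q_y²),
and a similar expression (complex, odd imaginary part) for the cross
spectrum. Positivity of the denominator is exactly the linear-stability
condition; `structure_factor` raises `StabilityError` naming the
offending modes otherwise (the kinetic estimates are hydrodynamic:
long-wavelength grids, q ≲ 1/b̄). Approaching q = 0 along the drive axis
gives a = Tx v²/(Dx (v² − c²)); along the transverse axis, b =
Ty Dy/(Dy² − D̃y²). With the coupling off and isotropic self-diffusion
the two coincide and the spectrum is constant (analytic — no structure);
any nonzero coupling makes a ≠ b and the spectrum non-analytic at q = 0.

In the self-similar wedge q_x ∼ q_y² the spectrum is a function of
u = q_x/q_y² alone, which Fourier-transforms into C(x, 0) ∝ x^{−3/2} with
transverse profiles in y/x^{1/2} — the same universal structure seen in
the particle-level pair correlations of the mingled liquid. The spectrum
also has a scale-free ray limit S_ray(q) = n_q v²/(2 D_q (v² − c²)) —
constant along every ray but angularly varying when the diffusion or
noise is anisotropic; its transform decays faster asymptotically but can
dominate numerically accessible distances, so
`realspace_correlations(..., subtract_ray_limit=True)` removes it exactly
before transforming when the clean jump-induced tail is wanted (this is
how the noise-anisotropy robustness of the exponent is tested).

**Numerics of the inverse transform.** Spectra are evaluated on grids of
4096×1024 modes (box 1433.6 × 358.4, spacing 0.35) for exponent work; a
fixed raised-cosine taper from 70% of the Nyquist edge suppresses
ringing; the q = 0 mode is pinned to zero (global mass fixed). The
longitudinal decay exponent is fitted on log |C(x,0)| over x ∈ [20, 200]
— a decade that starts past the crossover from the analytic core (local
slopes reach −1.5 around x ≈ 40 for O(1) coefficients) and ends before
periodic wrap-around images contribute at the percent level. Collapse
slices are taken at x ∈ {12, 20, 32, 50}. Random-coefficient robustness
draws (`random_stable_params`) use isotropic self-diffusion and require
the jump amplitude |a − b| ≥ 0.15 max(a, b): below that the tail cannot
be resolved above the competing contributions on any desk-size grid.

**Stochastic-field integrator.** `spde_integrate` evolves each Fourier
mode's 2×2 linear system with Hermitian-symmetric spectral noise (the
real-space fields stay real) and exactly zero forcing at q = 0. The
default scheme is the exact Gaussian propagator: M = e^{A dt} and the
exact noise covariance Q = ∫₀^dt e^{As} N e^{A†s} ds built from the
eigendecomposition of A (only decaying exponentials appear, so stiff
high-q modes are computed stably), which makes the stationary law of the
discrete chain exactly the continuum one at any dt. A semi-implicit
Euler–Maruyama variant is available for reference; it is unconditionally
stable but biases the stationary spectrum by O(dt·ω²/γ) on weakly damped
advective modes, which is why it is not the default for quantitative
spectra. Mode spectra are accumulated after a 20% burn-in with
batch-means standard errors (32 batches).

A statistical note on "every mode" comparisons: with ~2×10³ independent
modes on a 64×64 grid, a correct, unbiased integrator is still *expected*
to show ~0.5% of modes beyond 3 standard errors (that is what standard
errors mean), so the library's own consistency tests assert a calibrated
bound (≥97% of modes within 3 s.e., max |z| < 6, mean spectrum ratio
within 2–3%) rather than a zero-exceedance rule that no correct sampler
could pass.

## What the synthetic generators emulate

`synthetic.py` generates the ground-truth inputs the estimators are
validated on: exact discrete Ornstein–Uhlenbeck series (correlation-time
recovery), free angular random walks (rotational-diffusivity recovery),
power-law correlation grids with a Gaussian master profile (collapse
scoring), and critical sweeps with the stated power laws plus Gaussian
noise at levels matching desk-scale simulation error bars
(`criticality.synthetic_sweep`). They deliberately omit features of real
simulation data — fat-tailed fluctuation statistics near B_c, slow
coarsening transients, interface pinning in small boxes — so estimator
tests passing on them demonstrates correctness of the estimators, not
that desk-scale runs reach the asymptotic critical regime (they do not;
see the scale note above).

## Known limitations

- The desk-scale critical point is finite-size shifted (B ≈ 3.3–4 versus
  ≈ 2.2 in large-box studies); quantitative exponent reproduction needs
  cluster-scale sweeps (N ≈ 5–8×10³, ≥ 50 τ_W per point), which the same
  API supports but the test suite does not attempt.
- The two-body deflection grid with the standard contact-start initial
  conditions does not enter the bound-pair basin in this parameterization;
  bound pairs are demonstrated from near-balance launches instead.
- Hydrodynamic coefficients are closure-grade estimates; only
  coefficient-robust statements (exponents, limits, conservation,
  stability boundaries) should be read quantitatively.
- The structure factor is derived for the linearized equations;
  nonlinear hydrodynamics, and any prediction of the transition line from
  the theory, are out of scope.
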