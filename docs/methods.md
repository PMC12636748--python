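# Methods

`airprint` simulates embedded printing of air into yield-stress support
baths and quantifies the outcome. The model couples three ingredients:
a regularized Herschel–Bulkley constitutive law for the bath, a
Cahn–Hilliard diffuse interface carrying the air/gel boundary, and an
incompressible variable-viscosity momentum balance with a
surface-tension body force and a Brinkman-penalized moving nozzle. This
note records the model, the numerical scheme, the parameters that
matter, and the limits of what the desk-scale 2D simulations can and
cannot show.

## Rheology

The bath is a Herschel–Bulkley (HB) fluid, τ = τ_y + K·γ̇ⁿ above yield.
For use in a flow solver the law is regularized in the Papanastasiou
form

    μ(γ̇) = K γ̇ⁿ⁻¹ + τ_y (1 − e^(−m γ̇)) / γ̇,

with regularization time scale `m_reg` (default 1000 s), which replaces
the unyielded solid by a very viscous fluid with zero-shear plateau
≈ τ_y·m_reg. The plateau is additionally capped (`mu_max`, default
10⁶ Pa·s; the flow solver uses a lower working cap, see below) because
the power-law term diverges at γ̇ → 0 for n < 1. Stress is monotone in
γ̇ for every admissible parameter set and converges to the ideal HB law
as m_reg → ∞; both are property-tested.

Flow curves are fitted to the ideal law by least squares on log stress
(decades weighted evenly); `m_reg` is not identifiable from rheometry
and is carried through unchanged.

The two-pass gel-tearing test is summarized by the plateau mean of the
final 50 % of each pass's torque trace; recovery (%) is the second-pass
plateau over the first. The plateau mean was chosen over the peak force
because it is robust to start-up transients; this estimator choice is a
genuinely open design point.

The plastocapillary number Y = τ_y·R/σ compares the yield stress with
the capillary pressure of a channel of radius R (radius, not diameter —
another open convention, chosen once). The regime taxonomy is: M3 if
recovery < 80 % (the gel tears and does not heal), otherwise M2
(channel-stable) if Y ≥ Y_crit and M1 (bubble-forming) below. Y_crit
defaults to 0.1, an order-of-magnitude plastocapillary threshold; it is
exposed in configuration because no measured value exists for it.

The built-in materials catalog (M1, M1A–M1D, M2, M3) contains
*representative* gelatin/silicone-like parameter sets chosen to realize
the three regimes at the package's default printing radius; they are
not measured data.

## Phase field

The air/gel order parameter ϕ ∈ [−1, 1] (+1 = air) obeys the advective
Cahn–Hilliard system

    ∂ϕ/∂t + u·∇ϕ = ∇·(M ∇ψ),   ψ = −∇·(ε² ∇ϕ) + (ϕ² − 1)ϕ,

with capillary width ε (default 2·dx; at least 1.5·dx is enforced) and
mixing energy density λ = (3/√8)·σ·ε, the sharp-interface calibration
that makes the integrated interface energy equal the physical surface
tension σ. Both are validated numerically: the relaxed 1D profile is
tanh(x/(√2 ε)) to within 2 % in width, and the discrete free energy per
unit interface length reproduces σ to well under 5 %.

The mobility is parameterized as M = chi_mob·λ (m²/s for chi_mob in
m·s/kg). chi_mob is a numerical parameter: large enough that the
interface stays near its equilibrium profile under advection
(interface Péclet of order one), small enough that Cahn–Hilliard
coarsening does not erode printed features on the simulated time scale.
The print scenarios use chi_mob = 0.5; the library default is 1.

Discretization: 5-point finite-difference Laplacian; one semi-implicit
(stabilized Eyre-type, S = 2) step per time step solved in transform
space — DFT on periodic axes, DCT-II on no-flux axes; the transform
symbols are exactly the eigenvalues of the FD Laplacian under the
respective boundary conditions, so the zero mode is untouched and the
mean of ϕ is conserved to round-off. Advection uses a conservative van
Leer-limited upwind flux (zero boundary fluxes on no-flux axes), so
conservation survives coupling to flow.

Bound handling: ϕ is never clamped inside `volume_fractions`' callers;
the evolution itself applies a mass-conserving redistribution only when
an excursion exceeds |ϕ| > 1.03 (excess returned to the interface band,
Σϕ conserved exactly). Strongly driven prints otherwise exceed the
±1.05 state invariant through advective over/undershoot; the clip is a
no-op in every unforced benchmark.

## Hydrodynamics

Momentum balance (reference density ρ₀ = gel density):

    ρ₀ (∂u/∂t + u·∇u) = −∇p + ∇·(μ ∇u) + f_st + f_brinkman (+ buoyancy)

with mixture viscosity μ = f_air·μ_air + f_gel·μ_HB(γ̇) blended by the
phase volume fractions (1 ± ϕ)/2. Choices worth knowing:

* **Domain.** Fully periodic box; physical walls and containers are
  Brinkman-penalized stationary strips (consistent with the moving
  nozzle treatment). Velocity is cell-centered; the pressure projection
  is exact in spectral space, so there is no checkerboard mode and the
  divergence residual is round-off every step. Nyquist wavenumbers are
  zeroed in spectral differentiation (no consistent sign for real
  fields).
* **Implicit viscosity.** The viscous term is taken fully implicit with
  the true variable viscosity by a Douglas ADI splitting (batched cyclic
  tridiagonal solves, numba-accelerated with a pure-numpy fallback).
  Regularized yield-stress plateaus are 10³–10⁵ Pa·s next to air; any
  explicit or constant-coefficient-split treatment is either unstable at
  usable time steps or quasi-statically wrong. The Brinkman term is
  folded implicitly into the first sweep — applying it as a separate
  split step leaves an O(dt·K) slip at penalized boundaries (observed as
  a 2× error in the Poiseuille benchmark before the fix).
* **Stress form.** ∇·(2μD) is reduced to ∇·(μ∇u): the transpose part
  is dropped. This is exact wherever μ is uniform and for unidirectional
  flows — i.e. for every closed-form benchmark (Poiseuille, Bingham
  plug, Laplace) — and confines the O(∇μ) error to the diffuse
  interface. It is what makes the per-direction implicit treatment
  possible.
* **Surface tension.** The continuum surface force is applied in the
  gradient-equivalent form −(λ/ε²)ϕ∇ψ with the exact difference
  (λ/ε²)ϕψ added to the reported pressure (ψ∇ϕ = ∇(ϕψ) − ϕ∇ψ). In the
  bulk this form is a near-pure gradient and is removed by the
  projection, so grid-scale ϕ noise cannot pump momentum into the flow.
  With the textbook ψ∇ϕ form, bulk noise couples to shear-thinning
  (noise → large apparent γ̇ → viscosity collapse → no damping) and
  forms a self-sustaining local instability. For the same reason the
  shear rate that feeds the viscosity law is evaluated on 3-point
  box-filtered velocities, which annihilates the grid-Nyquist
  checkerboard; the public kinematics op is unfiltered.
* **Creeping flow.** Print scenarios default to the Stokes balance
  (inertia is available per job). The prints live at Re ≪ 1 in the gel;
  the air phase is given a numerical viscosity of 0.05 Pa·s in
  scenarios — still ≥10² softer than any sheared gel here — because an
  effectively inviscid phase carried at the reference density is
  numerically pathological and dynamically irrelevant in this regime.
  The working viscosity cap in scenarios is 10⁴ Pa·s, far above any
  sheared-gel value and high enough to arrest unyielded regions over
  the simulated times.
* **Stability.** Explicit pieces (advection when enabled, CSF) impose
  an advective CFL and the capillary time-step bound
  √(ρ₀h³/(4πσ)); scenario drivers adapt the step to transient speed
  spikes and re-check the phase-field CFL against the *new* velocity.

## Nozzle and air injection

The nozzle is a Brinkman-penalized moving mask: a disc for straight and
ball nozzles, a capsule of length 3d aligned with the motion standing in
for the horizontal segment of a bent nozzle. Air exudes from a
lumen-sized mouth trailing the solid (air flow antiparallel to the
motion, as with a bent nozzle).

Injection is a *mass source*: a velocity-divergence source of integral
q2d at the mouth, compensated by a sink spread over the gel (a quasi-2D
slab accommodates added volume out of plane), plus the matching
pure-transport phase correction +ϕ·S so the bulk phases are transported
unchanged and the created air is booked exactly. A small clamp
saturates the mouth only when it has lost contact with air (nucleation
after a body is shed) or drains it under aspiration (negative flow
rate). A purely kinematic ϕ-source (painting air onto a moving disc)
was rejected: it recenters the deposited air onto the source and
thereby dictates the outcome morphology; with the mass source the bath
rheology decides whether the air follows the nozzle or is left behind.

2D bookkeeping: the volumetric rate Q maps to an area rate
q2d = Q / ((π/4)·d), i.e. the lumen mean speed times the lumen width,
and the deposited band width is w = q2d/v = PN·d by conservation. A 2D
width maps to a 3D-equivalent diameter via D_eq = d·√(w/d), because the
2D width ratio corresponds to the 3D cross-section *area* ratio
(D/d)² = PN. The PN sweep reports both.

## Scenarios: what the desk-scale 2D model shows

Default print job: 256×128 cells at dx = d/8 (a 32×16-diameter box),
bent nozzle of d = 0.5 mm, nozzle speed 100 mm/s, container walls at
the y-edges *and* x-edges, PN set through the air flow rate, and a
post-path relaxation of 0.4·Lx/v with the nozzle removed (the
bubble/channel dichotomy runs use a 0.16 s window, roughly the capillary
remodeling time of the longest printed fragment). The path starts with
the lumen mouth just off the left container wall, so the channel's tail
end is anchored there as when printing from the vessel boundary: with a
free tail the whole deposit can contract axially, which fattens channels
(~+15 % in width) and suppresses pinch-off. These sizes keep a full
print in the 1–3 minute range at second-order accuracy in space.

* **M2 (channel) regime.** A single uniform channel spanning the path
  with width ≈ PN·d (uniformity CV ≈ 0.05 at PN = 1); the equivalent
  diameter tracks d·√PN. The channel survives the post-path relaxation:
  the yield stress arrests surface tension, matching the
  plastocapillary criterion Y ≥ Y_crit.
* **M1 (bubble) regime.** The deposit cannot hold a channel: the
  ligament stretched between the wall-anchored tail and the advancing
  mouth necks and pinches (2D pinch-off of a stretched filament — note
  this is *not* Rayleigh–Plateau, which a 2D strip does not have: any
  area-conserving varicose modulation of a straight 2D strip increases
  its perimeter), shedding separate bodies that round up to circularity
  ≈ 1 within the observation window. The deposit does not span the path.
  The catalog's M1 is deliberately thin (K = 0.1 Pa·sⁿ): the capillary
  remodeling time μ_eff·d/σ of printed features must be short relative
  to the simulated window for the regime's end state to be observable at
  desk scale; the regime label itself depends only on Y = τ_y·R/σ.
  Circularity of small fragments can slightly exceed 1 (the smoothed
  contour perimeter estimator is biased low by a few percent for bodies
  of a few hundred cells or less).
* **Neighbor disturbance.** A pre-printed channel (width 1.5 d, the
  scale a unit-PN print lays down) spans the bath at a given clearance
  between its near surface and the nozzle path; a plain nozzle pass (no
  air, by default — printing a parallel channel at small clearance
  merges the two air bodies in 2D instead of constricting the old one)
  covers the first ~55 % of the channel and the bath then relaxes for
  five viscous relaxation times with the nozzle removed ("permanent"
  deformation). The deformation ratio is the minimal local width inside
  the disturbance zone over the median width of the untouched far
  segment; normalizing by the same-age far segment cancels the slow
  diffuse-interface background drift of thin-strip widths. Clearances
  at or below the nozzle radius are rejected as collisions.
* **Aspiration.** Retracing the path with Q < 0 removes the printed
  air through the mouth sink; recovery is reported as removed area over
  |q2d|·T.

## Printability classification

Features: yield stress (Pa), reference viscosity at 0.01 1/s (Pa·s),
nozzle diameter (µm); label printable/not-printable. The synthetic
generator samples features log-uniformly over τ_y ∈ [1, 10³] Pa,
μ_ref ∈ [10, 10⁶] Pa·s, d ∈ [100, 2000] µm — ranges bracketing
soft-matter baths and printing nozzles — and labels by the physics
rule: printable iff Y(τ_y, d/2) ≥ Y_crit **and** μ_ref below a tearing
threshold (3×10⁵ Pa·s, the zero-shear plateau scale of
elasticity-dominated baths). In log space that boundary is an
intersection of two half-planes, so clean data are nearly linearly
separable. Optional label noise flips labels independently.

Seven families (random forest, XGBoost, feed-forward net, k-NN,
logistic regression, SVM, Gaussian naive Bayes) are evaluated with
stratified k-fold CV (default 5) on standardized log₁₀ features, scaling
fitted on training folds only. What passing tests show: the bank
recovers a known, nearly separable physics rule and degrades gracefully
under label noise. What they do not show: performance on the real
laboratory dataset, whose size, ranges and noise structure are not
reproduced here.

## Known limitations

* 2D planar only: no Rayleigh–Plateau breakup (above), no out-of-plane
  drainage; channel diameters are 2D widths mapped by conservation.
* Regularized (not exact) yield surfaces: unyielded regions creep at
  the plateau viscosity; "arrested" means arrested on the simulated
  time scale.
* The constant-density projection treats buoyancy as a Boussinesq-type
  body force (off by default; the experiments' bubbles are
  drag-stabilized).
* The materials catalog is representative, not measured; quantitative
  agreement with any specific laboratory bath requires fitting its flow
  curve first.
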