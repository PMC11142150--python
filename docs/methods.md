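# Methods

## Model and assumptions

The package models bulk cytoskeletal flow in a cell projected onto a 1D
axis x ∈ [0, L] (rear → leading edge) as an active viscous fluid in
steady state:

    F_m(x) + μ v''(x) − ξ(x) v(x) = 0,
    F_m = f ∂M/∂x,   M(x) = M₀ exp(−((x − x_CZ)/σ)²).

Assumptions inherited from this formulation:

* **Fluid limit.** On the time scales of sustained motility the crosslinked
  meshwork flows; elastic (Maxwell) response to abrupt force changes is
  outside scope, as are membrane tension, polymerization forces, extensile
  microtubule stresses and multiple convergence zones.
* **Steady state.** Assembly/disassembly fluxes maintain constant geometry;
  the solver computes a single stationary velocity field, not dynamics.
* **Single Gaussian motor field.** Contractility is summarized by one
  convergence zone of width σ. The force per motor f and peak density M₀
  only ever enter as the product f·M₀, which is stored as one amplitude.
* **Linear adhesion (clutch) law.** Traction is T = ξ(x)·v with piecewise
  coefficients ξ_L, ξ_R across the convergence zone. T is reported as the
  stress exerted on the substrate. The step sits at x_CZ with the
  right-closed convention (the x_CZ node takes ξ_R); an optional logistic
  blend of configurable half-width is available for extreme ratios.
* **No-gradient edges.** v'(0) = v'(L) = 0, i.e. flow is uniform at the
  cell edges.

Key derived scalars: F_max = √2·e^(−1/2)·fM₀/σ (≈0.86·fM₀/σ) at
x_CZ ± σ/√2; dissipation length ℓ = √(μ/ξ); λ = 2μ/(σ²ξ_L) = 2(ℓ/σ)².
The analytic partition at the peak-stress point,
|F_visc| = F_max·λ/(1+λ) and |T| = F_max/(1+λ), sums exactly to F_max.
Two published forms of the traction estimate conflict (the printed traction
equation repeats the viscous one); the implementation follows the
text-consistent form |T| = F_max/(1+λ), which satisfies the stated limits
T → −F_max as λ → 0 and T → 0 as λ → ∞.

## Units

Lengths are µm; the time unit is whatever the velocity data carry (a
`velocity_unit` label, default "um/min", is passed through untouched and
never converted); stresses are an arbitrary consistent unit. All
physically identifiable outputs are ratios — velocities scale as
stress/adhesion — so the ratio constructor (`ModelParams.from_ratios`)
normalizes ξ_L = 1. The published table of fitted parameters prints the
F_max/ξ_L unit ambiguously; presets carry the printed numbers verbatim
with the unresolved-unit label.

## Numerics

* **Discretization.** Uniform grid (default n = 2001), centred second-order
  differences, Neumann conditions via ghost points (v₋₁ = v₁, vₙ = vₙ₋₂),
  direct banded (tridiagonal) solve. The system is solved in model units
  with the ξ_L = 1 normalization; the condition number is scale-invariant,
  and measured force-balance residuals are ~1e−12·max|F_m| across all
  preset regimes including λ ≈ 9·10⁷, so no further nondimensionalization
  is applied.
* **Verification.** Pointwise residual ≤ 1e−6·max|F_m|; Richardson
  refinement confirms O(Δx²) convergence (report ≤ 1e−4 on the default
  grid, shrinking ≈4× per grid doubling); symmetric parameter sets give
  antisymmetric v with |mean flow| ≤ 1e−8·max|v| and net traction ≤
  1e−6·∫|T|; solutions are invariant under joint rescaling of
  (ξ_L, ξ_R, μ, fM₀) and linear in the forcing.
* **Degenerate inputs.** A zero motor amplitude returns v ≡ 0 (the operator
  stays nonsingular as long as ξ > 0). A grid that under-resolves the motor
  peak (Δx > σ/10) triggers a warning, not an error.
* **Analytic-limit checks.** The closed forms for F_visc and T at x_c are
  derived from a three-point finite-difference estimate with spacing σ/√2,
  which is crude at small λ; the acceptance check therefore applies that
  same three-point estimator to the converged numerical velocity field
  (agreement within 25% across λ ∈ [0.2, 2000]), while the traction — which
  needs no stencil — is compared directly.

## Fitting procedure

Inputs are (position, velocity) tables with ≥ 15 samples; non-uniform
sampling is linearly resampled to a uniform grid. Forward solves run on a
grid commensurate with the data (refined to ≥ 1001 nodes) so model and data
are compared without interpolation bias.

1. **x_CZ** — location of max |dv/dx| (Savitzky–Golay quadratic smoothing,
   sub-grid parabolic refinement; ties resolve to the plateau midpoint).
2. **σ** — the motor stress peaks at x_CZ ± σ/√2, so σ = √2 × the distance
   from x_CZ to a flanking |v''| extremum. Each side contributes its
   largest-|v''| interior extremum outside a half-window guard zone around
   x_CZ, and the larger one-sided estimate wins. The guard zone and the
   per-side-maximum rule (rather than nearest-extremum) exist because the
   adhesion jump at x_CZ produces a boundary-layer spike in v'' on the
   strong-adhesion side, and noise ripples on the smooth shoulder otherwise
   masquerade as near extrema.
3. **ξ_R/ξ_L** — monotone root search on a log scale (bracket 1e−6..1e6)
   matching the model's right/left plateau-mean speed ratio to the observed
   one. Plateau windows exclude |x − x_CZ| < 3σ (configurable), shrunk per
   side to min(margin, 0.8·edge-distance/σ) so a convergence zone near an
   edge keeps a usable window.
4. **F_max/ξ_L** — the force balance is linear in the forcing, so a single
   closed-form rescale matches the observed left plateau speed.
5. **μ/ξ_L** — golden-section search on log μ (bracket 1e−2..1e10 × σ²)
   minimizing the RMS mismatch left of the convergence zone.

Steps 3–5 are nested, not cycled: the outer search runs on μ and each
candidate μ re-solves steps 3–4 exactly. At the noiseless fixed point this
is identical to cycling, but it is stable by construction where the
left-window objective is flat in μ while μ still shifts the step-3
inversion (large-λ regimes), a combination under which a flat cycle
oscillates chaotically. Steps 1–2 are refined by up to three damped
calibration passes that apply the identical estimators to the model curve
and subtract their bias (smoothing shifts the max-gradient location of
wide, asymmetric profiles by up to ~15%, which would otherwise inflate
ξ_R/ξ_L errors severalfold). The pass with the lowest full-profile RMS is
reported, so the recorded RMS sequence never ends above its starting value.

**Smoothing windows** adapt to the data: clean profiles (robust
second-difference noise estimate below 1e−3 of the peak speed) use a light
7-point window; noisy ones walk a ladder of windows (~n/10, n/20, n/50
points) and accept the largest whose σ estimate agrees with the
next-smaller one within 40% — wide motor zones need heavy smoothing,
narrow ones would be swallowed by it.

**Weak identifiability.** When the μ objective at the top of the bracket is
within tolerance of its minimum, the result sets `mu_lower_bound` and
reports the smallest compatible μ: in the uniform-flow limit the left-side
profile carries no information about μ beyond a lower bound. The
neuronal-migration regime (λ ~ 1e8) always triggers this. In the amoeboid
regime at a few percent noise, (ξ_R/ξ_L, F_max/ξ_L, μ/ξ_L) are jointly
degenerate along a ray ξ ∝ μ, F ∝ μ that preserves the right-side boundary
layer ℓ_R = √(μ/ξ_R); individual estimates are then high-variance but
median-unbiased across replicates, and only the ratios to μ are sharp.
Per-point uncertainty-weighted or Bayesian inference is out of scope.

## Synthetic data

The generator's role is verification: it produces exactly the data
structure the fits assume — a forward-model velocity field plus independent
additive Gaussian noise with sd expressed as a fraction of the peak speed —
with seeded, reproducible draws. Default cell geometries per preset
(cytokinesis L=30/x_CZ=15; amoeboid 60/35; mesenchymal 40/28; neuronal
60/55; axon outgrowth 100/95 µm) place the convergence zone centrally for
cytokinesis and near the front otherwise, matching the respective cell
architectures; the published ratio table does not fix L or x_CZ.
Kymograph emulation advects uniformly seeded tracers through v(x) with
fixed-step RK4 and renders Gaussian streaks.

What the generator does **not** emulate: spatially correlated tracking
errors, photobleaching, drift, finite kymograph resolution, or deviations
of real cells from the single-Gaussian/piecewise-adhesion idealization.
Passing recovery tests therefore demonstrate that the procedure inverts its
own model class at realistic noise levels — not that the model is correct
for any given cell.

The cytokinesis preset's μ/ξ_L is reconstructed (5.0e2) from σ = 1 and the
λ ~ 1e3 order of magnitude because the printed value is illegible; the
mesenchymal row's printed λ order (~1e1) disagrees with the recomputed
value (≈45, order 1e2 after rounding) and is flagged rather than forced
into agreement.

## Problem sizes

Default solves use n = 2001 nodes (~0.1 ms each); a full profile fit costs
roughly 1–3·10³ solves (≲0.5 s). The recovery benchmark shipped in the
tests uses 20 replicates per noise level at n = 2001, the scale at which
the median-based criteria stabilize.

## Known limitations

* Absolute mechanical parameters (μ, ξ in physical units) are not
  identifiable from a velocity profile alone; only the ratio set is fitted.
* ξ_R/ξ_L saturates for very strong asymmetries (the side-speed ratio
  becomes insensitive above ~10⁴–10⁵ when ℓ_R exceeds the front
  compartment), so such estimates are order-of-magnitude.
* The σ estimator assumes one dominant convergence zone; profiles with
  multiple contractile zones violate the model class.
* The noise-adaptive window ladder can occasionally lock onto an
  over-smoothed σ on an unlucky noise draw (one of twenty mesenchymal
  replicates at 2% noise in the shipped benchmark); median-based summaries
  absorb this.
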