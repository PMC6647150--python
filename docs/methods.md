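# Methods

## Model and regime

The package studies the planar FitzHugh–Nagumo neuron

    dv = (v − v³/3 − w + I) dt
    dw = ε (v + α − β w) dt + h(w) ∘ dB,

with `h(w) = σ₀` (additive channel noise) or `h(w) = σ₀ w`
(multiplicative), `∘dB` the Stratonovich integral.  The excitable
regime requires (i) a positive discriminant
Δ = (1/β − 1)³ + (9/4)(α/β − I)² of the fixed-point cubic, so that the
nullclines intersect once, and (ii) a complex stable eigenvalue pair
−μ ± iν of the Jacobian M = [[1 − vₑ², −1], [ε, −εβ]].  The fixed
point is evaluated by Cardano's formula with real, sign-handled cube
roots plus one safeguarded Newton step on v³ + pv + q (the step is
taken only if it reduces the residual); this protects the printed
6-digit values against cancellation near Δ → 0.  The closed-form
eigenvalues are cross-checked against `numpy.linalg.eigvals` at 1e−10
on construction.

The averaging reduction additionally needs μ/ν ≪ 1.  "≪" is
operationalized as a configurable threshold, default 0.2 (the
reference set has μ/ν ≈ 0.111); the excitability report carries all
flags rather than raising, since exploration outside the regime is
legitimate.  Parameter validation is permissive: only mathematically
required constraints (β > 0, ε > 0, σ₀ ≥ 0) are errors; ε ≥ 1 warns.

## Stochastic integration

All SDEs are driven by a single scalar Brownian motion.  The default
scheme is Euler–Heun: drift by Euler, diffusion by the Heun midpoint
½(H(Xₙ) + H(Xₙ + H(Xₙ)ΔB))ΔB, which is consistent with the
Stratonovich convention and *coincides exactly* with Euler–Maruyama
for additive noise.  A `stochastic_rk` switch applies the Heun average
to the drift as well.  Default step dt = 0.01 time units, which
resolves the rotation period 2π/ν ≈ 22.3 by ~2200 steps.  Drivers
accept pre-drawn increment arrays, so two systems can be integrated on
the same Brownian path (required by the pathwise linearization
comparison) and every stochastic run is replayable bit-for-bit from
its seed.  Ensembles are advanced as vectorized state blocks; the
first-passage and firing-probability drivers shrink their active set
as trials finish instead of storing paths.

Spikes are upward crossings of v = 0 with linear interpolation of the
crossing time and a refractory re-arm: after a spike, the next
crossing counts only once v has dipped below the rest level (default
−1.0 ≈ vₑ).  This gives one spike per excursion regardless of
numerical jitter at the threshold.  The crossing convention is
"v ≤ 0 before, v > 0 after".

The 2-D standard OU process used by the averaged approximation and the
radial norm construction is advanced by its exact Gaussian transition
(it is linear; Euler would only add bias), which also makes the
noiseless path decay exactly like e^{−μt}.

## Linearization error

The shifted process Z = X − Xₑ and its linearization Z̄ (noise field
at the state, or frozen at the equilibrium) are integrated on shared
increments; the remainder obeys ‖F̄(Z)‖ ≤ γ(r)‖Z‖ with
γ(r) = r²/3 + |vₑ|r inside the radius-r ball, so the pathwise error up
to the exit time τ(r) is bounded by C γ(r) r ~ C|vₑ|r² for additive
noise (mean-square with the square of the envelope for
multiplicative).  τ is evaluated on the discrete grid — this is
bound-checking, not precision timing.

The scaling experiment saturates the bound by scaling σ₀
proportionally to each radius and replaying the same increments across
radii.  With a fixed amplitude, small-radius exits happen before the
remainder accumulates (the error needs ~1/μ time units to reach its
envelope), the measured error decays much faster than r², and the
log-log slope is uninformative about the bound; with proportional
amplitudes the measured slope is ≈ 2.2 for additive noise and the
envelope constant is stable across an 8-fold radius range.  The
fixed-amplitude variant remains available
(`scale_noise_with_radius=False`).

## Normal form and radial reduction

Q = [[−ν, m₁₁ + μ], [0, m₂₁]] conjugates M to the
rotation-contraction matrix A = [[−μ, ν], [−ν, −μ]] *exactly* (the
identity is algebraic; the builder verifies it at 1e−10 and all
printed constants — 1.27722, 12.5, 157.881, 8.88486σ₀, 12.5651 — are
computed from M, never hard-coded, so the chain generalizes to other
parameter sets).  The transformed noise vector h_e = Q⁻¹(0, σ₀)ᵀ has
second component exactly σ₀/ε.

Two radial constructions are provided:

* **norm backend (default, reference)**: R_t = (σ/√μ)‖S̄_{μt}‖ with S̄
  the standard 2-D OU — the derivation route of the radial SDE, free
  of the 1/R singularity, valid from R₀ = 0 (the image of reset at the
  fixed point), and samplable at arbitrary nonuniform times via the
  exact OU transition.
* **direct Euler backend** on dR = [σ²/(2R) − μR]dt + σdB̃, for
  demonstration, with a positivity guard: a step driving R ≤ 0 is
  redone as two half-steps with fresh increments, recursively up to 20
  halvings.  (Conditioning the halves on the rejected coarse increment
  — a Brownian-bridge split — traps the recursion when that increment
  is extreme, because the conditioned path genuinely crosses zero; the
  fresh-increment rule lets the 1/R drift resolve it.  The laws agree:
  two-sample KS 0.03 at n = 1500 against the norm backend.)

The polar-coordinate variant keeps the rotating projection
⟨h_e, θ_t⟩, θ_t = (sin νt, cos νt), as its time-dependent diffusion
coefficient.  Its 1/R̄ drift cannot start at exactly zero; the
sampler's default start is √(‖h_e‖²dt/2) — one diffusion step from the
origin and ~6% of the stationary scale at the defaults — as a
practical stand-in for reset at rest.  The time-average of its squared
diffusion coefficient over one period equals σ² by construction.

## Firing mechanism

35 starting points L_i = (vₑ, wₑ − iδ), δ = |wₑ − w_sep|/20 with the
separatrix reference w_sep = −0.453 (a configuration value specific to
the reference parameter set), put the separatrix at grid index 20.
1000 trials per point ask whether the path crosses v = 0 within its
*first cycle* around the rest point.  The cycle is formalized as 2π of
unwrapped angle of Y = Q⁻¹(X − Xₑ) — the transformed dynamics rotates
near-uniformly at rate ν, so angle is the natural clock — with a hard
cap of 3·(2π/ν) for trials stalled near the origin; capped trials
count as non-spikes and their frequency is reported (≈ 3·10⁻⁵ at the
defaults).  The 35 estimates are fitted by unweighted least squares to
p(l) = 1/(1 + e^{(a−l)/b}) (binomial weighting available), with
starting values a₀ = first l where p̂ > ½ and b₀ = 5σ₀, and b
constrained positive.  Both parameters convert to normal-form radii by
the factor √(−m₁₂/(m₂₁ν²)) = 12.5651, which leaves a/b — hence the
logistic shape — invariant.

At the reference amplitudes the calibration lands within ~1e−3 of the
reference regression table (e.g. a = 0.0485, b = 0.0114 at σ₀ = 0.01),
a grows toward the separatrix distance 0.05 and b shrinks toward the
step-function limit as σ₀ → 0.

## Hazard, ISI density and sampling

The hazard is α(r) = (ν/2π)/(1 + e^{(a*−r)/b*}): the per-cycle firing
probability divided by the mean cycle duration.  The first-firing-time
density g(t) = E[α(R_t) e^{−∫₀ᵗα(R_s)ds}] is estimated over M = 1000
radial realizations shared across all evaluation times, with the inner
integral by the trapezoidal rule on n = 10 subdivisions (the
reference's coarse default; a finer n is used for the
exponential-oracle test, and on multi-thousand-unit horizons n = 10
carries a visible positive bias of ~2% in the total mass).  Sampling
uses thinning — fire with probability α(R_t)dt per step, dt·(ν/2π)
kept below 0.05 — because the hazard depends on the whole radial path;
under a constant hazard the sampler provably reproduces the
exponential law (KS < 0.05 at n = 2000) and the density estimator hits
α₀e^{−α₀t} to better than 1%.

## Spectral comparison

Welch's estimator (Hann window, 50% overlap, default segment length
1024 samples) on mean-removed series; ensembles are averaged
segment-wise and comparisons rescale every spectrum to a common
maximum before computing the normalized L2 gap.  At dt = 0.01 the
default bandwidth (0.098 cycles/unit) does not resolve the rotation
peak at ν/2π ≈ 0.0448, so the comparison captures the broadband shape;
with 4096-sample segments the peak is resolved and the
shifted-vs-linearized gap at σ₀ = 0.01 grows from ~0.6% to ~12%,
reflecting the genuine nonlinear variance amplification at that
amplitude (the gap collapses to < 1% at σ₀ = 0.002 at any
resolution).  The three radial processes (‖Y‖ of the linearized
system, the radial OU, the polar variant) agree within 2–7% at every
tested bandwidth.  Sub-threshold comparisons use many 50-unit path
pairs from rest, discarding pairs whose nonlinear member heads into a
spike.

## What the reduction does and does not reproduce

Everything up to the hazard transfer is quantitatively tight:
calibration constants, stationary Rayleigh law, backend equivalence,
spectra, linearization scaling.  The end-to-end ISI comparison at
σ₀ = 0.01 is qualitative: both distributions are unimodal,
right-skewed and on the same time scale, but the reduced model fires
~30% faster (two-sample KS ≈ 0.12–0.18 at 1000 + 1000 samples).  The
cause is the radial symmetry assumed by the hazard: the calibrated
p(l) is measured on the line L below rest, while the hazard applies it
to the *radius* of the process in every direction.  The nonlinear flow
produces large-radius excursions in directions that do not fire (its
transformed radius is heavier-tailed than the linear one, yet its
observed firing is slower), so the radial hazard over-counts.  The
discrepancy shrinks with σ₀ along with everything else nonlinear; the
test asserting distributional agreement at the 0.1 KS level documents
this limit and is expected to fail at σ₀ = 0.01.

## Problem sizes and randomness

Default experiment sizes: calibrations at the original 35 × 1000
trials; ISI comparisons at 1000 trials per side with horizon 1000;
stationary-law checks on 4000–5000 independent replicates; spectral
comparisons on 100–400 sub-threshold segments or 12–16 long paths;
error scaling on 20 replicates over radii 0.0125–0.1.  Stationary
variances are estimated from ensembles (e.g. 300 paths × 400 units
with 100 units of burn-in) rather than one long path — same effective
sample count, one vectorized sweep.  All randomness flows from
`numpy.random.Generator`; the pipeline derives per-stage generators
from the root seed via `SeedSequence.spawn` and records them in its
manifest, so every artifact is reproducible bit-for-bit.

## Known limitations

* The separatrix reference −0.453 and the firing threshold v = 0 are
  specific to the reference parameter set; the geometry of the
  separatrix itself is not computed.
* Only additive noise is calibrated and validated end-to-end;
  multiplicative calibration runs but is unvalidated.
* No higher-order SDE schemes (Milstein, adaptive), jump or colored
  noise.
* The hazard model assumes radial symmetry of the firing decision (see
  above) and a constant cycle clock ν; both degrade at large σ₀.
* Analytic first-passage formulas for the radial OU are out of scope;
  all reduced-model ISI quantities are Monte Carlo.
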