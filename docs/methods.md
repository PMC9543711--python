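# Methods

## The statistical model

All inference is on centroid-level quarterly growth rates
`r = ln(N' + c) − ln(N + c)` with offset `c = 3.03` (= 100/33, the smallest
non-zero value of a percent-of-33-sections index). Growth rates, rather
than log abundances, detrend multiplicative site quality: with `c = 0` and
positive indices a constant site factor cancels exactly; the offset breaks
exact cancellation but keeps zero indices usable.

Each wave hypothesis maps an observation's mean-centred coordinates and
time to one or two *space-modified time* covariates `ρ = T + D/ζ` (see the
module docstring of `wavegam.waves` for the full catalogue). Conditional on
the wave parameters the model is a weighted Gaussian additive model

    r = α₁ + Σ_k f_k(ρ_k) + ε,   Var(ε_i) = σ² / w_i,

with pairing weights `w = n_t n_{t+1}/(n_t + n_{t+1})`, the harmonic-type
combination of the two quarters' survey counts: observation variance is
proportional to 1/n under varying monitoring effort. The printed weight
subscripts pair a quarter with its predecessor; this package pairs exactly
the two quarters that enter each growth rate, which is the formula's
intent.

## The inner smoother

`PenalizedSplineGAM` is a low-rank radial-basis spline of the thin-plate
family: for a univariate smooth the basis is a linear term plus cubic
radial bumps `|u − κ_j|³` on the covariate rescaled to [0, 1]; knots sit at
covariate quantiles taken in base-2 van der Corput order, which makes the
knot sequence a prefix of an infinite one, so bases of increasing size are
nested (likelihood is then monotone in basis size, a property the tests
exercise). The wiggliness penalty is a ridge on the radial coefficients, so
the penalty null space contains exactly the linear functions: as λ → ∞ the
fit collapses to weighted linear regression, the oracle used in tests.
Basis dimension is capped at 12 for univariate smooths and 10 per margin
for the spatial tensor product (marginal bases [1, u, radials], products of
two margins, constant ⊗ constant removed).

Smooth terms are weighted-centred for identifiability, so α₁ is the global
mean level. When a smooth applies to a row subset (the river-split models),
every masked smooth after the first carries an unpenalized 0/1 group-level
column: without it the two river banks would be forced to share one mean
level, which the split hypothesis does not intend.

Numerical choices:

- Weights are normalised to mean 1 internally; fits are exactly invariant
  to uniform weight rescaling, and the log-likelihood is unchanged by the
  normalisation.
- Smoothing parameters minimise GCV `n·RSS_w/(n − edf)²` on a log grid
  (coordinate descent for multiple smooths, one local refinement pass).
  A `criterion="fixed"` mode accepts explicit λ. REML selection is not
  implemented; GCV is the package's single documented criterion.
- `AIC = −2 logLik + 2(edf + 1)`, with logLik the weighted Gaussian
  likelihood at the ML variance `RSS_w/n`, edf the hat-matrix trace
  (intercept included) and +1 for the variance. Only AIC *differences*
  between models matter for selection; the convention is applied uniformly
  to all twelve structures. The residual variance reported as `scale_` uses
  the denominator `n − edf`.
- Normal-equation solves add a tiny ridge jitter only if the system is
  numerically singular (degenerate designs raise instead).
- Fewer than three distinct covariate values, non-finite inputs or
  non-positive weights raise immediately; the annealer treats such
  degenerate proposals as rejected.

## Outer estimation

Wave parameters enter the likelihood only through ρ, so they are estimated
by minimising the inner GAM's AIC (not the raw likelihood: smooth
complexity must be penalised inside the search, or the optimizer drifts to
parameters that let the smooth overfit).

- **Direct search.** A deterministic coarse cross: epicentres on a lattice
  over the data bounding box ± 20%, 16 planar directions, speeds on a
  log-spaced grid from 10 m/day to 50 km/day. Two-wave models search
  sequentially (wave 1 against a neutral wave 2, then wave 2 given wave 1).
- **Simulated annealing.** Gaussian proposals per parameter (5 km for
  epicentre coordinates, 0.2 rad for angles, 10% multiplicative for speeds,
  which are optimized on the log scale); Metropolis acceptance; the
  initial temperature is calibrated from ~20 probe proposals so that about
  60% of early uphill moves accept. Cooling is geometric and normalised to
  the iteration budget — the temperature falls to 10⁻³ of T₀ by the final
  iteration (≈ 0.9995 per step at the default 15,000 iterations), and
  proposal scales shrink as √(T/T₀) with a floor — so that short runs still
  end cold enough to refine the optimum to sub-proposal scale. The
  *best-ever* parameters are returned, not the final state; passing an
  explicit `cooling` makes runs with a shared seed share their proposal
  stream prefix, so longer runs can only improve the best-ever objective.
- **Selection.** `adjustedAIC = AIC + 2K` with K the wave-parameter count
  (0/2/3/4/6 across the catalogue). Ties break toward fewer parameters,
  then label order. Per-model failures become table rows with an error
  message, never an abort.
- **Profiles.** One parameter is fixed on a grid; the remaining wave
  parameters are re-optimized by a short annealing restart (default 2,000
  iterations) from the joint optimum; the 95% interval is the grid region
  within χ²₁(0.95) = 3.84 of the profile minimum, with linear interpolation
  at the crossings. A profile that never crosses on one side yields a
  one-sided interval and a warning. For a planar wave, θ and θ + π with
  mirrored smooths describe the same fit; angles are reported in [0, 2π)
  and the selection study accepts either mirror of a radial pair (an
  expanding wave is statistically indistinguishable from a contracting one
  with a time-reversed smooth on symmetric designs).

## The synthetic-data generator

`wavegam.synth` emulates the statistical structure the analysis assumes —
not vole biology. The noise-free growth field is
`α₁ + Σ_w A_w · shape(2πρ_w/period)` with a sinusoidal default shape (any
periodic callable is accepted, since the fitted smooth is free-form).
Defaults describe the study system: a 3-year (1,095-day) cycle, growth-rate
amplitude 1.5 per quarter, residual σ = 0.3, a 200 × 150 km region, and a
six-year study (24 quarters, two full cycles — the span of the monitoring
programme the design mimics).

Abundance indices are derived from the field's exact running integral
along the wave: log(index + c) equals a baseline plus the antiderivative of
the growth field in space-modified time (composite Gauss–Legendre, exact to
machine precision for smooth shapes). Every location therefore sits at its
wave-consistent cycle phase from day 0 — the initial condition of an
established wave. Indices are clipped to the 0–100 scale; with amplitude
1.5 the cycle spans ~5.7 natural-log units against an available range of
~3.5, so roughly half of each cycle saturates at one boundary, exactly as
proportion-of-sections indices saturate in outbreak systems (zeros during
crashes motivated the 3.03 offset in the first place). Clipping is a pure
function of ρ, so it deforms the estimable cycle shape without breaking the
space-modified-time structure.

Per-survey observation noise is Normal with SD `σ·(index + c)` — i.e. σ on
the log scale — so a centroid mean over n independent transects has
variance ∝ 1/n, the premise of the weighting term. Survey days are jittered
uniformly inside quarters (never on a boundary). The adaptive design sends
each survey to a core rectangle with probability `core_fraction` (default
0.75); peripheral candidates are kept with probability 0.1 unless the local
noise-free growth rate exceeds the trigger (default 0.75). Because the
trigger uses the noise-free field — a function of ρ — peripheral selection
is covariate selection and does not bias E[r | ρ].

What the generator does *not* emulate: spatially heterogeneous site
quality, temporal drift in monitoring protocols, non-Gaussian index error
(a binomial section count would be natural), spatial correlation of
residuals, and real survey-location clustering along field margins.
Passing tests therefore show the estimation machinery recovers the assumed
structure; they do not validate the model against unmodelled features of
field data.

## Problem sizes and reference experiments

The canonical recovery experiment simulates ~400 surveys/quarter for six
years (≈9,600 surveys, ≈3,200 growth observations, ≈700 centroids) and
refits the RE model with 3,000 annealing iterations. The selection study
uses 20 replicates at 150 surveys/quarter with 250-iteration anneals for
all twelve structures; the profile-coverage study uses 50 replicates at 100
surveys/quarter with 500-iteration joint fits and 250-iteration restarts on
a 9-point multiplicative grid. These sizes were chosen as the smallest at
which the respective statistical property is cleanly expressed (e.g. the
single-radial truth stops being separable from its dual extension below
roughly 500 growth observations, because the extra smooth of the dual model
can absorb noise faster than the 2K penalty grows).

## Known limitations

- Under the default conditions the maximum-likelihood epicentre is
  displaced from the truth by ~0.3–2.5 km (median ≈ 1.5 km) and the speed
  by up to ~30 m/day across seeds; short anneals are not the bottleneck —
  the displacement is the estimator's sampling error at this noise level,
  so single-seed recovery error should be read with that spread in mind.
- The adaptive design concentrates peripheral observations around the
  high-growth phase, which sharply reduces the phase-lag information that
  identifies the wave speed: adaptive-design speed recovery is markedly
  less precise than under uniform sampling, while epicentre recovery
  degrades only mildly.
- ζ is a constant per wave; curved or accelerating fronts are out of scope.
- Errors are assumed independent Gaussian given the weights; no spatial or
  temporal residual correlation is modelled.
- The AIC of a penalized smooth is a convention (edf-based, conditional on
  the selected λ); absolute values are not comparable across packages, only
  within-catalogue differences are meaningful.
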