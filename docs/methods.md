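# Methods

This note records the model, the conventions and defaults the package
commits to, what the synthetic generator does and does not emulate, and the
numerical choices behind the diagnostics. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Model and assumptions

Memory strength is a unitless latent scalar; a recall test returns correct
exactly when strength is **strictly greater** than the threshold θ. The
strict inequality is a convention (the boundary case has probability zero
for continuous distributions but matters for empirical ones); ties at θ
count as forgotten everywhere in the package. The strength scale is
arbitrary, so defaults fix θ = 0 and initial strengths Normal(μ = 2,
σ = 1), placing the default population in the high-recall regime.

Homogeneous forgetting means every item loses the same decrement d(t); the
observed curve is then p(t) = 1 − F(θ + d(t)) exactly. The Monte Carlo
engine evaluates items on the caller's time grid only — there is no
event-driven threshold-crossing detection — so grid resolution is the
caller's responsibility.

The exponential family uses the literal form f(t) = s − aᵗ, whose intercept
is f(0) = s − 1 (the aᵗ term is 1 at t = 0). Rather than silently
re-normalising, the package keeps the literal form, reports
`initial_strength = s − 1` for this family, and routes all shared-shift
logic through the decrement d(t) = aᵗ − 1, which starts at 0 for every
family. Bases a ∈ (0, 1] are rejected because they would make strength
non-decreasing. Strength has no floor: observed forgetting comes from
threshold crossings, not clamping.

## Shape classification

Curves are classified from **slope changes**: with divided first
differences sᵢ = (pᵢ₊₁ − pᵢ)/(tᵢ₊₁ − tᵢ), the second difference at an
interior point is sᵢ₊₁ − sᵢ (units: p per time unit). A point is concave
below −ε, convex above +ε, linear otherwise; the overall label is the
majority, with "mixed" when both curvature signs occur or the vote ties.
The default ε = 10⁻⁴ was chosen so that, on the proportion scale, a slope
change of a few hundredths of a percentage point per trial counts as
curvature while numerical noise does not. Slope changes (rather than true
second-derivative estimates, which divide again by the time span) are the
natural scale for the experiment's question — "does forgetting per unit of
time increase between intervals?" — and keep the three-point design
(2, 20, 80) sensitive: its slope change of −1.75 × 10⁻³ classifies as
concave, whereas a per-time² measure would shrink it by the 78-trial span
and misread the design as linear at any comparable tolerance.

## Curve fitting

`fit_observed` fits aggregate forms on the observed-proportion scale,
clipped to [0, 1]: power p(t) = c − a·tᵇ and exponential p(t) = c − aᵗ
(parameterised by λ = ln a > 0; the intercept c may exceed 1 so the clipped
curve can start at ceiling). Fitting uses a seeded multi-start grid over
the shape parameter plus bounded trust-region least squares; degenerate
constant input returns the constant fit with a `constant_input` flag.
Fits operate on observed recall fractions, never on latent strengths,
because strengths are unobservable in a recall experiment.

## Bivariate population

Storage strength is operationalised as a latent z-score mapped
log-linearly to the forgetting scale, a = a_base·exp(−κz) (plus 1 for the
exponential base), with κ ≥ 0; the log-linear link is the simplest monotone
map that keeps parameters in range while implementing "more durable ⇒
slower forgetting". The latent (retrieval, storage) pair is bivariate
normal with correlation ρ (default 0.6); the joint form is a modelling
choice, not an empirical commitment. Per-item power exponents may vary
(lognormal, log-sd `b_sd`) but are fixed by default. With ρ = 0 and zero
parameter spreads the population reduces exactly to the homogeneous model,
which the tests verify against the analytic curve. This model can fit many
curve shapes, so the package deliberately exposes no fit-to-data API for
it — a good fit would not be evidence for the model.

## Regime-comparison defaults

The high/low-recall curvature comparison uses Normal(2, 1), θ = 0 and a
power decrement with scale 0.25 and exponent 0.8 on the grid t = 0…50.
With d = a·tᵇ the curvature ratio in closed form is
|p″|/|f″| = φ(z)·(1 + z·a·b·tᵇ/((1 − b)σ²)); exponents near 0.5 with small
scales cannot push the low-recall ratio above 1 anywhere on a practical
grid, while b = 0.8 yields both regimes on the same grid (ratio ≈ 0.24 at
p > 0.6, ≈ 1.85 at p < 0.3). These are the demo's defaults only; users can
probe any configuration.

## Experiment pipeline conventions

- **Slope scale**: percentage points per intervening item. Proportion
  inputs are multiplied by 100; divisors are the interval differences
  (18 and 60 for the 2/20/80 design). Slopes are signed; the Wilcoxon
  compares slope1 vs slope2, so the difference slope1 − slope2 is positive
  when forgetting accelerates and the rank-biserial sign then indicates
  concavity.
- **Exclusions**: participants who did the task before, who left > 50% of
  final answers blank, or who had zero initially-correct items in any
  condition (they would have no analyzable data there). Item filtering to
  initially-correct trials never removes participants.
- **Wilcoxon**: W = sum of ranks of positive differences; zero differences
  dropped; midranks for ties. The exact p (n ≤ 25) comes from the tie-aware
  null distribution built by convolution over sign assignments on doubled
  midranks; larger n uses the normal approximation with tie correction and
  a 0.5 continuity correction. The rank-biserial is the matched-pairs form
  (R⁺ − R⁻)/(R⁺ + R⁻). Alternative W conventions (e.g. min of the two rank
  sums) differ only in the statistic, not the p-value.
- **Shapiro–Wilk** delegates to scipy's implementation and is reported, not
  gated on: the pipeline always uses the Wilcoxon test, since slope
  differences from bounded proportions are generally non-normal.

## Synthetic generator

The generator emulates the three-interval paired-associate design: 99
participants, 10 analyzed pairs per interval. Initial strengths are drawn
directly as μ₀ + participant effect + item noise; the study phase is not
simulated mechanistically because the design specifies no learning model.
Initial and final correctness are threshold read-outs of the *same*
realised strength (minus d(interval) at final test), optionally perturbed
by lapse/guess probabilities that default to 0 so oracle tests stay sharp.
Blank responses are injected at a configurable rate and always score
incorrect. Fillers and the practice phase are not generated.

Three canonical configurations:

- `default_config()` — thresholds at the 33rd percentile of the marginal
  strength distribution, so ~1/3 of items fail the initial test and are
  excluded downstream; this reproduces the characteristic exclusion rate
  of criterion-style experiments.
- `default_concave_config()` — the concave-replication conditions: high
  initial strength relative to threshold (θ = μ₀ − 1.645σ, ≈5% initial
  failures), small spread (participant and item SDs 0.25), and a power
  decrement (scale 0.017, exponent 0.87) whose bulk-crossing falls inside
  the second retention interval. Under a *sharp* threshold truncated at
  the 33rd percentile of a normal, the maximum achievable slope
  acceleration is bounded by the truncated-normal density ratio along the
  crossing path (about 10%), far too small to detect at n = 99; strong,
  detectable concavity requires the filtered distribution to sit clear of
  the threshold, which is what this configuration implements. The two
  configurations therefore split the two empirical signatures (exclusion
  rate vs concavity) rather than forcing one parameter set to fake both.
- `null_config()` — zero decrement with lapse 0.5: analyzed final outcomes
  are independent fair coins, making the per-participant slope difference
  exactly symmetric about 0; used for type-I calibration of the full
  pipeline.

What passing tests show — and do not show — about real data: the generator
produces binomial item outcomes from a normal random-effects strength
model with a sharp threshold. It does not model answer scoring, spacing or
lag effects, item difficulty structure, participant dropout, or momentary
retrievability fluctuation, so pipeline results on synthetic data validate
the *machinery* (exclusion logic, slope algebra, test calibration, shape
labels), not any claim about human memory.

## Problem sizes and numerical choices

Monte Carlo checks use n = 10⁵ items with 3·SE agreement bands; morphing
margins are required to exceed 3 bootstrap SEs (200 resamples on a 5000-item
subsample); the averaging artifact and the synthetic replication use 20
seeds; type-I calibration uses 200 seeds at n = 99 participants. These
sizes give comfortable statistical margins while keeping the whole suite
fast. All randomness flows through numpy `default_rng` seeds; identical
seeds give bit-identical outputs, including CSV bytes.

## Known limitations

- Threshold movement and momentary retrievability fluctuation (reminiscence
  / hypermnesia) are out of scope; the threshold is fixed.
- The package does not fit the model to real datasets; the identifiability
  problems of the flexible bivariate model are the stated reason.
- The exact simulation settings behind qualitative regime illustrations are
  free configuration — curves are regenerated, not bit-matched to any
  external figure.
- The exponential fit form c − aᵗ can only represent initial values below
  ceiling via clipping (c > 1), which makes its early-time gradient zero in
  the clipped region; the multi-start grid mitigates, but pathological
  curves may need user-supplied starts.
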