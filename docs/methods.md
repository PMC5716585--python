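# Methods

`acuityfit` implements the statistical machinery of a two-alternative
forced-choice (2AFC) grating-acuity experiment: subjects (dogs or humans)
choose between a rewarded and an unrewarded grating card, the spatial
frequency of the gratings is raised until discrimination fails, and the
acuity threshold is read off a fitted psychometric function. This note
records the model, the conventions and numerical choices, what the
synthetic-data generator does and does not emulate, and the known limits.

## The psychometric model

The probability of a correct choice is modelled as a Weibull function with
guess and lapse rates:

    psi(x) = gamma + (1 - gamma - lambda) * (1 - exp(-(x / a)^b))

* `gamma` — guess rate, the lower asymptote. Fixed at 0.5: in a 2AFC task
  a blind observer is right half the time.
* `lambda` — lapse rate. The upper asymptote is `1 - lambda`: even
  trivially easy trials are missed at this rate (attention slips,
  motivation). Bounded to [0, 0.2], so fitted asymptotes lie in
  [0.8, 1.0]; estimates at the 0.2 bound are accepted as-is since real
  cohorts do show asymptotes as low as 80%.
* `a` — scale (cpd on the performance axis): the point where the rise has
  covered 1 − 1/e of its span. `b` — steepness. Both free and positive.

### The reversed performance axis

`psi` as written is increasing in `x`, but performance *falls* as grating
frequency rises. The package evaluates the model on

    x' = axis_origin - frequency,

where `axis_origin` is the top of the tested frequency grid, and maps all
thresholds back to cycles per degree. Two consequences are worth stating
openly:

* at the origin (the highest tested frequency) the model is pinned exactly
  to chance — an assumption, adequate when the grid top is chosen, as in
  practice it is, well above any subject's acuity;
* this is *one* consistent way to drive an increasing Weibull with
  falling performance data; the mapping is not determined by the
  functional form alone, and other conventions (e.g. fitting in
  log-frequency with a decreasing parameterisation) would give slightly
  different interpolations. The choice is documented here and in
  `acuityfit.observer` rather than hidden.

### Threshold

The acuity threshold is the frequency at which the fitted function crosses
75% correct, computed by the closed-form inverse

    x'_75 = a * (-ln(1 - (0.75 - gamma)/(1 - gamma - lambda)))^(1/b)

and mapped back as `axis_origin - x'_75` — an analytic interpolation on
the fitted curve, not a line between data points. The 75% level is not
arbitrary: with 20 trials per frequency, 15/20 is the smallest count whose
exact one-tailed binomial tail probability under chance falls below 0.05
(P(X ≥ 15 | 20, ½) ≈ 0.0207; P(X ≥ 14) ≈ 0.058), so the threshold level
and the per-frequency significance criterion coincide at 75%.

## Fitting

The aggregated binomial negative log-likelihood (binomial coefficients
dropped; psi clamped to [1e−9, 1 − 1e−9] before logs) is minimised over
(a, b, lambda) with gamma fixed. The surface is multimodal at 20 trials
per frequency — a shallow-curve basin and near-step basins at large `b`
compete — so the fit:

1. evaluates a factorial start grid vectorised: ~10 log-spaced scales over
   the data span *plus* the data's own x' values and their midpoints
   (at steep `b` the likelihood is nearly piecewise-constant in `a`, so
   gradient polish cannot move `a` between data points — the starts must
   already straddle them), times b ∈ {0.5, 1, 2, 4, 8, 16, 30}, times
   lambda ∈ {0, 0.1, 0.2};
2. polishes the overall best eight starts **and** the best start within
   each steepness stratum with L-BFGS-B in (ln a, ln b, lambda), bounds
   a ∈ [1e−3, 1e4], b ∈ [0.05, 50], lambda ∈ [0, 0.2], ftol 1e−8.

Polishing only the global top-k is not enough: the top starts often all
sit in one basin while the true optimum is a near-step fit; the
per-steepness stratification closes that gap (verified against a dense
200×200×21 brute-force grid search, where the multistart optimum is never
worse than the grid optimum beyond 1e−3 nats).

A fit is reported `converged=False` — a flagged row, never an exception —
when the subject never scores above chance, when the optimum pins `a` or
`b` to the search boundary, or when the fitted 75% crossing falls outside
the representable frequency range (below 0 cpd). These are the synthetic
analogues of real subjects excluded because "the psychometric function
could not be fitted".

## The alternative, model-free estimate

`significance_threshold_acuity` returns the highest tested frequency whose
(k, n) counts are significantly biased away from chance (exact one-tailed
binomial, alpha = 0.05, no multiple-testing correction — deliberately, to
mirror standard practice for this estimate). The maximum is taken over all
tested frequencies even when non-significant dips occur below it; no
monotonicity is imposed on raw counts. Users should know this estimate is
grid-quantised and can exceed the Weibull interpolation by up to a grid
step or more for lucky runs.

All binomial tails are exact sums (scipy's survival function); at n = 20
a normal approximation would distort the criterion itself.

## Session design

Schedules satisfy: the rewarded side never repeats more than twice in a
row; within each frequency, left/right counts of scored trials balance to
within one (the balancing unit is per-frequency; for odd counts the extra
trial's side is randomised); interleaved (dog-style) sessions start with
the lowest frequency after two unscored warm-up trials at that frequency;
blocked (human-style) sessions run each frequency as a contiguous block in
ascending order.

Generation assigns sides trial-by-trial among the admissible options,
weighting by remaining side quota (pure uniform choice drains one side's
pool early and dead-ends on long sessions), and restarts from scratch on a
dead end with a 10,000-restart cap. All randomness flows through one
integer seed; identical seeds give identical schedules.

## The synthetic observer

`simulate_choices` draws each scored trial as an independent Bernoulli
success with probability psi(x'), then aggregates to per-frequency
(n_correct, n_total); only the first 20 choices per frequency are scored
(configurable), matching a first-20 analysis rule. `make_study_fixture`
builds a subject on the exact grid of one of four condition profiles —
dog/bright 2–16 cpd (extended to 30 cpd when the observer's threshold
exceeds 12 cpd, as extra frequencies were added for high scorers),
dog/dim {0.5, 2, 4, 6, 8, 10}, human/bright {30, 39, 44, 50, 64, 70, 78}
blocked, human/dim {0.5 … 14} — and solves the scale so the observer's
true 75% point sits at a requested threshold.

Default observer shape per light condition (overridable):

| condition | b | lambda | rationale |
|---|---|---|---|
| bright | 3.0 | 0.15 | upper asymptotes observed around 80–89% correct; gradual fall-off |
| dim | 6.0 | 0.09 | asymptotes around 87.5–95%, with performance plateauing within the grid, which on the reversed axis requires a steep rise |

What the generator does **not** emulate: learning or fatigue across
sessions, side bias, sequential dependence between trials, inter-subject
lapse variability within a condition, or stimulus artefacts such as
aliasing. Passing recovery tests therefore shows the estimator is sound
for independent-trial observers of this family, not that every real
subject is well described by it.

## Stimulus geometry and rendering

Visual angles use the exact relation `2·arctan(extent / (2·distance))`
(the study's printed 2.9°/7.6° for a 20 cm card at 4 m/1.5 m are
reproduced to one decimal only by the exact form). Spatial frequency is
cycles across the card divided by the card's full visual angle;
`cycles_for_cpd` rounds to whole cycle counts and reports the realised
cpd. Rendered cards are `0.5 + 0.5·C·G·sin(2π·n·u)` with phase 0, mean
luminance 0.5 (so Michelson contrast equals the amplitude ratio), and a
Gaussian envelope `G` centred on the card with SD = 0.22 of the side
length — 0.22 is taken as a fraction of the (unit-normalised) card since
it is only meaningful as a normalised width. The nominal 81% Michelson
contrast is interpreted as the envelope-peak sinusoid amplitude; measured
over the full central period of a rendered card the envelope has already
decayed slightly, so the operational contrast comes out ≈ 0.80–0.81
depending on cycle count (within ±0.02 of nominal for study-like cards).
Rendering refuses fewer than 4 pixels per period.

## Verification problem sizes

The shipped checks use: 500 simulated subjects per condition profile
(5 true-threshold levels spanning the condition's observed acuity range ×
100 replicates, 20 trials per frequency) for threshold recovery, pooled
median of recovered/true within 10%; 50 random small datasets against the
200×200×21 brute-force grid; 1,000 seeded schedules through the
validator; 2^n enumeration of binomial tails for n ≤ 12; closed-form
inverse round-trips to 1e−10.

## Known limitations

* **Grid-edge bias.** When the true threshold lies near the bottom of the
  tested grid (e.g. ≈1.8 cpd on the dim {0.5 … 10} grid), only one tested
  frequency sits above threshold and the median recovered threshold is
  biased upward by ~10% even for a steep observer. This is an
  identifiability limit of the sampling design, not of the optimiser; the
  pooled median over a condition's realistic threshold range stays within
  10%.
* The chance-at-origin pinning (see axis section) makes thresholds at or
  above the grid top inexpressible; `make_study_fixture` refuses them and
  fits flag out-of-span thresholds.
* The supplementary-workbook converter is written defensively against
  three plausible layouts (long counts, long trials, wide counts) and
  reports, rather than drops, rows that violate invariants; genuinely
  novel layouts raise a descriptive error listing what was expected.
* The binomial machinery applies no multiple-testing correction across
  frequencies and no sequential correction to the learning criteria, by
  design.
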