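# Methods

This note documents the models, conventions and design choices behind
`snakeroad`, in the order the pipeline runs them.

## Survey summarization

Encounter records are validated dataclasses (SVL, tail, weight positive
when present; route position within the 37-km transect; AOR/DOR status
and species mandatory). Carcasses too degraded to measure keep their
missing morphometrics: they are excluded from trait summaries but
retained in counts and %DOR, mirroring how the field protocol recorded
unmeasurable snakes. Dates carry no timezone; months are calendar
months of the encounter date.

Monthly summaries report AOR/DOR tallies, species counts, snakes/km
(count ÷ distance driven that month), snakes/visit, %DOR =
100·DOR/(AOR+DOR), and the AOR:DOR ratio (missing when no DOR). A month
with encounters but no recorded effort is an error rather than a silent
infinity.

**Spatial binning.** The 37-km route does not divide evenly into 2-km
bins; the trailing 1-km remainder is merged into the final bin (18 bins,
the last 3 km wide) and the χ² uniformity test uses width-proportional
expected counts. This keeps every expected count positive without
inventing a 19th half-empty bin. The statistic is the classical
Σ(obs−exp)²/exp with df = bins − 1.

**Morphometrics.** Group summaries are mean ± sample SD (ddof = 1) with
ranges; single-animal groups report no SD. Sex comparisons use Welch's
t from summary statistics with Satterthwaite df. The demographic
classification is a single four-level categorical (male / female /
juvenile / unknown); juveniles are not additionally sexed.

## Synthetic data

The generator's defaults are the study conditions: eight months × three
standardized surveys of 74 km; per-night encounter counts
Poisson-distributed at the observed monthly rates; species drawn from
the observed relative abundances; demographic class per species from
the observed class counts; route positions uniform over the transect
(the field study found no hotspots, so none are modeled).

Sizes are truncated normals matching each species × class mean ± SD,
truncated at the observed range — the simplest family consistent with
the published moments that cannot produce negative lengths. Weight is
drawn conditionally on SVL through a log-log linear predictor with an
allometric exponent of 3 (isometric mass scaling) and residual noise
moment-matched so the marginal weight SD approximates the published
one; this makes length and weight collinear, as in real snakes, which
matters for the DOR model that uses both. Classes never measured in
the field (e.g. "unknown") are generated without morphometrics.

DOR status is Bernoulli with log-odds linear in total length, weight,
and male/juvenile indicators (reference: adult female); the default
coefficients are the all-sizes fitted model, so juvenile mortality
behavior comes from the juvenile coefficient rather than a separate
mechanism. All draws flow from a single `numpy` generator: identical
(config, seed) gives byte-identical CSVs.

What the generator does **not** emulate: spatial clustering,
recaptures, carcass-persistence bias, observation times beyond a
uniform nightly window, and between-year heterogeneity. Passing tests
therefore demonstrate correctness of the estimators under the assumed
data-generating process, not robustness to those field realities.

## Mortality models

Fits are binomial GLMs (logit link) via iteratively reweighted least
squares to tolerance 1e-10. Categorical coding: reference level female,
with juvenile as an additional level in all-sizes data; month and year
enter as unordered categoricals. Model comparison uses AIC =
2·df − 2·loglik on the listwise-complete intersection of rows, so all
candidates share one likelihood support; ties break toward fewer
parameters, then candidate order. Complete separation is detected (via
degenerate fitted probabilities or separation warnings) and raised as a
named error with a scan for the offending covariate.

Odds-ratio CIs default to profile likelihood — each bound inverts the
likelihood-ratio test by refitting with the focal coefficient fixed as
an offset and root-finding where the deviance excess crosses
χ²₁(0.95) — because the asymmetric published interval is consistent
with profiling; Wald intervals are available and are the fallback when
a profile bound cannot be bracketed. AUC is the rank-statistic
concordance of fitted probabilities with ties counted ½.

The prediction curve conditions weight at its sample mean and sex at
the reference (the original analysis does not state its conditioning
point); CIs are normal on the link scale mapped through the inverse
link. The fitness smooth is a cubic smoothing spline of per-individual
fitted probabilities against total length with smoothing chosen by
generalized cross-validation, clamped to [0, 1], with a
case-resampling bootstrap percentile band; duplicate abscissae are
averaged before spline fitting. The selection surface evaluates the
fitted model over a length × weight grid at the reference sex.

## Crossing simulator

The crossing is a static snapshot: no speeds or timing, only widths and
positions, which is all the published description specifies. The snake
is a 1-D interval [head, head + L] perpendicular to traffic with the
head uniform over the full paved width [0, W]; the body may extend past
the far edge. This convention reproduces the closed-form single-car
probability 2(L + w)/W at the mixture mean (25.8%), whereas confining
the whole snake to the pavement does not. A wheel [p, p + w] kills
heads in (p − L, p + w); the kill zone is the clipped, merged union
over wheels.

Geometry defaults: 732-cm road, two equal lanes, 20-cm wheels, 177-cm
wheel separation interpreted center-to-center (the automotive
track-width convention; edge-to-edge is a config switch). The length
mixture is the empirical one: Normal(mean, SE) components for measured
AOR (71.83 cm, 27.35/√50) and DOR (81.14 cm, 24.25/√21) snakes weighted
50:21, truncated at the 135-cm maximum observed.

One-car trials center the car in a randomly chosen lane (the
expectation is placement-invariant while the kill zones stay interior).
The two-car lateral-placement convention is genuinely open — the
published description does not state one — and changes the answer
materially: both cars centered ≈ 52%, one car per lane with
uniform-in-lane offsets ≈ 49%, both uniform in the same lane ≈ 37%,
both independently uniform over the full width ≈ 43%. The package
defaults to the last (free placement), the convention closest to the
published two-car mean among physically plausible ones, and exposes all
four as a config enum. Summaries are binomial: SD = √(p̂(1−p̂)), 95% CI
= p̂ ± 1.96·SD/√n clipped to [0, 1]. The mortality-versus-length smooth
is a univariate logistic regression of the kill flag on length with
link-scale CIs; a run with a single outcome class yields a flat curve
at the Jeffreys-adjusted rate.

## Selection differential and projection

s standardizes the *pooled* total lengths (R `scale` convention: sample
SD, ddof = 1) and contrasts survivor and casualty means, so s < 0 when
casualties run larger. The bootstrap resamples individuals (not
stratified by status — a stratified flag exists); replicates that lose
a status group are redrawn and logged.

The projection draws h² ~ N(0.59, 0.27) and s ~ N(−0.421, 0.268) *once
per population* and holds them fixed: the between-population spread of
final lengths then matches the delta-method prediction
(Σₜe^(−kt))·SD(h²·s) ≈ 9.2 cm, which reproduces the scale of the
published ±0.6-cm CI over 1,000 populations, whereas per-generation
redraws would shrink it by ~√50. Draws are untruncated so sign-flipping
draws can produce growing populations, as observed. The per-generation
response h²·s·e^(−kt) (t = 0…49, k = 0.005) is applied **directly in
centimeters**: the published ~12-cm/50-generation decline is only
consistent with the cm-direct reading (an SD-scaled response would give
sub-centimeter dynamics); an SD-scaled variant sits behind
`response_scale="sd"`, and `(1−k)^t` decay — numerically
indistinguishable at k = 0.005 — behind `decay_form="geometric"`. With
variances and k zero the recursion collapses to the closed form
80.66 + 50·0.59·(−0.421) = 68.2405 cm; with decay the expectation is
80.66 − 0.2484·Σₜe^(−0.005t) ≈ 69.64 cm. Final-length-versus-h²
regression is OLS with the usual two-sided slope test; generations
convert to years by multiplying with the 3.3-yr generation time.

## Orchestration and problem sizes

The pipeline spawns per-stage child seeds from one global
`SeedSequence`, records per-stage status and SHA-256 hashes of every
output in a manifest, and lets independent stages run when one fails
(e.g. a no-DOR season kills the model stage but not the crossing or
projection stages, the latter falling back to the configured s).

Default problem sizes follow the study: 10,000 crossing trials, 1,000
bootstrap replicates, 1,000 populations × 50 generations. Test and
driver code uses the same sizes except where an operation is
super-linear in n — the GCV spline bootstrap is run at the study's
n = 48 sample (as the original figures were) rather than on
5,000-row synthetic tables.

## Known limitations

- The two-car result depends on the placement convention; only the
  convention family, not the exact published 40.6%, is reproducible.
- Profile CIs assume the constrained deviance is monotone beyond the
  crossing; pathological likelihoods fall back to Wald.
- The generator's weight-given-length calibration matches moments only
  approximately when length variance dominates the weight variance on
  the log scale.
- The projection is purely phenotypic: no drift, mutation, density
  dependence, or competing selective agents.
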