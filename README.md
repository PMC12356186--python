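# snakeroad

Road ecology of a Chihuahuan Desert snake community: survey
summarization, size-based road-mortality models in the Western
Diamondback Rattlesnake (*Crotalus atrox*), a geometric Monte-Carlo
road-crossing simulator, and breeder's-equation projections of
selection on body size.

## The problem

Nocturnal road-cruising surveys on a 37-km two-lane desert road yield
one record per snake found alive-on-road (AOR) or dead-on-road (DOR),
with species, sex/stage, snout–vent length (SVL), tail length, mass and
route position. Three questions drive the analysis:

1. **Community description** — monthly encounter rates (snakes/km,
   snakes/visit), mortality fractions (%DOR), per-species morphometrics,
   and whether encounters cluster spatially (χ² uniformity over 2-km
   route bins).
2. **Is road mortality size-biased?** Binomial logistic regressions of
   DOR status on body size (total length = SVL + tail), weight and
   sex/stage, compared by AIC across an 11-model candidate set, with
   odds ratios (profile-likelihood CIs), AUC, a prediction curve, a
   GCV cubic-spline fitness smooth, and a length × weight selection
   surface. A geometric simulator cross-checks the mechanism: a snake of
   length *L* crossing a road of width *W* under a car with two *w*-cm
   wheels dies with probability 2(*L* + *w*)/*W* (single car, kill zones
   interior), and Monte-Carlo trials extend this to two-car traffic.
3. **What could size-biased mortality do over time?** The standardized
   selection differential *s* = mean(z<sub>AOR</sub>) −
   mean(z<sub>DOR</sub>) of pooled-standardized total lengths (bootstrap
   SD), iterated through the breeder's equation *Z* = *h*²·*s* with
   per-generation decay e^(−*k·t*) across 1,000 populations for 50
   generations.

Because the raw capture data are not redistributable, a first-class
synthetic generator (`snakeroad.synth`) draws seasons with the study's
structure — Poisson encounters per survey night, published species and
demographic mixes, truncated-normal sizes, weight allometric in SVL,
and logistic DOR status — so every downstream stage is testable
offline. Published summary tables live in `snakeroad.fielddata` and are
used directly where the analysis operates on summaries.

## Worked example

```python
from snakeroad import crossing, evolution

one = crossing.simulate_crossings(scenario="one_car", n_trials=10_000, seed=42)
two = crossing.simulate_crossings(scenario="two_car", n_trials=10_000, seed=43)
print(f"one car: {100*one.mean:.1f}%  two cars: {100*two.mean:.1f}%")

traj = evolution.simulate_response(evolution.EvoSimConfig(seed=42))
out = evolution.summarize_trajectories(traj)
print(f"grand mean after 50 generations: {out['grand_mean_final_cm']:.1f} cm")
```

prints

```
one car: 26.2%  two cars: 43.5%
grand mean after 50 generations: 69.2 cm
```

A ~26% single-car kill probability for the empirical snake-length
mixture (closed form: 25.8%), roughly 43% when two cars pass
simultaneously, and a ~11.5-cm decline in mean total length over 50
generations (≈165 years at 3.3 yr/generation) when selection against
large snakes decays at *k* = 0.005.

The numbered scripts under `analysis/` run the full narrative —
synthetic season, survey summaries, model ranking, crossing simulation,
selection response — and write their tables under `results/`. The same
stages are available as a CLI (`snakeroad synth|summarize|fit|crossing|
differential|evolve|run`), e.g.

```bash
snakeroad run --seed 1 --out results/run1
```

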