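# moultshift

Analysis pipeline for **seasonal coat-colour moult phenology and
camouflage-mismatch behaviour** in snowshoe hares (*Lepus americanus*) and
other colour-moulting species.

Hares moult between brown summer and white winter pelage. When snow arrives
late or melts early, a white hare on bare ground (or a brown hare on snow) is
conspicuous to predators — *camouflage mismatch*. Field studies of this
problem produce longitudinal radiotelemetry data: weekly sightings of
radiocollared hares scored for % coat whiteness and % background snow cover
in 20% increments, plus behavioural measurements (concealment in vegetation,
flight initiation distance, and the snow cover of the chosen resting spot
versus its eight surrounding "pie slices"). `moultshift` provides the full
statistical toolchain for such data, together with a synthetic-data generator
that emulates the study design so every estimator can be validated against
known generating truth.

## What it computes

**Moult phenology** — a hierarchical Bayesian change-point model. Each hare
*i* has a piecewise-linear latent whiteness trajectory: 0% before its
initiation date, ramping to 100% over its moult duration (mirrored in
spring). Individual initiation dates vary around a population mean,

```
init_i = μ_init + ε_i,   ε_i ~ N(0, σ_ind²)
dur_i  = d̄ · exp(β_snow·snow_i + β_temp·dd_i) + β_sex·sex_i
y_ij   = traj(t_ij; init_i, dur_i) + e_ij,   e_ij ~ N(0, σ_obs²)
```

with snow cover and cumulative degree days (sum of daily means below 0 °C in
autumn, above 0 °C in spring) as moult-rate covariates. Posterior sampling is
by adaptive random-walk Metropolis-within-Gibbs (≥2 chains, split-chain R-hat
diagnostics); the population completion date `μ_init + dur` at covariate
means is derived per draw with a 95% equal-tailed credible interval.
Covariate effects are summarised as completion-date shifts (e.g. the shift
from 100% to 0% snow), and individual reaction norms are extracted for hares
observed in the same season of ≥2 years.

**Camouflage metrics** — signed colour contrast (`whiteness − snow`),
mismatch classification at the inclusive ±60% threshold, weekly averages,
degree-day series.

**Behaviour** —
* *Concealment*: linear mixed models (random intercept per hare) over an
  AICc-ranked candidate set screened for collinearity (|r| ≥ 0.8), including
  quadratic contrast terms; fixed-effect precision from 100 000 posterior
  draws (normal approximation at the ML mode) summarised as 95% HPD
  intervals.
* *Flight initiation distance*: Cox proportional hazards on the 20 → 3 m
  approach, flight the event, "no flush" right-censored at 3 m; Efron ties,
  Schoenfeld-based proportionality tests, AICc best set.
* *Resting spots*: used–available binomial logit (1 used spot vs 8 available
  slices per location) for snow and contrast separately, with an exact
  conditional-logit fit per choice set as cross-check, a presence-probability
  curve over snow 0–100%, and the probability ratio between bare and
  snow-covered spots.
* *Habituation truncation*: both behavioural responses are first regressed on
  the cumulative location attempt; the data are truncated at the largest
  attempt count whose slope interval still includes zero.

## Worked example

Simulate a small single-site study and fit the autumn change-point model:

```bash
moultshift simulate --fixture phenology_small --seed 11 --out demo/
moultshift phenology fit --data demo/observations.csv \
    --temps demo/temperatures.csv --season autumn --site gardiner \
    --year 2010 --seed 7 --no-covariates --out demo/fit/
```

prints

```
 parameter      mean       sd    ci_low    ci_high     rhat
   mu_init 60.401831 4.423214 47.486846  66.987205 1.032892
      dbar 35.361022 1.867232 31.764585  38.982562 1.038606
 sigma_ind  9.503384 4.383058  4.938614  23.317070 1.121297
 sigma_obs  6.741933 0.502387  5.833867   7.773461 1.006556
  duration 35.361022 1.867232 31.764585  38.982562 1.038606
completion 95.762853 4.362804 83.782995 101.985757 1.062959
```

Days count from 1 August, so the population initiation posterior
(mean day 60, CI 47–67) covers the generating value recorded in
`demo/truth.yaml` (day 55 ≈ 25 September), and the completion posterior
(mean day 96, CI 84–102) covers the generating completion (≈ day 96); the
moult takes about five weeks. `sigma_ind` is the between-hare spread of
initiation dates in days and `sigma_obs` the whiteness scoring error in
percent. With 30 heavily-censored hares the sampler warns that one R-hat
exceeds 1.05 — rerun with more draws (`--warmup/--draws`) for publication
use.

`moultshift behaviour concealment|fid|resting` run the behavioural analyses
on the same CSV, and `moultshift run-all` executes the entire study
(metrics → phenology → behaviour) into an output directory with a
checksummed JSON manifest, byte-identical on rerun with the same config.

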