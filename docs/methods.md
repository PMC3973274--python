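# Methods

This note documents the models, the synthetic-data generator, numerical
choices, and the design decisions taken where the design was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and scoring conventions

Coat whiteness is scored in 20% increments with the field convention that
just-initiated and nearly-complete moults score 5% and 95% rather than 0/100,
so the legal grid is {0, 5, 20, 40, 60, 80, 95, 100}. Snow cover (1-m and
10-m radii, and all eight pie slices) lies on the plain 20% grid. Missing
behavioural fields are explicit absences, never zeros — zero is a legal
datum. Flight trials record distance to the nearest metre between a 20-m
reliability limit and a 3-m minimum approach; a hare that does not flush is
right-censored at 3 m. `attempt_index` (cumulative location attempts,
including unsuccessful ones) is supplied with the data because failed
attempts leave no observation row from which it could be reconstructed.
Dates are ISO-8601 calendar dates and all day arithmetic is integer days;
the data have no sub-weekly time resolution to preserve.

Each site carries its own month→season calendar: the low-elevation site has
winter Dec–Mar and spring Apr–May; the high site winter Nov–Apr and spring
May–Jun, reflecting its longer snowpack.

## Camouflage metrics

Colour contrast is `whiteness − snow` (signed percent; positive = white hare
on bare ground). Mismatch uses the inclusive thresholds contrast ≥ +60
(positive), ≤ −60 (negative), otherwise none; the threshold is configurable
(`StudyConfig.mismatch_threshold`). Degree days accumulate the *magnitude*
of sub-zero daily means over September–December (autumn) and of above-zero
means over March–June (spring), so both seasons' series are non-negative and
comparable; the accumulation requires a gap-free daily window and refuses to
impute. Weekly averages bin by ISO week within ISO year.

## The change-point model

* Trajectory: piecewise linear between the two change points (initiation,
  initiation + duration), clamped to [0, 100]. A logistic ramp is a
  deliberate non-goal: weekly scoring at 20% resolution cannot distinguish
  the two, and the linear form makes initiation/completion dates exact model
  parameters.
* Random effects sit on **initiation**; the moult rate is shared across
  hares apart from covariate effects. Putting effects on both initiation and
  rate is unidentifiable at ~10 sightings per hare; the alternative is noted
  here and not implemented.
* Covariates (per-hare seasonal snow mean, seasonal degree-day mean, sex)
  modify duration multiplicatively through an exponential link, with sex as
  an additive days-offset: `dur_i = d̄·exp(β_s·snow + β_t·dd) + β_sex·sex`,
  floored at 1 day. Sex is coded 0 (male) / −1 (female): positive `β_sex`
  shortens the female moult. Time-varying covariates are summarised as
  seasonal window means; a day-resolved rate integral is out of scope.
  When a daily site snow series is supplied, every hare of a site-year gets
  the site window mean (free of detection/mortality sampling bias, so the
  date estimates are clean, but the snow effect is then only identified
  across site-years); without one, the mean `snow10m` of each hare's own
  sightings is used, which carries real between-hare microhabitat signal at
  the cost of selection noise.
* Observation model: Gaussian on the latent percentage, grid scores treated
  as point observations. An interval-censored likelihood over the scoring
  bins is the documented alternative; at σ_obs ≈ 8% the Gaussian treatment
  is adequate and far cheaper inside MCMC.
* Priors: uniform initiation window over the season axis (default day 0–150
  from 1 Aug / 1 Feb); uniform (1, 120) d̄; uniform-positive σ_ind ≤ 30 d,
  σ_obs ≤ 40%; N(0, 0.01²) for the per-percent and per-degree-day rate
  coefficients (one prior sd already allows a 2.7-fold duration change over
  a 100-unit covariate span, i.e. effects far beyond the plausible range, so
  the prior is diffuse *on the right scale* while keeping the derived
  completion-shift summary finite when the coefficient is weakly
  identified); N(0, 10²) days for the sex offset. All configurable.
* Sampling: adaptive random-walk Metropolis-within-Gibbs. Global parameters
  update one at a time (Robbins–Monro scale adaptation towards 0.44
  acceptance during warm-up); the per-hare effects update as a vectorised
  elementwise block (conditionally independent given the globals); and a
  joint *shift* move proposes `μ→μ+δ, ε→ε−δ`, which leaves the likelihood
  invariant and breaks the strong μ/ε posterior correlation — without it the
  population mean mixes an order of magnitude slower. Two chains from
  overdispersed starts; split-chain R-hat on μ_init, d̄, σ_obs and the
  derived completion, threshold 1.05; non-convergence is flagged on the
  returned fit, never silently discarded. Defaults 1500 warm-up + 1500
  draws per chain (~3 s for 30 hares on one CPU); the seed is a mandatory
  argument — no hidden global state.
* Intervals are equal-tailed 95% quantile intervals.
* Reaction norms: hares with ≥3 sightings in the same season of ≥2 years;
  per-hare-year least-squares change-point fits (coarse grid + Nelder–Mead
  polish) give the per-year initiation/completion and the between-year
  initiation difference in days.

## Behavioural analyses

* **Habituation truncation.** Response ~ attempt_index with a per-hare
  random intercept, fitted on all data with attempt ≤ k for each k from 3
  upward. The truncation index is the **largest k whose slope 95% interval
  includes zero** — robust both to isolated false positives at small k and
  to the lag before a real decline reaches significance. A decline
  significant at every k truncates at k = 3 with a warning; a flat response
  keeps everything. The interval criterion stands in for an unspecified
  notion of "significant decline" and is deliberately simple.
* **Concealment** is modelled as a continuous 1–4 response with identity
  link (ordinal-scale mixed models are a non-goal). Candidate fixed-effect
  sets exclude any pair with |r| ≥ 0.8; quadratic contrast appears only
  with its linear term; the null model is always included. AICc uses the
  observation count; the best set is ΔAICc ≤ 2. Fixed-effect uncertainty
  for the best model: 100 000 draws from the multivariate-normal
  approximation at the ML mode, summarised as 95% HPD intervals; the method
  is recorded on the output because it is an approximation to full
  posterior sampling. MixedLM fits try lbfgs first (25× faster here) and
  fall back through the default, cg and powell optimisers; degenerate
  (singular random-effect) fits are flagged but retained.
* **FID** is analysed on the approach-progress scale: progress = 20 − distance,
  so flight at 12 m is an event at progress 8 and "no flush" censors at
  progress 17. A flight recorded at the full 20 m is placed at progress
  0.25 (half the rounding interval) to avoid zero event times. Ties are
  common after metre rounding, hence the Efron approximation. AICc uses the
  number of events (the information-carrying unit of a partial likelihood).
  Proportionality is checked per term by score tests on scaled Schoenfeld
  residuals and reported, never fatal. Constant covariates are dropped with
  a warning. If the best model shows a monotone partial likelihood (a
  category with no events sends a coefficient to ±∞), it is refitted with a
  small ridge (0.1) and flagged. An in-package partial-likelihood evaluator
  (Efron/Breslow) provides the closed-form identities used by the tests,
  independent of the fitting library.
* **Resting spots.** Each qualifying sighting becomes nine rows (1 used +
  8 available); locations that are entirely snow-covered or snow-free carry
  no choice information and are excluded (the filter is idempotent). Snow
  and contrast are fitted separately. The marginal binomial GLM supplies
  the AICc comparison against the null, the presence-probability curve over
  snow 0–100% (delta-method CI) and the probability ratio between bare and
  fully snow-covered spots. Because the choice sets are 1-of-9, an exact
  conditional-logit fit stratified by location is always attached: it is
  the estimator consistent for a within-location preference when locations
  differ in overall snow (the marginal GLM attenuates towards zero in
  exactly that situation, a known property of used–available designs, which
  our recovery experiments reproduce). A variational Bayes mixed fit with
  nested hare/location intercepts is available behind `random_effects=True`.
  Complete separation is flagged.

## The synthetic-data generator

The generator emulates the study design the analyses assume, and its
defaults are the study conditions used throughout the tests:

* two sites whose generating phenologies are offset — the high-elevation
  site initiates the autumn moult 10 days earlier (day 55 vs 65 from 1 Aug)
  and the spring moult 30 days later (day 93 vs 63 from 1 Feb);
* base durations 39.9 d (autumn) and 41.9 d (spring); σ_ind = 5 d between
  hares; σ_obs = 8% scoring error, snapped to the legal grid (except in the
  exact noise-free limit σ_obs = 0, which reports the latent trajectory
  unsnapped so exactness can be asserted);
* rate coefficients chosen to reproduce the derived effect sizes a field
  study of this design reports: β_snow = 7×10⁻⁴ per % (a 100→0% snow change
  shifts spring completion by ~3 days), β_temp = 8×10⁻⁵ per degree-day
  (~1 day over the seasonal range), β_sex = +2 (females finish ~2 days
  earlier);
* weekly location attempts with detection probability 0.8; discrete weekly
  mortality hazard 0.0263 (~50% of hares survive a 26-week season,
  emulating heavy predation); fresh cohorts of 30 hares per site-year;
  collaring staggered uniformly over the year so attempt counts are not
  confounded with season;
* per-hare microhabitat snow offsets (sd 10%) around the site snow course,
  which feed both the observed snow scores and the true per-hare moult-rate
  covariate;
* daily site snow courses: a 0→100 step-ramp at onset and 100→0 at melt
  (high site: late Oct–mid May; low site: late Nov–mid Apr), with a
  configurable number of transient >30% fluctuations against the seasonal
  direction (early autumn snowfalls that melt out; post-melt spring
  storms), discretised to the 20% grid — plus the module's own excursion
  detector used to verify the count;
* behaviour: concealment from an ordered logit (season, site, linear +
  concave quadratic contrast, peak near +30% contrast); habituation as a
  latent level drop (1.5) plus slope (0.6/attempt) once a hare has been
  located more than 9 times; FID from a proportional-hazards draw on the
  approach (baseline rate 0.08/m, concealment −0.30/level, high site +0.64,
  summer +0.19, brown-on-snow −1.73 ≈ hazard ratio 5.6 for matched vs
  negatively mismatched, habituation onset 5); resting spots chosen among
  nine candidates with log-linear snow preference −0.016/%.

All randomness flows from one seed through named streams, so every stage is
independently reproducible and any dataset exactly regenerable from its
recorded truth. What the generator does **not** emulate: spatial movement
(pie-slice snow is local snow plus noise, not a landscape raster),
photoperiod mechanisms, observer identity, and year-to-year weather beyond
the scripted snow scenarios. Passing recovery tests therefore show the
estimators are correct *for data of this structure*; they cannot certify
robustness to field phenomena outside it.

## Validation experiments

`moultshift.validation` packages the experiments behind both the test suite
and `scripts/acceptance.py`: credible-interval coverage of generating
initiation/completion dates over 20 simulated replicates of the full
two-site design (coverage counted per quantity; two nominal-95% intervals
jointly cover only ≈ 90% even under perfect calibration); a brute-force
scipy summation oracle for the likelihood (1e-9); Cox null closed forms
(−Σ log risk-set size; the two-subject −log 2 case to 1e-12); a 2-D
grid-search MLE oracle for the resting-spot logit (1e-3); conditional-logit
recovery of the generating preference within 2 SE at 300 locations;
habituation-onset recovery (experiment design: 60 hares, attempts capped at
14, chosen for ~100% power at the generating effect size before the
experiment was frozen); exhaustive mismatch enumeration over all 48 legal
grid pairs; and null-effect calibration of the three behavioural intervals
(binomial band at 20 replicates). Replicate counts and problem sizes were
sized so the whole suite runs in ~2 minutes on one CPU.

## Known limitations

* The snow moult-rate effect is only weakly identified within a single
  site-year; its posterior is honest but wide, and the completion-shift
  summary relies on the weakly-informative rate prior for regularisation.
  Pooled multi-site fitting with group-specific initiation dates would
  sharpen it and is the natural next extension.
* Concealment is ordinal but modelled with an identity link; coefficients
  are on the 1–4 class scale.
* The variational mixed resting-spot fit (statsmodels Bayes mixed GLM) is
  approximate; the conditional logit is the estimator of record for the
  within-location preference.
* The habituation screen is univariate by design and will absorb any
  covariate that trends with attempt count if monitoring is not staggered
  in time.
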