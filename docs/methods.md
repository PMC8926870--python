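# Methods

`asfintake` estimates mean intake of seven animal-source foods (unprocessed
red meat, processed meat, seafood, eggs, milk, cheese, yoghurt) per country,
year (1990–2018) and demographic stratum from heterogeneous survey-stratum
summaries, and validates the whole machinery on synthetic worlds with known
truth.  This note records the model, its assumptions, the numerical choices,
and what the synthetic validation does and does not show.

## Stratification

A stratum is one cell of age band × sex × education (low/medium/high) ×
urbanicity (urban/rural).  The full surveillance grid uses 22 age bands
(`<1, 1-2, 3-4, 5-9`, then 5-year bands to `90-94`, `95+`): 264 strata.
Children are ages below 20, adults 20 and above; no band straddles that
boundary.  A compact 6-age-band grid (72 strata) is the default for
simulation studies, chosen so a full fit runs in seconds on one core.

## Harmonisation

Reported means are rescaled to an age-specific reference energy
(700 kcal/day below age 1; 1000 for 1–<2; 1300 for 2–5; 1700 for 6–10;
2000 for 11–74; 1700 from 75) by ratio: `adjusted = mean × ref(age)/energy`.
Ratio scaling is transparent, exactly invertible, preserves zeros and is
scale-equivariant; where a survey lacks an energy estimate the mean passes
through unchanged with a flag.  A band is mapped to the schedule by its
midpoint age (so the `1-2` band, midpoint 2.0, uses 1300 kcal/day).
Serving conversions use fixed portion sizes (g/serving): red meat 100,
processed meat 50, seafood 100, eggs 55, cheese 42, yoghurt 245, milk 245.
Plausibility caps are ten times the largest regional mean per food; values
above them are warnings, not rejections.

## Intake model

Observation `i` is a survey-stratum mean `y_i` (g/day, energy-adjusted).
With offset δ = 0.5 g/day,

    log(y_i + δ) ~ Normal(θ_i, s_i² + od_i·τ²)

`s_i²` is the delta-method sampling variance of the reported mean,
`(sd_i/√n_i)²/(y_i+δ)²`, floored at 1e-4 (SDs missing from a survey are
imputed from the food's median coefficient of variation).  `od_i` flags
surveys that are not nationally representative **or** not stratified by
fine age bands, sex, education and urbanicity; those receive the extra
study-level variance τ² (overdispersion), which down-weights them.

The linear predictor nests random effects globally, by region and by
country, with country time slopes centred at 2004:

    θ_i = α + u_r + u_c + (φ₀ + Δφ_c)(t−2004) + a_g + b·male + d_e
          + h·urban + γ'w_i + λ'z_ct

* `u_r ~ N(0, σ_r²)`, `u_c ~ N(0, σ_c²)`, `Δφ_c ~ N(0, σ_φ²)`.
* `a_g` (one per age band) carries a first-order random-walk smoothing
  prior with scale σ_age plus a weak ridge (precision 0.01) for the level;
  22 bands with sparse data need smoothing and the functional form is
  otherwise unconstrained.
* Education uses an orthonormal sum-to-zero contrast, so the three
  implied effects sum to zero in every draw.
* γ are bias coefficients for assessment method (FFQ, short questionnaire,
  household budget survey; 24-hour recall is the reference) and metric
  type (household vs individual); λ are optional country-year covariate
  coefficients.  Predictions are always at the reference characteristics,
  which is what makes "bias-corrected" well defined.
* Survey rows that collapse a dimension (e.g. sex not stratified) enter
  with the uniform average of the level codes of the covered categories —
  the exact regression representation of an aggregated observation under
  uniform within-cell weights.  The fit signature carries no population
  table, so uniform weights are the model's own assumption; the mismatch
  with a mildly non-uniform truth is at the percent level and is absorbed
  by τ for the surveys concerned.

Priors: half-normal on all scales (σ_r, σ_c: scale 1; σ_φ: 0.03/yr;
σ_age: 0.5; τ: 0.5); Normal(0, 10²) on α, Normal(0, 0.05²) on the global
slope φ₀, Normal(0, 1) on the remaining coefficients.  These are weakly
informative on the log scale, where a unit is roughly a 2.7-fold intake
ratio.

**Inference.**  Given the variance components the model is linear-Gaussian,
so the sampler is a collapsed Gibbs scheme: each of (σ_r, σ_c, σ_φ, σ_age,
τ) is slice-sampled on the *marginal* posterior with every location
parameter integrated out analytically, then the full coefficient vector is
drawn exactly from its multivariate-normal conditional.  Integrating out
the coefficients removes the centred-parametrisation funnel that cripples
naive Gibbs when random effects are only partially identified (e.g. a
country with one survey); variance-component effective sample sizes are
typically a large fraction of the retained draws.  Default: 4000 retained
draws over 2 chains after 500 warmup iterations; the R-hat gate (flagging,
not failing, at 1.1) is computed with arviz over all coefficients and
scales.  Everything is deterministic given the seed; per-chain and
per-stage seeds are derived by name hashing so one stage's stream is
unaffected by another's.

**Prediction.**  Per-stratum draws are `exp(θ) − δ` floored at zero, at
the reference survey characteristics.  A country without surveys is
predicted from its region with intercept/slope deviations sampled per draw
from the fitted N(0, σ_c²) and N(0, σ_φ²) — so it shrinks toward its own
region's mean and its interval widens accordingly.  Prediction outside
1990–2018 requires an explicit extrapolation flag.

## Trend model and combination

Food-availability series (per-capita g/day equivalents) carry annual time
signal the sparse survey inventory lacks.  They are fitted with a
varying-slopes model on the log scale:

    log A_ct ~ Normal(η_c + β_c(t−2004), σ_A²),  (η_c, β_c) ~ BVN(μ, Σ)

with the intercept–slope correlation ρ estimated across countries; the
two-dimensional partial pooling regularises both parameters.  All
conditionals are conjugate (Gaussian / inverse-Wishart ν₀ = 4 /
inverse-gamma), so this is a plain Gibbs sampler.  Countries with fewer
than three points contribute no likelihood and receive pooled-only draws,
with a warning.

The two models are combined at the slope level, per country and per
paired draw, by inverse-variance weighting:

    slope_d = (p_I·φ_d + p_T·κ·β_d) / (p_I + p_T)

with p the inverse posterior variance of each slope and κ a scaling from
availability trends to intake trends, estimated by through-origin
regression of posterior-median intake slopes on availability slopes
(overridable, as is the trend weight; weight 0 reproduces the intake model
exactly).  Combined draws are convex combinations, so they always lie
between the two inputs.  Countries without availability data keep the
intake slope.  Combining on slopes (rather than levels or predictions) is
a deliberate, configurable choice: it strengthens exactly the quantity the
availability data inform, without letting supply levels — a biased proxy
for intake — move intake levels.

## Aggregation

All aggregation is at the draw level: for each retained draw, stratum
predictions are averaged with population weights (sequentially accumulated
so results are reproducible by a scalar loop, bit for bit), and medians
with 2.5/97.5 percentile intervals (linear interpolation between order
statistics) are taken afterwards.  Draw-level nesting is exact: the global
draw-mean equals the population-weighted mean of regional draw-means,
which is *not* true of medians.

* Subgroup differences (A − B) use the comparator group — low education,
  rural, the 1990 baseline — as the relative denominator; the education
  contrast is high vs low with medium excluded entirely.
* Time changes weight both years with the 2018 stratum proportions, so
  demographic change cannot masquerade as consumption change.
* A difference is significant exactly when the 95% interval of the
  absolute difference excludes zero.
* Threshold counts (countries above/below a g/day or g/week bound, with
  their population share) use posterior-median national estimates.
* Food intercorrelations are Spearman rank correlations of national
  medians; constant columns yield missing entries.

## Cross-validation

Five-fold, at the survey level: all strata of a survey share a fold
(row-level splits would leak within-survey structure).  Held-out strata
are predicted at the survey's own characteristics — bias terms applied —
so predictions are on the same measurement scale as the observations they
are scored against (slope/intercept of observed-on-predicted, R², RMSE,
mean bias; per fold and pooled).  An optional stratified partition spreads
each region's or country's surveys across folds, the usual choice for
hierarchical data; the validation studies stratify by country so no
country loses most of its surveys to one fold.  Folds failing the
convergence gate are flagged in the output, never dropped silently.

## Synthetic worlds

The generator builds latent intake surfaces multiplicatively on the log
scale — global mean per food, region and country effects, an age curve
rising to a plateau at 25, sex/education/urbanicity multipliers, and
correlated country intercepts and slopes — then observes them through
configurable survey designs: assessment-method bias (24HR 1.0, FFQ 1.15,
ShortQ 0.9, HBS 1.1 — fixed synthetic truths for recovery tests, not
empirical estimates), lognormal sampling noise whose log-scale SD is
`cv/√n` (so the reported SD and n imply exactly the generating noise),
extra noise for non-representative or incompletely stratified surveys,
reported-energy jitter, and population-weighted collapsing of
unstratified dimensions.  Default effect sizes: region/country SDs
0.25/0.30 (log), sex ×1.1, education ×1.0/1.1/1.25, urban ×1.2, slopes
N(0.01, 0.012²) per year with intercept–slope correlation 0.6, survey CV
0.25 with n = 50 per stratum.  Population weights are products of
configured marginals (age pyramid, 50/50 sex, education 0.35/0.40/0.25,
urban 0.55, optionally ramping) with lognormal country totals.

The scaled-down study world is 3 regions × 4 countries × 6 age bands with
2 surveys per country — sized so the full validation battery runs in
minutes on one core; the 264-stratum grid and more regions are available
by configuration.

**What passing tests show, and don't.**  The generator draws from the same
family the model fits (lognormal noise, multiplicative effects, extra
variance exactly where the model puts τ).  Recovery within 15%, 95%-UI
coverage in the 90–98% band, and near-perfect noiseless cross-validation
therefore demonstrate that the estimation machinery is *correct and
calibrated under its own assumptions* — they do not certify performance
under real-world misspecification (non-lognormal errors, survey-level
correlated biases, informative survey placement, reporting heaping), which
no synthetic check can.

## Numerical and edge-case choices

* δ = 0.5 g/day; configurable.  Sampling-variance floor 1e-4 on the log
  scale keeps noiseless synthetic surveys numerically benign.
* Percentiles: linear interpolation; summaries require ≥ 100 draws.
* Zero-variance draw vectors give degenerate but valid intervals
  (lower = median = upper); constant chains report R-hat as not
  applicable rather than failing.
* Ties in Spearman correlations get average ranks (scipy).
* `n_draws` is the total retained across chains; chains receive
  `ceil(n_draws/n_chains)` and the pooled array is trimmed, so intake and
  trend draws pair one-to-one for slope combination.

## Known limitations

* Within-stratum intake *distributions* are out of scope; only means are
  modelled, so prevalence-type quantities are unavailable.
* Age and sex effects are global (not region-specific); country effects
  absorb residual differences.
* The energy adjustment is ratio-based; residual-based alternatives would
  need individual-level data the stratum summaries do not carry.
* Availability-to-intake scaling κ is a single global coefficient per
  food; food-specific waste/loss gradients across countries are not
  modelled.
* The full-scale grid with hundreds of countries is supported by the
  design but the collapsed sampler's per-iteration cost grows with the
  cube of the coefficient count; desk-scale studies keep it in seconds.
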