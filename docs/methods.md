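# Methods

`microgbd` is a desk-scale reimplementation of the estimation chain used
for global injury burden accounting: from cause-of-death observations and
non-fatal incidence data to internally consistent deaths, YLLs, YLDs and
DALYs by cause of injury and nature of injury.  Everything runs on a
synthetic world with known ground truth, so every stage can be tested for
parameter recovery and the chain as a whole for end-to-end identity.

## Cause-of-death ensemble

Cause-specific mortality is modelled per cause by an ensemble of covariate
submodels.  Every non-empty subset of the candidate covariates is crossed
with two model spaces — log death rate and logit cause fraction (deaths
over the all-injury envelope) — enumerated deterministically and optionally
capped.  Each submodel is a weighted least-squares fit in its transform
space with age-group and sex fixed effects, plus nested location random
effects (super-region → region → country).

Two estimation choices depart from a full mixed-model solver and are
deliberate simplifications at this scale:

- **Slopes by within-location estimation.**  Covariate and demographic
  effects are estimated with per-location intercepts absorbed.  With few
  countries, a pooled regression lets location effects leak into covariate
  slopes (they are confounded with the between-country component of any
  covariate); absorbing location intercepts removes that channel entirely
  and makes the fit exact when the generating model is within the family.
- **Random effects as shrunken residual means.**  The per-location
  intercept deviations are decomposed top-down into super-region, region
  and country effects, each shrunk by n/(n + κ) with κ = 5 (observations
  dominate the prior once a location has a handful of data points).  This
  reproduces the borrowing-of-strength behaviour of a nested mixed model
  without REML.

Zero-death cells are floored at half the smallest positive observed rate
before the log/logit transform; the floor is configurable.

Predictive validity uses test–train holdouts stratified by location-year
(whole strata held out together): RMSE in transform space, trend (share of
held-out adjacent-year first differences with the correctly predicted
sign; reported as undefined when no such pairs exist) and 95% interval
coverage, averaged over repeats.  The ensemble ranks submodels by
out-of-sample RMSE (ties broken by coverage) and weights rank r as
ψ^(m−r), normalised; ψ defaults to 2.5.  An optional trimming rule zeroes
the weight of submodels whose out-of-sample RMSE exceeds a multiple
(default 2×) of the best submodel's — the ensemble "may be a single
model" when one clearly dominates, which is also what makes the noise-free
identity exact.  Draws sample a submodel per draw by weight and add
Gaussian residual noise in transform space before back-transforming.

The submodel-recovery experiment (acceptance property) generates data from
a known ln-rate submodel that uses *both* candidate covariates, with an
envelope varying independently of the cause rate.  Competing submodels are
then either underfit (proper covariate subsets) or misspecified
(cause-fraction family), so out-of-sample RMSE should identify the truth;
the design was fixed before any results were measured.

## Consistency correction and YLLs

Independent cause models need not respect the hierarchy, so deaths are
rescaled top-down per draw and cell: level-1 groups proportionally to the
all-injury envelope, then each sibling set to its (already scaled) parent.
Aggregate causes absent from the input are synthesised as sums of their
children first.  A sibling set summing to zero under a positive parent
receives the parent uniformly and is counted in a diagnostic attribute.
Scaling is exactly conservative and idempotent.

The reference life table takes, per age group, the minimum mortality rate
across locations with population above 5 million, and converts it to
residual life expectancy with a standard abridged life table
(a(x) = half-interval; open-ended top interval with e = 1/rate).  YLLs are
deaths × residual life expectancy at the age-group midpoint (the open top
group uses its start plus its own expectancy implicitly through the
midpoint convention).

## Non-fatal chain

**Crosswalks.**  The reference case definition is inpatient care.
Table-derived category-to-inpatient ratios convert outpatient / formal
care / warranted-care observations by division (the inverse operation
multiplies); the applied factor is recorded on each row.  Blank cells in
the bundled coefficient table are a lookup error by design.

**Incidence and excess mortality.**  Inpatient incidence is fit with the
same log-linear machinery as mortality.  The excess-mortality hazard f
among the injured is constructed as csmr / max(i × acute window, 1e-8),
clamped to [0, 50]/year, which softly reconciles incidence, the acute
phase and corrected mortality without a full compartmental solver.
Incident cases that die during the acute window (default 28/365 years) are
removed by exponential thinning, i·exp(−f·w).

**Cause–nature apportionment.**  Only the most disabling nature per case
is modelled (10 candidate natures already admit 10! ≈ 3.6 million severity
orderings).  Per (cause, age, sex), probabilities over natures are
Dirichlet–multinomial posterior means (n_k + α)/(N + Kα) with α = 0.5 by
default, optionally pooling counts across adjacent age groups with a
triangular kernel (bandwidth two groups).  Rows are always on the simplex,
so splitting conserves incidence exactly.  A per-cause eligibility mask
can zero implausible natures before renormalisation; the default is
permissive.

**Short/long split and prevalence.**  Each nature carries a probability of
long-term disability: 1 for amputations, 0 for the four natures assumed to
have no lasting sequelae (foreign bodies in ear / respiratory /
GI-urogenital systems, superficial injury), and a configurable default of
0.5 elsewhere pending follow-up-study inputs.  Short-term prevalence is
incidence × mean duration, where the mean duration blends treated and
untreated durations by the treated fraction
π = clamp((HAQ − 30)/(95 − 30), 0, 1).  Long-term prevalence integrates
dP/dt = i(1−P) − (m + f_n)P with classical RK4 at step 0.1 years
(piecewise-constant annual rates, vectorised across series and draws),
initialised at the steady state of the first estimation year since the
pre-1990 epidemic history is unmodelled.  Short-term prevalence is then
subtracted from long-term prevalence, floored at zero and flagged — the
literal reading of the double-counting correction; whether the correction
should apply to overlapping person-time only is an open question upstream
and documented as such.

**YLDs and comorbidity.**  YLD = (P_st·dw_short + P_lt·dw_long) ×
population, with the bundled short-term weights and a configurable
long-term weight table (defaulting to the short-term value per nature, and
to chosen per-amputation values, since no location/year table is bundled).
Cause-level and nature-level results are the two marginals of one
cause–nature array and therefore always agree.  Comorbidity is adjusted by
microsimulation: individuals receive independent condition indicators; a
multi-condition individual's combined weight is 1 − Π(1 − dw_k),
attributed to conditions proportionally to dw_k.  In the pipeline the
conditions are the natures (prevalence summed over causes), simulated per
demographic cell with vectorised cohorts; the resulting per-nature
attenuation factors multiply the cause–nature YLD array so both marginals
stay consistent.  Attribution conserves the combined weight per individual
and never increases a YLD.

## Sexual violence

A non-fatal-only branch: past-year prevalence is modelled from survey rows
with a binomial logit GLM, with per-capita alcohol consumption as a
location predictor and a study-level indicator for surveys capturing
penetrative violence only.  The indicator enters as a downward shift, so
its coefficient is the definition bias; adjusted observations never fall
below the raw ones.  If every row is penetrative-only the bias is
unidentifiable and the fit refuses with instructions.  Prediction draws
sample the coefficient covariance.  Short-term disability is assigned per
prevalent case with a configurable weight (the default 0.10 is a
placeholder — no weight is bundled for this outcome); requesting deaths or
YLLs for this cause is a capability error.

## DALYs and summaries

DALY = YLL + YLD per draw and cell; non-fatal-only causes contribute YLDs
alone.  Cause-level results are aggregated up the tree so conservation
holds at every level.  Summaries report the draw mean with a 95%
uncertainty interval from the 2.5/97.5 percentiles (linear interpolation
between order statistics).  Age standardisation is a weighted sum over age
groups; the standard population is a config input with a uniform default.

## Synthetic world

The default world is desk-scale: 2 super-regions × 2 regions × 2 countries
(8 countries, populations 2–60 million, fixed age pyramid), 8 age groups,
both sexes, 1990–2017, six causes spanning the tree's shapes (road
injuries with two sub-causes; falls; drowning; foreign body in eyes as the
non-fatal-only cause) and eight natures from the bundled registry,
including one amputation and one no-long-term nature.  True mortality and
incidence surfaces are log-linear in two covariates with age, sex and
nested location effects (country random-effect SD 0.1 on the log scale) —
deliberately within the estimator's model family, so that estimation error
is attributable to the machinery rather than to misspecification.
Inpatient incidence intercepts are chosen so that *total* incidence
(inpatient plus expanded outpatient) lands in a realistic 0.005–0.03
events per person-year regardless of the cause's outpatient multiplier.
True cause–nature probabilities make severe natures rare (Dirichlet
concentration decaying with the disability weight), as in dual-coded
clinical data.  The all-injury envelope equals the sum of true
cause-specific deaths.  The full 38-cause / 47-nature registries are
available behind a config flag.

Simulators are Poisson (deaths, hospital counts), multinomial (dual-coded)
and binomial (surveys), all reproducible from (config, seed), each with an
`expected=True` switch that emits exact expected values — the
infinite-population limit used by the identity test.  What the generator
does **not** emulate: garbage-coded or ill-defined deaths, verbal-autopsy
misclassification, reporting gaps correlated with development, secular
trends in case definitions, or overdispersion beyond the optional
negative-binomial switch.  Passing tests therefore demonstrate correctness
of the estimation machinery under a well-specified data-generating
process, not robustness to the messiness of real registration data.

## End-to-end identity

With expected counts everywhere, a large dual-coded sample (50 000 per
cell, so the Dirichlet prior's α/N bias is negligible — dual-coded sources
are large administrative datasets, and the infinite-population limit is
applied to them like every other input) and comorbidity disabled (the
world's truth surfaces are defined pre-comorbidity; the adjustment has its
own closed-form and conservation tests), the pipeline reproduces the true
YLL/YLD/DALY surfaces to within about 0.3% in every cell — an order of
magnitude inside the 2% acceptance band.  The remaining error is random
effect shrinkage (≈1% of an effect whose SD is 0.1 in log space) plus draw
noise.

## Problem sizes

The test and acceptance runs use the desk-scale world throughout: ensemble
recovery uses 50 replicates of 224 country-year observations with 10
holdout repeats; the identity run uses 10 draws on the full 1990–2017
grid; sexual-violence recovery uses 50 replicates of 200 survey rows.
These sizes were chosen as the smallest at which the statistical
properties under test are stable.

## Known limitations

- No spatio-temporal smoothing stage and no REML mixed-model parity with
  production cause-of-death ensembles; holdouts are random stratified
  partitions rather than missingness-pattern knockouts.
- No full compartmental (ODE-constrained) incidence–prevalence–mortality
  fit; consistency enters through the constructed excess-mortality hazard.
- Single most-disabling nature per case; multi-injury disability is out of
  scope by design.
- Long-term disability weights and per-nature long-term probabilities are
  config inputs with documented defaults, not estimates.
- The location hierarchy is three levels; no subnational estimation.
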