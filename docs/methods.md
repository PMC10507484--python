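# Methods

## Submodels and coding

Two cause-specific Cox-form submodels drive everything: lung-cancer death
(LCDRAT-style) and all-cause mortality (ACM).  Covariates are coded per
the published schemes: log terms for age, BMI, quit-years (log of at
least one year, so current smokers and recent quitters code to zero),
years smoked and cigarettes/day; ordinal trends for education (1 = less
than 12th grade … 6 = graduate school) and family history of lung cancer
(0/1/2+ first-degree relatives); one-hot categories for pack-years
(lung-cancer model) and BMI (mortality model); binary indicators for sex,
low BMI, smoking more than a pack a day, and thirteen comorbidities.  The
"Asian or other" coefficient is applied to the `asian_american` input
level, mirroring the models' application to survey data.

Term values are stored raw (the education trend for a bachelor's degree
is 5); the linear predictor subtracts a fixed reference profile — a White
male current smoker of one pack/day for 20 years, age 62, BMI 22.5,
education 1, no comorbidities, assessed in 2015 — so the reference scores
exactly zero and a unit change in any term multiplies the hazard by that
term's published hazard ratio.  The mortality model's BMI categories
leave BMI = 35 unassigned in print; it is treated as part of the
">35" band.

Covariate terms, including log-age and calendar year, are frozen at entry;
attained age acts only through the baseline, so hazard ratios between
people are age-invariant during projection.  The calendar-year trend is
not projected forward.

## Baseline hazards

Only hazard ratios are published; baselines are this package's own
parameterization: annual Gompertz `h0(a) = λ·exp(γ(a−40))` over ages
40–100, strictly positive and nondecreasing.  Defaults: mortality
λ = 1.8e-3, γ = 0.085 (reference 62-year-old ≈ 1.2%/yr, doubling every
≈ 8 years); lung-cancer death λ = 2.7e-4, γ = 0.05 — deliberately shallow,
because the steep cross-sectional age gradient is carried by the log-age
covariate (HR 422.4 per log-year), leaving the baseline to express the
residual within-projection rise.  The no-race fixture files carry slightly
higher levels to absorb the removed race effect on average.  Baselines are
configuration: every correctness test runs against generator-truth
baselines, so conclusions do not depend on these defaults.

## Life table and screening benefit

Annual cycles from entry age to a 100-year cap (deaths forced by the cap;
remaining life is truncated).  Cause-specific decomposition per cycle:
`q_all = 1 − exp(−(h_LC + h_OC))` split in proportion to the hazards
(exponential within-cycle split).  The other-cause hazard is
`h_OC = max(h_ACM − h_LC, 0)`: the published models do not expose the
lung-cancer model's own competing-risk coefficients, so the mortality
submodel net of the lung-cancer hazard is used, with the clamp at exactly
zero (rather than a small ε floor) so that the no-competing-risk limit is
exact; the division guards against 0/0 separately.  Attending screening
multiplies `h_LC` by 0.796 for the first five cycles only, leaving
`h_OC` untouched.  Life expectancy uses the standard actuarial half-cycle
correction, `LE = Σ S(t)(1 − q_all(t)/2)`, and the benefit is
`365.25 × ΔLE` days.  Both the cap and the half-cycle rule are exposed as
arguments.

## Eligibility strategies

The 16.2-day threshold is inclusive (`benefit ≥ 16.2` — "at least").
Counterfactual substitution changes only the race field; every other
covariate is untouched.  `counterfactual_acm` substitutes White race into
the mortality submodel only (the lung-cancer risk keeps the person's own
race), `counterfactual_full` into both; each takes the maximum of the
own-race and substituted benefits, which guarantees monotonicity:
eligibility can only expand, and White records are bit-for-bit unchanged.
Ties at the maximum are reported as own-race.  Population summaries are
survey-weighted; groups absent from a cohort are omitted rather than
reported as zero.  Preventable-burden accounting values everyone under
the standard (with-race) models: preventable deaths are the weighted sum
of five-year lung-cancer risk differences without vs with the screening
effect among the strategy-eligible, and gainable life is the weighted sum
of standard-model days gained.

## Calibration

E/O = (Σ w·predicted 5-year risk) / (Σ w over target events within the
horizon).  Expected counts are censoring-invariant by construction.  The
95% CI uses a log-normal approximation with Poisson variance on the
*unweighted* event count — the standard choice for standardized ratios;
the published analyses do not state their CI method, so this is an
approximation.  AUC is the survey-weighted concordance of predicted risk
for the within-horizon event; records censored before the horizon without
an event are excluded (competing-cause deaths count as known non-events
for the lung-cancer target).  Inverse-probability-of-censoring weighting
is a noted extension, not implemented.  Risk quintiles use weighted
quantile cut points with stable-rank tie resolution; an all-tied risk
vector collapses to a single bin flagged as degenerate.  The five-year
all-cause risk reported for the mortality submodel is `1 − S(5)` from the
same cause-specific construction, so calibration closure against the
simulator is exact in expectation.

## Cox refitting

Refits use age as the time scale: subjects enter risk sets at entry age
(left truncation) and exit at death or censoring age; ties use the Efron
approximation; convergence tolerances are tightened well below the
default so tiny-sample fits agree with a brute-force partial-likelihood
enumeration to 1e-6.  Structurally constant columns (the screening
indicator, race dummies in a single-race cohort) are dropped and
reported.  The baseline hazard is a Breslow estimator computed in-package
with risk sets that honour delayed entry (suffix sums over sorted entry
and exit ages), rescaled to the reference profile, binned to annual
hazards and smoothed by event-weighted least squares on the log scale to
the Gompertz form; with fewer than three informative age bins a flat
hazard is returned.  Survey weights are accepted as frequency weights but
fitting defaults to unweighted, with weights applied at the
population-summary stage.

## Synthetic cohorts

The generator emulates a survey population of ever-smokers aged 50–80:
race mix (9.7/2.9/8.7/78.7%), and per-race marginals for sex, age bands,
smoking status, pack-year and quit-year categories, BMI classes and
emphysema follow the published weighted characteristics.  Within race,
covariates are sampled independently given those marginals — no copula —
except for deterministic smoking-history links: quit-years are zero for
current smokers; years smoked equal age minus a uniform 15–20 start age
minus quit-years (minimum 3); cigarettes/day derive from the sampled
pack-year category and duration, clipped to 2–60, with pack-years then
recomputed exactly as intensity × duration / 20.  Within-category values
are uniform (pack-years ≥ 70 capped at 120).  Education, family history,
the remaining comorbidity prevalences and the gamma(4, 0.25) survey
weights are invented defaults with no published marginals.  Outcomes are
drawn from configurable true submodels by annual competing-risks
simulation on the age scale with the same exponential within-cycle split
the life table uses, then administratively censored (exactly five years,
or a horizon with uniform staggered entry).  A single seed feeds a
per-stage splittable generator, so covariates and outcomes are
independently reproducible and cohort CSVs are byte-identical across
runs.

What passing tests on these cohorts do *not* show: agreement with real
joint covariate distributions, survey design effects (strata/PSUs),
item missingness, or the true values of the unpublished baselines.
Qualitative conclusions (signs of miscalibration, direction of
eligibility shifts) are the transferable results; magnitudes are specific
to the synthetic conditions.

## Monte-Carlo verification scales

The life-table benefit is verified against a one-million-path simulation
of the same discrete death process per profile, with common random
numbers across the screen/no-screen arms, to three standard errors.
Calibration closure is checked on a 50 000-person cohort with the
observed count averaged over outcome replications until every
race/ethnicity group accumulates at least 15 000 lung-cancer events,
driving the Monte-Carlo standard error of each E/O below 1% — smaller
than the ±3% closure band being asserted.  Training cohorts for the
refit-based checks use 20 000 subjects each (a trial-like cohort aged
55–74 for the lung-cancer model; a survey-like cohort aged 40–80 with
staggered 1–18-year follow-up for the mortality model).

## Interfaces

Cohorts are strict-header CSV (UTF-8, empty cell = missing; missing
values are errors unless complete-case filtering is requested); models
are JSON (`outcome`, `includes_race`, `coding_scheme`, log-HR
`coefficients`, Gompertz `baseline`); reports are tidy CSV plus a JSON
manifest with package and library versions and input digests, written
deterministically.  Config files for the generator are JSON; two fixture
configs ship with the package (`nhis_like_small`, n = 5000 with survey
weights; `plco_like_small`, n = 10 000, trial-like).  The CLI subcommands
(`simulate`, `refit`, `calibrate`, `eligibility`, `compare`) are thin
wrappers over the library; no plotting is built in.

## Known limitations

- The other-cause hazard construction is an approximation to the original
  lung-cancer model's unpublished competing-risk component.
- Whether the original benefit model uses a half-cycle correction and a
  100-year cap is not stated; both are defaults here, exposed as options.
- The E/O confidence-interval method and the AUC censoring treatment are
  this package's documented choices, not the published ones.
- Survey-weighted fitting uses frequency-weight semantics; no
  design-based (Taylor-series) variances.
- Multiple imputation is out of scope; records with missing covariates
  are rejected or dropped.
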