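# Methods

This note documents the models implemented in `demproj`, the assumptions
behind them, the synthetic world they are tested against, and the numerical
and design choices that were genuinely open.

## 1. Scope and structure

The package is an end-to-end re-implementation of a dynamic
dementia-projection analysis for an England-and-Wales-style population:

1. **`cohort`** — a synthetic six-wave biennial ageing panel (2002–2012,
   auxiliary wave in 2014) with known ground truth, plus stylised
   mortality-rate series and an age–sex population grid;
2. **`ascertain`** — the operational dementia case definition (cognitive
   test batteries, ADLs, IQCODE, doctor diagnosis);
3. **`trends` / `jointmodel`** — three calendar-trend estimators of
   dementia incidence: naive discrete-time, competing-risks, and a
   shared-random-effects joint model correcting for informative dropout;
4. **`calibration`** — eight-state transition-probability estimation,
   starting prevalences, state-specific mortality, mortality projection,
   and assembly of calendar-indexed one-year transition probabilities;
5. **`engine`** — the annual cohort-projection engine (2006–2040);
6. **`uncertainty`** — Monte Carlo probabilistic sensitivity analysis and
   the scenario battery.

Real survey microdata and official mortality/population series are not
bundled; the synthetic generator produces inputs with the statistical
structure the downstream analysis assumes, under known parameters, so that
every estimator can be validated against its own ground truth.

## 2. The synthetic cohort

**Latent cognition.** Each person carries a one-dimensional latent cognitive
score (in units of the reference-population SD),

&nbsp;&nbsp;c_i(t) = g(age_i(t)) + x_i'β + b_{0i} + b_{1i} t + γ_cal (year − 2006),

where g is a quadratic in *attained* age (−0.32 and −0.15 per decade at the
linear and quadratic terms, centred at 65), x_i carries sex, education and
midlife risk factors, t is time since study entry, and (b0, b1) ~ N(0, Σ)
with SDs 0.50 and 0.045 and correlation −0.25. Writing the age profile in
attained age makes cross-sections at a given age stationary: long-enrolled
participants and fresh recruits of the same age differ only through their
mean-zero random effects. (An earlier design with entry-age profiles plus
trajectory curvature leaked deterministic time-in-study effects into the
calendar dimension and biased every marginal trend estimator; this is the
main reason the attained-age form was adopted.) After true dementia onset
the *observed* trajectory additionally declines by 0.45 SD/year — dementia
accelerates decline — while the pre-onset process that drives onset risk
stays linear.

**Observed scores.** Six test scores (orientation; immediate and delayed
recall; fluency; numeracy at waves 1, 4, 6; literacy at wave 6) equal the
effective latent value plus a domain shift and N(0, σ_d²) noise with σ_d
between 0.40 and 0.50 (test–retest reliability ≈ 0.85). Items are missing
at 2% each; severely impaired participants switch to informant (proxy)
interviews with an IQCODE score increasing in impairment.

**Dementia onset (ground truth).** Per two-year epoch, for participants
whose latent value lies below a threshold (0.75 SD), the onset log-odds are

&nbsp;&nbsp;logit P(onset) = a₀ + a₁(age−80) + a₂(age−80)² + a_f·female +
β_cal(year−2006) + α_v c_i(t) + α_s ċ_i(t) + γ' r_i(t),

with α_v = −0.4, α_s = −4, a₁ = 0.10/yr, a₂ = −0.002, and time-varying risk
factors r (current smoking, physical inactivity, uncontrolled hypertension).
The intercept and sex effect are calibrated so that ground-truth incidence
at 2010 among those aged 50+ is ≈ 14.3 (men) and 17.0 (women) per 1000
person-years — the published dropout-corrected rates this package treats as
its study conditions. Crude *ascertained* incidence is lower (≈ 10–13 per
1000), mirroring the crude-versus-corrected gap in real panels.

**Total versus direct trend.** The configured per-year odds ratio (default
0.973) is the *total* calendar trend. Part of it is mediated by secular
improvement of the time-varying risk factors; the generator computes the
analytic mediation from the configured prevalence trends and multiplies it
by a calibrated realisation factor (0.6; cohort turnover and event-pool
composition damp the plug-in formula) before subtracting it from the total
to obtain the direct calendar coefficient. With the default settings the
realised mediation is ≈ 25% of the total trend.

**Mortality, CVD and dropout.** Two-year cause-specific death probabilities
are logistic in age (Gompertz-like), sex and calendar (CVD falling ≈ 4%/yr
in men, 3.6%/yr in women; non-CVD ≈ 1%/yr), with log-odds increments for
CVD status, cognitive impairment, and dementia (+2.2 non-CVD, +1.2 CVD —
mean survival with dementia ≈ 4 years, the short side of the literature,
consistent with a moderate-to-severe operational definition). CVD incidence
declines in parallel with CVD mortality. Panel dropout is logistic per epoch
with baseline 0.11 and +0.7 log-odds per SD of latent *decline* — strongly
informative attrition, chosen so the naive trend estimator is visibly biased
(≈ one OR point) and the correction is a meaningful test.

**Entry equilibration.** Every recruit's pre-entry disease and mortality
history from age ~50 is simulated with the same models (calendar effects
clamped 20 years back), redrawing the latent path of candidates who die
before recruitment. The entry cross-section is therefore the model's own
survivor equilibrium; without this step the first study epochs harvest an
artificial stock of near-onset individuals and fake a steep incidence
decline.

**What the generator does not emulate.** Survey weights (a unit weight
column is emitted), geographic or household structure, item-level test
discreteness, returning dropouts, and migration. Its dementia burden is
*higher* than England-and-Wales reality — pinning the corrected incidence
at 14.3/17.0 per 1000 PY in a threshold world with absorbing operational
caseness yields ≈ 15% crude dementia-state prevalence at ages 50+ versus
the ≈ 3.5% of the real study. Absolute projected counts are therefore
larger, and growth ratios smaller (prevalence saturation at old ages leaves
less room for ageing-driven growth), than the published projections; the
quantities that transfer are trend estimates, scenario orderings and ratios,
and standardised-prevalence trends.

## 3. Case ascertainment

Domain z-scores standardise each test against the ages-50–80 reference
population of the same education level; domain composites (concentration =
orientation; memory = mean of recalls; executive = mean of fluency,
numeracy, literacy where offered) are re-standardised within
(education × availability pattern). An assessment with fewer than three
answered tests is invalid. A domain is impaired at z ≤ −1.5 (boundary
inclusive); cognitive impairment requires two or more impaired domains
*among those observed* (the handling of partially missing domains is a
documented choice, flagged per observation via `n_domains_observed`).
Impairment is rescinded as transient when the mean standardised score rises
by ≥ 1 SD at the consecutive wave; functional impairment (≥ 1 of 7 ADLs) is
transient when it occurs at a single wave with full recovery at all later
observed waves. The auxiliary wave (2014) only resolves transience at the
final analysis wave — it never contributes impairments or cases of its own.

Caseness requires (cognitive impairment and functional impairment at the
same wave) or (IQCODE ≥ 3.6, inclusive, and functional impairment) or a
reported doctor diagnosis; the reported route follows the precedence
doctor-diagnosis > IQCODE > tests. Onset is dated to the mid-point between
the ascertaining wave and the latest previous assessment; caseness that
hinges on the numeracy test is dated to the mid-point of consecutive
numeracy-bearing waves (1→4, 4→6). Cases at a person's first observed wave
are prevalent-at-entry and excluded from incidence analyses. Missing IQCODE
never excludes; it simply cannot establish the IQCODE route.

## 4. Trend estimators

Events are interval-censored at two-year waves, so all estimators are
discrete-time per-epoch analogues of the usual continuous-time models
(a deliberate design decision: the discrete-time likelihood is exact for
biennial panels, and its odds ratios convert directly to transition
probabilities).

**Naive.** Logistic regression of incident dementia per epoch on age, age²,
sex, their interactions, and calendar year. Everyone interviewed at the
epoch's first wave and dementia-free contributes; deaths contribute their
final epoch as non-events (the analogue of uninformatively censoring deaths)
and dropouts are censored at the last interview. Calendar time is measured
in years, so the fitted coefficient is the per-year log odds ratio; with
`time_unit="epoch"` the fitted two-year OR is the square of the reported
per-year OR.

**Competing risks.** The same person-epochs fitted as a multinomial
(none / dementia / death). Death becomes a modelled outcome instead of a
censored non-event; since deaths decline over calendar time, their presence
in the naive denominator mechanically flattens the naive trend, and the
multinomial's dementia-versus-none coefficient is systematically steeper.
Model-implied cumulative incidence over a horizon is available via
`cumulative_incidence`.

**Joint model.** A linear mixed model for the mean standardised cognitive
score (fixed effects: entry age, entry age², time, time², sex, calendar
year, education, midlife obesity/hypertension/diabetes; random intercept
and slope on time) is fitted jointly with discrete-time event submodels
sharing the random effects. The default association is on the random
effects themselves: the dementia submodel's log-odds add α_v(b₀ + b₁t) +
α_s b₁ to a covariate term that includes age, sex, calendar, education,
midlife factors and current risk factors. The *current-value* association
(α on m(t) and m′(t) including the fixed parts) is available as an option,
but with one dominant recruitment cohort the deterministic part of m(t)
duplicates the age/calendar covariates and creates a likelihood ridge along
which the calendar coefficient trades off against the association
parameters; the random-effects association is the same generative model
reparameterised with the deterministic parts absorbed into covariates, and
is much better identified here.

Because both attrition and death select on the latent trajectory, censoring
is not ignorable for the longitudinal-plus-dementia likelihood alone. Two
auxiliary discrete-time submodels sharing the random effects are therefore
included by default: all-cause death (risk epochs continue after dropout —
vital status is registry-observed) and panel dropout. They contribute
likelihood factors that tilt each person's random-effect posterior the way
their observed attrition/survival history implies.

*Estimation.* Conditionally on the longitudinal data the random effects are
exactly Gaussian, so the marginal likelihood factorises as L_LMM ×
E_{b~N(b̂,V)}[L_events(b)], with the first factor closed-form and the
expectation evaluated by product Gauss–Hermite quadrature centred on the
exact per-person posterior (adaptive by construction; 9 points per
dimension by default, and 5 are ample in practice — the multi-seed study
uses 5 for speed). An EM algorithm with closed-form variance updates and
single damped Newton steps for the coefficient blocks maximises the
likelihood; the log-likelihood path is monitored and non-convergence is
flagged, never silent. Association and calendar functionals stabilise well
before full convergence (~45 iterations suffice). Standard errors for the
dementia submodel come from the final expected-information matrix — an
approximation that understates posterior-propagation uncertainty; the
trend's headline confidence interval instead comes from the prediction
regression below.

*Prediction and extraction.* For every non-prevalent participant alive and
dementia-free at an epoch start — including epochs after dropout, with
risk factors carried forward from the last interview — the fitted model
yields the conditional probability of incident dementia in that epoch,
integrating the person's tilted posterior and conditioning on being
event-free so far. The calendar trend is then the coefficient of calendar
year in a linear regression of the predicted log-odds on sex, age, age²,
their sex interactions, and calendar year; the risk-factor-adjusted variant
adds the time-varying risk factors, and the attenuation is
100 × (1 − β_adj/β_unadj).

*What the correction achieves, and its limit.* In the canonical 20-seed
study (n ≈ 15,000 per seed, true total OR 0.973, informative dropout on)
the naive estimator averages ≈ 0.961 (a −0.012 attrition bias: decliners
leave the panel before their onset can be ascertained), the competing-risks
estimator is uniformly steeper in the mean, and the corrected estimator
averages ≈ 0.967 (−0.006). The residual is structural rather than
numerical: ascertainment detects onset one to two waves late, so events
among fast decliners who leave during the detection window are absent from
*any* fit, and posterior shrinkage bounds how far individual predictions
can be extrapolated for thinly observed dropouts. The correction recovers
roughly half to two-thirds of the attrition bias — clearly less biased than
the naive estimator, and within ±0.01 of the truth.

## 5. Calibration of the multi-state model

**States.** 1 healthy; 2 CVD; 3 CIND; 4 CIND+CVD; 5 functional impairment
(no dementia, no CVD); 6 dementia; 7 dementia+CVD; 8 functional impairment
with CVD; plus CVD and non-CVD death. This is the only labelling consistent
with "6 and 7 are dementia, 5–8 are functional impairment, dementia implies
functional impairment". Dementia and CVD are absorbing (no recovery);
CIND and functional-impairment recovery are allowed (transience is real in
panel data), and 5→6 / 8→7 progression is allowed — all three choices are
configurable because the source structure does not pin them down.

**Transition probabilities.** Pooled two-year wave pairs (one observation
per person-epoch) feed destination-specific logistic models with terms for
age, sex, age×sex and the initial state; destinations in the CIND states
add age² and age²×sex. Margins are evaluated on the single-year age grid
35–100+, clipped into rows that sum to one with the stay probability as
residual. Two-year probabilities convert to one year via
TP = 1 − exp(ln(1 − P)/2) (P = 1 maps to 1 by continuity). Separation in a
destination model falls back to a weakly penalised fit; empty destinations
get probability zero with a warning.

**Starting prevalence.** Person-wave states pooled across waves are
attributed to 2006 and smoothed per sex by one-vs-rest logistic fits in age
and age², renormalised across states; below the observed age range the
disease-state prevalences taper smoothly (quadratic) to zero at age 35.

**State mortality.** Per-cause logistic models of two-year death with
age, sex and state indicators give per-state odds ratios (reference:
healthy). States with no observed deaths fall back to the pooled
impaired-state log-OR with a warning.

**Mortality projection.** Log-linear per-stratum extrapolation of the
historical rate series (≥ 10 years required), behind a surface interface so
a more elaborate age-period-cohort backend could be substituted; 5-year
bands interpolate to single ages by a monotone PCHIP spline on the log
rate. Rates convert to annual probabilities via q = 1 − exp(−rate).

**Calendar effects.** For each year to the horizon: dementia- and
CIND-incidence entries are scaled on the *odds* scale by OR^(year−2006);
CVD-incidence entries follow the age-standardised CVD-mortality index of
that year (frozen after the freeze year in that scenario); death entries
apply the state odds ratios to the year's projected cause-specific rates,
anchored by solving (Newton, per age–sex–cause cell) so the
prevalence-weighted mean over states matches the population rate. Odds
scaling and the two-year→one-year conversion commute to < 1e-3 for P < 0.3
per year of trend (the gap grows to ≈ 2.3e-3 when a full decade of trend is
applied in one factor).

## 6. Projection engine

Annual iteration: apply the year's transition probabilities, advance age by
one year (100+ is an open band), inject the entering cohort of 35-year-olds
into the healthy state, accumulate cause-specific deaths. No half-cycle
correction (plain annual iteration is the modelled design); deaths belong
to the year of the transition; transition-then-age ordering keeps the entry
cohort defined at exact age 35. Outputs per year: state counts; dementia
counts; crude prevalence for ages 50+/65+ by sex; age-standardised
prevalence using the modelled population of the standard year (2015 by
default) as weights; deaths; and period or cohort life expectancy and
disability-free life expectancy (states 1–4) by unit-mass cohort
simulation, holding the final year's probabilities beyond the horizon.
Person conservation (entrants + initial = alive + cumulative deaths) holds
to < 1e-8 relative at every year.

## 7. Uncertainty and scenarios

Parameter draws are multivariate normal at the *coefficient* level — every
transition destination model, the state-mortality coefficients, and the
calendar-trend log-odds (SE implied by its CI) — so derived probabilities
stay internally consistent within a draw; non-PSD covariances are repaired
by eigenvalue clipping with a warning. Each of the 1000 default iterations
rebuilds the transition set and re-runs the projection; uncertainty
intervals are empirical 2.5/50/97.5 percentiles (not normal
approximations). Failed draws are logged and excluded; more than 5%
failing is an error. A single top-level seed determines the entire draw
stream. The scenario battery comprises: the estimated trend, fixed 2%/yr
and 1.1%/yr declines, no decline, and the estimated trend with CVD
incidence frozen after 2014.

## 8. Problem sizes and numerical settings

The default panel is 15,000 participants (9,600 at wave 1; refreshment of
1,200/2,700/1,500 at waves 3/4/6). The recovery study uses 20 seeds at this
size with 5-point-per-dimension quadrature and a 45-iteration EM cap; the
acceptance script adds a single-seed full calibration, the five-scenario
battery to 2040, and a 1000-draw sensitivity analysis. Logit clipping for
the prediction regression uses ε = 1e-6; Newton steps are damped to ±1
(coefficients) and ridge-stabilised at 1e-8; 2×2 covariance algebra is
closed-form throughout.

## 9. Known limitations

- The synthetic world's dementia burden exceeds the real population's (see
  §2); absolute projected counts are upper-shifted and growth ratios
  damped accordingly.
- The joint model corrects one-half to two-thirds of the attrition bias in
  this world (detection lag; posterior shrinkage); the residual is
  quantified in the acceptance outputs rather than hidden.
- Realised risk-factor attenuation of the calendar trend (~14%) falls short
  of the ~25% analytic mediation because the operational case definition
  dilutes fitted risk-factor coefficients and dropouts' covariates are
  carried forward.
- Event-submodel association parameters (α_v, α_s) are weakly identified
  individually (their predictive functional is what is stable); their
  reported standard errors are expected-information approximations.
- The CVD-freeze scenario is nearly neutral for dementia counts in this
  world (-1% to +1%): freezing the CVD-incidence decline adds both
  competing mortality (fewer survivors at risk) and CVD-state person-years
  with slightly higher dementia transition probabilities, and the two flows
  almost cancel. A world in which CVD raises mortality more, or dementia
  risk less, would reproduce the sizeable "fewer cases under frozen CVD"
  effect instead.
- The mortality projector is deliberately a log-linear trend model; cohort
  effects in mortality, migration, and severity-stratified transitions are
  out of scope.
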