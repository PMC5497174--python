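# demproj

Dementia-burden projection for England-and-Wales-style populations:
dropout-corrected incidence trends from a biennial ageing panel, feeding an
eight-state annual Markov cohort model with Monte Carlo uncertainty.

## The problem

How many people will live with dementia in 2040? Simple projections that
hold age-specific prevalence fixed only track population ageing. A credible
forecast has to combine three moving parts at once: a *declining*
age-specific dementia incidence, *declining* mortality (which enlarges the
pool of old people at risk), and changing cardiovascular disease (which
shares risk factors with dementia and competes through survival). And the
incidence trend itself is hard to estimate from panel data, because people
in cognitive decline drop out of studies before their dementia can be
ascertained — naive estimators are biased by exactly the people they lose.

`demproj` implements that full analysis as a tested pipeline for
epidemiologists and health-policy modellers. Because the original microdata
(a national ageing panel and official mortality series) are restricted,
the package ships a first-class synthetic-data generator that reproduces
the statistical structure of such a panel under known ground truth, so
every estimator in the chain is validated against parameters it is supposed
to recover.

## Models

**Case ascertainment.** Dementia is defined operationally per wave:
impairment (z ≤ −1.5 against the education-matched ages-50–80 reference) in
≥ 2 cognitive domains *plus* impairment in ≥ 1 activity of daily living, or
an informant IQCODE ≥ 3.6 plus ADL impairment, or a reported doctor
diagnosis; one-off transient impairments are rescinded. Onset is mid-point
dated between waves.

**Incidence trend.** Three discrete-time per-epoch estimators of the
per-year incidence odds ratio e^γ: a naive logistic model (deaths censored
uninformatively, dropouts censored at last interview); a multinomial
competing-risks model (death as an outcome); and a shared-random-effects
joint model,

    y_ij = x_ij'β + b_0i + b_1i t_ij + ε_ij,          b_i ~ N(0, Σ)
    logit P(onset_ik) = w_ik'γ + α_v (b_0i + b_1i t_ik) + α_s b_1i

fitted jointly with auxiliary attrition and survival submodels sharing b_i
(censoring selects on the trajectory, so it is not ignorable without them).
Estimation is EM with adaptive Gauss–Hermite quadrature centred on the
exact per-person longitudinal posterior. Individual predictions for
everyone alive — including those lost to follow-up — are regressed
(log-odds scale) on age, sex and calendar time to extract the corrected
trend; adding time-varying risk factors gives the adjusted trend and the
attenuation share.

**Projection.** Pooled two-year transitions between eight health states
(cardiovascular disease × cognitive impairment × dementia × functional
impairment, plus two death states) are estimated by logistic regression,
converted to one-year probabilities via TP = 1 − exp(ln(1−P)/2), trended on
the odds scale (incidence by the estimated OR, CVD in parallel with
projected CVD mortality, deaths anchored to projected population rates via
state odds ratios), and iterated annually from 2006 with entering cohorts
of 35-year-olds. Outputs: counts, crude and age-standardised prevalence,
deaths, (disability-free) life expectancy, and 95% uncertainty intervals
from a 1000-draw coefficient-level Monte Carlo.

## Worked example

```python
import warnings
from demproj import (CohortConfig, generate_cohort, ascertain,
                     fit_naive_trend, observed_incidence)

cfg = CohortConfig(n_core=4000, seed=7,
                   recruitment_waves=((3, 2006, (50, 55), 500),
                                      (4, 2008, (50, 74), 1100),
                                      (6, 2012, (50, 55), 600)))
panel = generate_cohort(cfg)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = ascertain(panel.panel)
statuses = result.statuses
print(f"participants: {panel.panel['person_id'].nunique()}")
print(f"dementia cases: {int(statuses['is_case'].sum())} "
      f"({int(statuses['prevalent_at_entry'].sum())} prevalent at entry)")
inc = observed_incidence(panel.panel, statuses)
print(f"crude incidence 2010, per 1000 PY: men {inc['m']:.1f}, women {inc['f']:.1f}")
trend = fit_naive_trend(panel.panel, statuses).trend_
print(f"naive per-year incidence OR: {trend.odds_ratio_per_year:.3f} "
      f"(95% CI {trend.ci95[0]:.3f}-{trend.ci95[1]:.3f})")
print(f"implied relative annual decline: {trend.relative_annual_decline_pct:.1f}%")
```

prints

```
participants: 6200
dementia cases: 761 (337 prevalent at entry)
crude incidence 2010, per 1000 PY: men 11.5, women 10.5
naive per-year incidence OR: 0.956 (95% CI 0.922-0.991)
implied relative annual decline: 4.4%
```

Read: in this 6,200-person synthetic panel the operational definition finds
761 cases; crude observed incidence around 2010 is ≈ 11 per 1000
person-years; and the *naive* estimator sees incidence falling 4.4% per
year — steeper than this world's true 2.7%/year decline, because
informative dropout removes decliners from observation. The joint model
(`fit_all_trends`, which also returns the competing-risks and corrected
estimates) exists to repair exactly that gap. From there,
`demproj.pipeline.calibrate` plus `demproj.uncertainty.run_scenarios`
project the population to 2040 under the scenario battery (estimated trend,
2%/yr, 1.1%/yr, none, CVD freeze).

A command-line interface mirrors the pipeline stages:

```bash
demproj simulate-cohort --seed 1 --out-dir out
demproj ascertain --panel out/panel.csv --out-dir out
demproj fit-trends --seed 1 --out-dir out
demproj scenarios --seed 1 --out-dir out
```

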