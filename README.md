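# gcomprisk

Marginal, public-health-interpretable effect estimates for time-fixed
exposure–outcome data, by **parametric g-computation** with ordinary GLMs
and **percentile-bootstrap** confidence intervals.

Epidemiologic results are often reported as covariate-conditional odds
ratios because logistic regression hands them over for free — even though
risk differences, risk ratios and the number needed to treat are what
public-health audiences can actually act on, and even though the odds
ratio badly overstates the risk ratio when the outcome is common.
`gcomprisk` is for analysts of cohort and trial data who want those
interpretable measures without giving up the statistical convenience of
standard GLMs.

## The method

For a binary exposure $A$, outcome $Y$ and covariates $W$, the target is
the average treatment effect

$$\varphi_{ATE} = \sum_w \left[E(Y^{A=1} \mid W=w) - E(Y^{A=0} \mid W=w)\right]\Pr(W=w),$$

the exposure contrast standardized to the covariate distribution of the
study population. The plug-in estimator runs in three steps:

1. **Fit** a GLM of the outcome on exposure and covariates
   (binomial/logit for binary outcomes; Poisson or negative-binomial/log
   for counts and person-time rates, with a log person-time offset;
   gaussian/identity for continuous outcomes).
2. **Predict** every observation's outcome under each exposure regime —
   the dataset is cloned with the exposure column forced to each level,
   and for rate outcomes the offset is set to the reporting denominator
   (e.g. 100 person-years).
3. **Average and contrast** the predictions: the per-regime means are
   marginal mean outcomes, and their differences/ratios give the risk
   difference, risk ratio, odds ratio, NNT, incidence rate
   difference/ratio, or mean difference.

Because the coefficient standard errors of the underlying model do not
describe these standardized quantities, 95% confidence intervals come
from the 2.5th/97.5th percentiles of the estimates over bootstrap
resamples of the data (ratio measures on the natural-log scale; cluster
resampling when observations are grouped). The NNT is reported without
an interval — interval methods for it are not standardized and it is
meant for communication. Categorical exposures give one contrast per
non-referent level; a subgroup variable adds an exposure×subgroup
interaction and reports effects per stratum; numeric exposures are
centered at the mean and contrasted over a user-chosen scalar.

## Worked example

The built-in simulator draws cohorts resembling a mid-century
cardiovascular cohort study: binary exposure (prevalent diabetes, ~10%)
depending on age, sex, BMI, smoking and hypertension, and a binary
24-year outcome (~40% incidence):

```python
from gcomprisk import AnalysisSpec, gcomp
from gcomprisk.simulate import framingham_like, generate

cohort = generate(framingham_like("binary", n_obs=5000, seed=1))
spec = AnalysisSpec(
    outcome_name="event", exposure_name="diabetes",
    covariate_names=["age", "sex_male", "bmi", "smoker", "hypertension"],
    outcome_type="binary", n_boot=200, seed=2,
)
result = gcomp(cohort, spec)
print(result.estimates.to_string(index=False))
```

```
subgroup contrast                     measure  estimate  ci_lower  ci_upper note
 overall   1 vs 0             Risk Difference  0.287272  0.246188  0.322687
 overall   1 vs 0                  Risk Ratio  1.791123  1.664924  1.901993
 overall   1 vs 0                  Odds Ratio  3.262874  2.733655  3.824431
 overall   1 vs 0 Number Needed to Treat/Harm  3.481027       NaN       NaN harm
```

Reading: the 24-year risk is 29 percentage points (95% CI 25–32) higher
with the exposure; the marginal risks are 0.363 (unexposed) vs 0.650
(exposed) (`result.marginal_means`). Note the odds ratio (3.26) is far
from the risk ratio (1.79) at this outcome prevalence — exactly why
reporting it alone misleads. About 3.5 exposed persons correspond to one
additional case ("harm" direction); the generative truth for this cohort
is a marginal risk difference of 0.30.

The same interface handles rates per 100 person-years with subgroup
effects:

```python
spec = AnalysisSpec(
    outcome_name="event", exposure_name="diabetes",
    covariate_names=["age", "bmi", "smoker", "hypertension"],
    subgroup_name="sex_male", outcome_type="rate",
    offset_name="follow_days", rate_multiplier=365.25 * 100,
    n_boot=200, seed=2,
)
```

Or from a shell:

```sh
gcomprisk --input cohort.csv --outcome-type binary \
    --y event --x diabetes --z age,sex_male,bmi,smoker,hypertension \
    --r 1000 --seed 42 --output-dir out/ --plots
```

which writes `results.csv`, a structured `report.json` (spec echo, seed,
failed-replicate count, centering value) and optional bootstrap
diagnostic plots (histogram and normal Q-Q per measure, ratios on the
log scale).

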