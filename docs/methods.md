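# Methods

## Estimand and estimator

The package estimates marginal (population-standardized) exposure
effects in time-fixed data. For exposure $A$, outcome $Y$ and covariates
$W$, the counterfactual mean under regime $a$ is
$\mu_a = E_W\,[E(Y \mid A=a, W)]$, estimated by plugging a fitted GLM
into the empirical covariate distribution: fit $E(Y\mid A,W)$ on the
observed data, predict each observation's outcome with $A$ forced to
$a$, and average. Contrasts of $\hat\mu_a$ against the referent
$\hat\mu_0$ give, per outcome family:

| outcome type | family/link | measures |
|---|---|---|
| `binary` | binomial/logit | RD $\mu_1-\mu_0$, RR $\mu_1/\mu_0$, OR, NNT $=\lvert 1/\mathrm{RD}\rvert$ |
| `count`, `rate` | Poisson/log | IRD, IRR |
| `count_nb`, `rate_nb` | negative binomial/log | IRD, IRR |
| `continuous` | gaussian/identity | mean difference |

Identification assumes exchangeability given $W$, positivity, and
correct outcome-model specification; the package makes no attempt to
check the first two.

### Exposure handling

* Categorical exposures are referent-coded (referent = first level of
  the ordered level list; default ordering is ascending sort of the raw
  values). $L$ levels yield $L-1$ contrasts against the referent.
* Numeric exposures enter the model as $(x-c)/s$ with $c$ the sample
  mean (overridable by a number, or 0 when centering is disabled) and
  $s$ the `exposure_scalar`. The reported contrast is raw exposure
  $c+s$ versus $c$ — one scaled unit above the center — and the results
  table labels those raw endpoints, because a GLM that is linear on the
  link scale does not give constant difference/ratio effects across the
  exposure range.
* Subgroup analysis fits **one** model on the full data with an
  exposure×subgroup interaction (the only interaction the model surface
  permits — user-supplied `*`/`:` terms are rejected), then standardizes
  within each subgroup's rows over that subgroup's own covariate
  distribution. Within-subgroup standardization is the deliberate
  choice: stratum-specific baseline risks/rates are what subgroup
  reports are read against.

### Rates, counts and offsets

`rate`-type outcomes require a strictly positive person-time column,
entering the model as a natural-log offset; counterfactual predictions
replace the offset with the `rate_multiplier` (e.g. `365.25*100` when
person-time is in days and rates are wanted per 100 person-years), so
IRD is on the multiplier scale while IRR is invariant to it.
`count`-type outcomes may omit the offset, in which case predictions are
per-observation expected counts and the multiplier is a pure display
scale. The negative-binomial variants use variance $\mu+\mu^2/\theta$;
$\theta$ is estimated by profile alternation — a GLM fit at fixed
$\theta$ alternating with a maximum-likelihood $\theta$ update at fixed
means, to joint log-likelihood convergence (relative $10^{-8}$, ≤30
rounds, $\theta$ searched in $[10^{-3},10^6]$).

### Effect-measure conventions

* NNT is reported as $\lvert 1/\mathrm{RD}\rvert$ with a direction note
  (`harm` when RD > 0, `benefit` when RD < 0, infinite at RD = 0), and
  never gets a confidence interval.
* A referent marginal mean of exactly 0 makes ratio measures undefined;
  they are reported as NaN rather than raising.

## Inference

Percentile bootstrap: the full pipeline (fit → counterfactual predict →
average → contrast) is recomputed on `R` resamples (default 200); the CI
is the (2.5th, 97.5th) percentile pair of the successful replicate
estimates, with **linear interpolation at $h=(n-1)p+1$** between order
statistics (the convention is echoed in the structured report, since
implementations differ in the last digit). Ratio measures are
summarized on the natural-log scale and exponentiated; this coincides
with raw-scale percentiles whenever no interpolation straddles two
draws, and respects the log-symmetry of ratio sampling distributions.

* **Centering:** the numeric-exposure centering constant computed on the
  original data is reused in every replicate, so all replicates contrast
  the same raw exposure values.
* **Cluster resampling:** with a cluster identifier, whole clusters are
  drawn with replacement (each drawn cluster contributes all its rows;
  resample sizes vary). Nested clustering is out of scope; for complex
  dependence users can call `point_estimate` inside their own resampling
  scheme.
* **Failed replicates** (non-convergent fit, singular design, or a
  non-finite measure, e.g. an empty exposure arm in the resample) are
  dropped and counted; the run aborts if more than 10% fail, since
  silently retrying would bias the bootstrap distribution.
* **Determinism/parallelism:** the root seed spawns one independent RNG
  substream per replicate (`numpy` `SeedSequence`), so output is
  bit-identical across worker counts and runs.
* **Diagnostics:** per-measure histograms and normal Q-Q arrays of the
  draws (ratios on the log scale; sorted standardized draws against
  standard-normal quantiles), requiring ≥10 successful replicates;
  plotting is a thin optional layer over these arrays.

Separation in a fit is flagged by a warning when any coefficient exceeds
20 on the link scale; the fit proceeds, because bootstrap resamples of
sparse strata separate routinely and the standardized means usually
remain stable. IRLS runs to relative tolerance $10^{-8}$ within 100
iterations; non-convergence raises (in a replicate: counts as a
failure).

## Input validation choices

* Rows with missing values in any referenced column are **rejected with
  a counted error**; listwise deletion is available only by explicit
  opt-in (`drop_missing` / `--drop-missing`) and logs the number
  dropped. Silent deletion is hidden state.
* Free-text columns cannot be modelled; exposures must be factors
  (ordered levels, first = referent) or numeric. Binary 0/1 exposures
  are promoted to two-level factors with referent 0; binary outcomes
  must be coercible to {0,1}, two-level categorical outcomes mapping
  their first level to 0; subgroup columns are coerced to factors.
* Validation is idempotent and referent ordering deterministic.

## Synthetic cohorts and what they show

`simulate.framingham_like` emulates the structure of a long-follow-up
cardiovascular cohort: covariates age ~ N(50, 8.5), male sex ~
Bern(0.44), BMI ~ N(25.8, 4.1), smoking ~ Bern(0.49), hypertension ~
Bern(0.31); a confounded binary exposure (~10% prevalence, logistic in
the covariates); and outcomes from known link-scale coefficients
(continuous covariates standardized in the linear predictors so
intercepts set baselines directly). The binary regime targets ~40%
incidence with a conditional exposure log-odds of 1.5, high enough
baseline risk that the marginal OR visibly diverges from the RR; rate
regimes use exponential follow-up (mean ≈ 24 years in days) and a log
IRR of 0.65; the overdispersion fixture uses $\theta = 1.5$, separable
from Poisson at n ≈ 2,000. Optional equal-size clusters share a normal
random intercept on the outcome link scale.

The generative truth oracle (`true_marginal_effects`) computes marginal
effects by potential-outcome Monte Carlo — draw covariates from the
generating law, evaluate the true mean outcome under each exposure, and
average — with delta-method Monte-Carlo standard errors. Tests built on
this machinery show unbiasedness and nominal CI coverage *under a
correctly specified outcome model with exchangeable, fully observed
data*; they say nothing about confounding by unmeasured variables,
model misspecification, measurement error or informative missingness in
real cohorts.

Problem sizes used by the test suite and acceptance script — bias over
100–200 cohorts of n = 5,000; coverage over 200 simulations at n = 500
with R = 200; truth oracles at 400,000 Monte-Carlo draws — were chosen
so that Monte-Carlo error is small relative to the tolerances being
asserted.

## Known limitations

* Time-fixed exposures only: no time-varying treatments or mediators,
  no inverse-probability weighting, no doubly-robust or TMLE-style
  estimation.
* Percentile bootstrap only — no BCa, studentized, or closed-form
  (delta/sandwich) intervals; percentile CIs can slightly undercover at
  small n (the coverage check's band is 0.90–0.98 for nominal 0.95).
* No survey weights, imputation, or regularized/quasi-likelihood models.
* The NNT is a communication device; its reciprocal transform is why it
  deliberately carries no interval.
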