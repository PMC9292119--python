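"""Synthetic cohort generation with a known causal truth.

The generator emulates the structure of a mid-century cardiovascular
cohort: a binary exposure (prevalent diabetes) whose probability depends
on mixed continuous/binary covariates (age, sex, BMI, smoking,
hypertension), and an outcome drawn from one of the six supported GLM
families with known link-scale coefficients.  Because the full generative
law is known, the true marginal (population-standardized) effects are
available from a potential-outcome Monte Carlo oracle, which is what makes
the estimation pipeline testable without any external data.

Continuous covariates enter every linear predictor standardized
(``(x - mean)/sd`` of their generating law), binary covariates enter as
0/1, so intercepts directly control baseline prevalence/rates.

Default regime (the :func:`framingham_like` factory): exposure prevalence
~10%, binary-outcome incidence ~40%, moderate confounding — high enough
baseline risk that the marginal odds ratio visibly exceeds the risk ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CohortTable, ValidationError, build_cohort

EXPOSURE = "diabetes"
OUTCOME = "event"
PERSON_TIME = "follow_days"
CLUSTER = "clinic"


@dataclass
class GenerativeModel:
    """Full generative law for one synthetic cohort.

    ``covariates`` maps a name to a law: ``("normal", mean, sd)`` or
    ``("bernoulli", p)``.  ``exposure_coefs`` and ``outcome_coefs`` are
    link-scale coefficients over ``{"(Intercept)", <covariate names>}``
    (plus ``EXPOSURE`` in ``outcome_coefs``); covariates enter standardized
    as described in the module docstring.

    For rate outcomes the linear predictor is the log event rate per unit
    person-time and follow-up is drawn from ``followup`` (``("fixed", t)``
    or ``("exponential", mean_t)``).  ``nb_theta`` is the negative-binomial
    dispersion (variance = mu + mu^2/theta).  ``gauss_sd`` is the residual
    standard deviation of a continuous outcome.

    Optional clustering: ``n_clusters`` equal-size clusters sharing a
    normal random intercept (sd ``cluster_sd``) on the outcome link scale.
    """

    n_obs: int = 5000
    outcome_type: str = "binary"
    seed: int = 0
    covariates: dict[str, tuple] = field(default_factory=dict)
    exposure_coefs: dict[str, float] = field(default_factory=dict)
    outcome_coefs: dict[str, float] = field(default_factory=dict)
    nb_theta: float = 1.5
    gauss_sd: float = 1.0
    followup: tuple = ("exponential", 8766.0)
    n_clusters: int | None = None
    cluster_sd: float = 0.0

    def __post_init__(self) -> None:
        for name, law in self.covariates.items():
            if law[0] == "bernoulli" and not 0 < law[1] < 1:
                raise ValidationError(f"covariate {name!r}: bernoulli p must be in (0,1)")
            if law[0] == "normal" and law[2] <= 0:
                raise ValidationError(f"covariate {name!r}: normal sd must be positive")
        if self.nb_theta <= 0:
            raise ValidationError("nb_theta must be positive")
        if self.followup[1] <= 0:
            raise ValidationError("follow-up time must be positive")


def _draw_covariates(model: GenerativeModel, n: int, rng: np.random.Generator):
    """Raw covariate columns and their standardized versions."""
    raw, std = {}, {}
    for name, law in model.covariates.items():
        if law[0] == "normal":
            _, mean, sd = law
            x = rng.normal(mean, sd, n)
            raw[name], std[name] = x, (x - mean) / sd
        elif law[0] == "bernoulli":
            x = rng.binomial(1, law[1], n)
            raw[name], std[name] = x, x.astype(float)
        else:
            raise ValidationError(f"unknown covariate law {law[0]!r}")
    return raw, std


def _linpred(coefs: dict[str, float], std: dict[str, np.ndarray], n: int) -> np.ndarray:
    eta = np.full(n, coefs.get("(Intercept)", 0.0))
    for name, beta in coefs.items():
        if name == "(Intercept)":
            continue
        if name not in std:
            raise ValidationError(f"coefficient refers to unknown column {name!r}")
        eta = eta + beta * std[name]
    return eta


def generate(model: GenerativeModel) -> CohortTable:
    """Draw one cohort from the generative law (reproducible given seed)."""
    n = model.n_obs
    rng = np.random.default_rng(model.seed)
    raw, std = _draw_covariates(model, n, rng)

    a = rng.binomial(1, expit(_linpred(model.exposure_coefs, std, n)))
    std_with_a = dict(std)
    std_with_a[EXPOSURE] = a.astype(float)
    eta = _linpred(model.outcome_coefs, std_with_a, n)

    cols = dict(raw)
    cols[EXPOSURE] = a
    if model.n_clusters:
        if n % model.n_clusters:
            raise ValidationError("n_obs must be a multiple of n_clusters")
        ids = np.repeat(np.arange(model.n_clusters), n // model.n_clusters)
        eta = eta + rng.normal(0.0, model.cluster_sd, model.n_clusters)[ids]
        cols[CLUSTER] = ids

    ot = model.outcome_type
    if ot == "binary":
        y = rng.binomial(1, expit(eta))
    elif ot in ("count", "count_nb", "rate", "rate_nb"):
        if ot in ("rate", "rate_nb"):
            kind, t = model.followup
            pt = np.full(n, float(t)) if kind == "fixed" else rng.exponential(t, n)
            cols[PERSON_TIME] = pt
            mu = np.exp(eta) * pt
        else:
            mu = np.exp(eta)
        if ot in ("count_nb", "rate_nb"):
            # Gamma-Poisson mixture: marginal NB with dispersion theta
            lam = mu * rng.gamma(model.nb_theta, 1.0 / model.nb_theta, n)
            y = rng.poisson(lam)
        else:
            y = rng.poisson(mu)
    elif ot == "continuous":
        y = eta + rng.normal(0.0, model.gauss_sd, n)
    else:
        raise ValidationError(f"unknown outcome_type {ot!r}")
    cols[OUTCOME] = y

    df = pd.DataFrame(cols)
    types: dict[str, str] = {}
    for name, law in model.covariates.items():
        types[name] = "binary01" if law[0] == "bernoulli" else "numeric"
    types[EXPOSURE] = "binary01"
    if model.n_clusters:
        types[CLUSTER] = "numeric"
    if PERSON_TIME in cols:
        types[PERSON_TIME] = "numeric"
    types[OUTCOME] = "numeric"
    return build_cohort(df, types)


@dataclass
class TrueEffects:
    """Potential-outcome Monte Carlo oracle values for a generative model."""

    measures: dict[str, float]
    mc_se: dict[str, float]
    marginal_means: tuple[float, float]  # (referent, exposed)
    n_mc: int


def true_marginal_effects(
    model: GenerativeModel,
    n_mc: int = 200_000,
    rate_multiplier: float = 1.0,
    seed: int | None = None,
) -> TrueEffects:
    """True marginal effects by averaging potential outcomes over covariates.

    Draws ``n_mc`` covariate vectors from the model's covariate laws,
    evaluates the true mean outcome with the exposure forced to 1 and to 0,
    and averages — the marginal (standardized-to-the-population) contrast.
    Rate measures are per ``rate_multiplier`` units of person-time.
    Monte Carlo standard errors accompany every measure.
    """
    from .engine import (
        MEAN_DIFFERENCE,
        NNT,
        ODDS_RATIO,
        RATE_DIFFERENCE,
        RATE_RATIO,
        RISK_DIFFERENCE,
        RISK_RATIO,
    )

    rng = np.random.default_rng(model.seed + 1_000_003 if seed is None else seed)
    _, std = _draw_covariates(model, n_mc, rng)
    if model.n_clusters and model.cluster_sd > 0:
        u = rng.normal(0.0, model.cluster_sd, n_mc)
    else:
        u = 0.0
    mu = {}
    for a in (0.0, 1.0):
        s = dict(std)
        s[EXPOSURE] = np.full(n_mc, a)
        eta = _linpred(model.outcome_coefs, s, n_mc) + u
        if model.outcome_type == "binary":
            mu[a] = expit(eta)
        elif model.outcome_type == "continuous":
            mu[a] = eta
        else:
            mu[a] = np.exp(eta) * rate_multiplier

    m1, m0 = float(mu[1.0].mean()), float(mu[0.0].mean())
    se1 = float(mu[1.0].std(ddof=1) / math.sqrt(n_mc))
    se0 = float(mu[0.0].std(ddof=1) / math.sqrt(n_mc))
    diff = mu[1.0] - mu[0.0]
    se_diff = float(diff.std(ddof=1) / math.sqrt(n_mc))
    # delta-method SE for the ratio of means
    se_ratio = abs(m1 / m0) * math.sqrt((se1 / m1) ** 2 + (se0 / m0) ** 2) if m0 else math.nan

    if model.outcome_type == "binary":
        rd, rr = m1 - m0, m1 / m0
        orat = (m1 / (1 - m1)) / (m0 / (1 - m0))
        measures = {
            RISK_DIFFERENCE: rd,
            RISK_RATIO: rr,
            ODDS_RATIO: orat,
            NNT: math.inf if rd == 0 else abs(1 / rd),
        }
        d_or1 = 1 / (m1 * (1 - m1))  # d log OR / d m1
        d_or0 = 1 / (m0 * (1 - m0))
        se_or = orat * math.sqrt((d_or1 * se1) ** 2 + (d_or0 * se0) ** 2)
        mc_se = {
            RISK_DIFFERENCE: se_diff,
            RISK_RATIO: se_ratio,
            ODDS_RATIO: se_or,
            NNT: math.nan if rd == 0 else se_diff / rd**2,
        }
    elif model.outcome_type == "continuous":
        measures = {MEAN_DIFFERENCE: m1 - m0}
        mc_se = {MEAN_DIFFERENCE: se_diff}
    else:
        measures = {RATE_DIFFERENCE: m1 - m0, RATE_RATIO: m1 / m0}
        mc_se = {RATE_DIFFERENCE: se_diff, RATE_RATIO: se_ratio}
    return TrueEffects(measures=measures, mc_se=mc_se, marginal_means=(m0, m1), n_mc=n_mc)


# ---------------------------------------------------------------------------
# default fixture


#: covariate laws of the default cohort (age y, BMI kg/m^2, rest 0/1)
DEFAULT_COVARIATES = {
    "age": ("normal", 50.0, 8.5),
    "sex_male": ("bernoulli", 0.44),
    "bmi": ("normal", 25.8, 4.1),
    "smoker": ("bernoulli", 0.49),
    "hypertension": ("bernoulli", 0.31),
}

#: exposure (diabetes) model: ~10% prevalence, older/heavier/hypertensive
#: participants more likely exposed
DEFAULT_EXPOSURE_COEFS = {
    "(Intercept)": -2.60,
    "age": 0.50,
    "sex_male": 0.20,
    "bmi": 0.35,
    "smoker": 0.10,
    "hypertension": 0.50,
}

#: outcome coefficient sets per family; exposure effect strong enough that
#: the marginal OR clearly exceeds the marginal RR at ~40% incidence
_SHARED_EFFECTS = {
    EXPOSURE: 1.5,
    "age": 0.90,
    "sex_male": 0.45,
    "bmi": 0.20,
    "smoker": 0.30,
    "hypertension": 0.60,
}

DEFAULT_OUTCOME_INTERCEPTS = {
    "binary": -1.25,
    "count": 0.10,
    "count_nb": 0.10,
    # log events/person-day; ~40% cumulative incidence over ~24 y mean follow-up
    "rate": -10.0,
    "rate_nb": -10.0,
    "continuous": 0.0,
}

_RATE_EXPOSURE_EFFECT = 0.65  # log IRR ~ 1.9


def framingham_like(
    outcome_type: str = "binary",
    n_obs: int = 5000,
    seed: int = 0,
    n_clusters: int | None = None,
    cluster_sd: float = 0.0,
) -> GenerativeModel:
    """Default cohort: mixed covariates, confounded binary exposure, and the
    requested outcome family with moderate, realistic effect sizes."""
    coefs = dict(_SHARED_EFFECTS)
    coefs["(Intercept)"] = DEFAULT_OUTCOME_INTERCEPTS[outcome_type]
    if outcome_type in ("rate", "rate_nb"):
        coefs[EXPOSURE] = _RATE_EXPOSURE_EFFECT
    if outcome_type == "continuous":
        coefs = {k: 5.0 * v for k, v in coefs.items()}
    return GenerativeModel(
        n_obs=n_obs,
        outcome_type=outcome_type,
        seed=seed,
        covariates=dict(DEFAULT_COVARIATES),
        exposure_coefs=dict(DEFAULT_EXPOSURE_COEFS),
        outcome_coefs=coefs,
        gauss_sd=10.0 if outcome_type == "continuous" else 1.0,
        n_clusters=n_clusters,
        cluster_sd=cluster_sd,
    )
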