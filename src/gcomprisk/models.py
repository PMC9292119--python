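"""Outcome regression models.

One GLM family per outcome type:

==============  =====================  ==========================
outcome type    family / link          measures downstream
==============  =====================  ==========================
binary          binomial / logit       RD, RR, OR, NNT
count, rate     Poisson / log          IRD, IRR
count_nb,       negative binomial /    IRD, IRR
rate_nb         log (theta by ML)
continuous      gaussian / identity    mean difference
==============  =====================  ==========================

Fitting is delegated to :mod:`statsmodels` (IRLS).  The negative-binomial
dispersion parameter ``theta`` (variance = mu + mu^2/theta) is estimated by
profile alternation: a GLM fit at fixed theta alternates with a
maximum-likelihood theta update at fixed mean, until joint convergence.

The design matrix is built here rather than through a formula engine
because the counterfactual step needs precise control over the exposure
column: centering/scaling of a numeric exposure, referent-coded factor
indicators, and the internally added exposure-by-subgroup interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special

from .cohort import AnalysisSpec, CohortTable, ValidationError

#: |coefficient| on the link scale beyond which we suspect separation
SEPARATION_BOUND = 20.0
IRLS_TOL = 1e-8
IRLS_MAXITER = 100
NB_MAX_ALTERNATIONS = 30


class FitError(RuntimeError):
    """A model fit failed (non-convergence or degenerate design)."""


@dataclass
class DesignInfo:
    """Everything needed to build the model matrix for observed or
    counterfactual data.

    For a numeric exposure the model term is ``(x - center) / scalar``; the
    two regimes contrasted are the centered values 0 and 1, i.e. the raw
    exposure values ``center`` and ``center + scalar``.
    """

    outcome_name: str
    exposure_name: str
    exposure_kind: str  # "categorical" | "numeric"
    exposure_levels: list | None  # categorical only, referent first
    center: float  # numeric exposure only (0.0 when uncentered)
    scalar: float
    covariates: list[tuple[str, str, list | None]]  # (name, kind, levels)
    subgroup_name: str | None
    subgroup_levels: list | None
    offset_name: str | None
    column_names: list[str] = field(default_factory=list)

    @property
    def n_exposure_cols(self) -> int:
        if self.exposure_kind == "numeric":
            return 1
        return len(self.exposure_levels) - 1

    def regimes(self) -> list:
        """Exposure regimes, referent first.

        Categorical: the level list.  Numeric: centered values [0, 1],
        i.e. raw ``center`` and ``center + scalar``.
        """
        if self.exposure_kind == "categorical":
            return list(self.exposure_levels)
        return [0.0, 1.0]

    def regime_label(self, regime) -> str:
        if self.exposure_kind == "categorical":
            return str(regime)
        raw = self.center + regime * self.scalar
        return f"{raw:g}"

    # -- matrix construction -------------------------------------------------

    def _exposure_block(self, df: pd.DataFrame, regime=None) -> np.ndarray:
        n = len(df)
        if self.exposure_kind == "numeric":
            if regime is None:
                x = (df[self.exposure_name].to_numpy(float) - self.center) / self.scalar
            else:
                x = np.full(n, float(regime))
            return x[:, None]
        if regime is None:
            codes = pd.Categorical(
                df[self.exposure_name], categories=self.exposure_levels
            ).codes
            if (codes < 0).any():
                raise ValidationError(
                    f"exposure {self.exposure_name!r} contains unseen levels"
                )
        else:
            codes = np.full(n, self.exposure_levels.index(regime))
        out = np.zeros((n, len(self.exposure_levels) - 1))
        for j in range(1, len(self.exposure_levels)):
            out[:, j - 1] = codes == j
        return out

    def _factor_block(self, df: pd.DataFrame, name: str, levels: list) -> np.ndarray:
        codes = pd.Categorical(df[name], categories=levels).codes
        if (codes < 0).any():
            raise ValidationError(f"column {name!r} contains unseen levels")
        out = np.zeros((len(df), len(levels) - 1))
        for j in range(1, len(levels)):
            out[:, j - 1] = codes == j
        return out

    def matrix(self, df: pd.DataFrame, regime=None) -> np.ndarray:
        """Model matrix for ``df``; ``regime`` overrides the exposure column
        (a level for a categorical exposure, a centered value for numeric)."""
        n = len(df)
        blocks = [np.ones((n, 1))]
        expo = self._exposure_block(df, regime)
        blocks.append(expo)
        if self.subgroup_name is not None:
            sg = self._factor_block(df, self.subgroup_name, self.subgroup_levels)
            blocks.append(sg)
            # exposure x subgroup interaction (the only interaction allowed)
            inter = np.einsum("ij,ik->ijk", expo, sg).reshape(n, -1)
            blocks.append(inter)
        for name, kind, levels in self.covariates:
            if kind == "categorical":
                blocks.append(self._factor_block(df, name, levels))
            else:
                blocks.append(df[name].to_numpy(float)[:, None])
        return np.hstack(blocks)

    def _make_column_names(self) -> list[str]:
        names = ["(Intercept)"]
        if self.exposure_kind == "numeric":
            enames = [self.exposure_name]
        else:
            enames = [f"{self.exposure_name}[{lv}]" for lv in self.exposure_levels[1:]]
        names += enames
        if self.subgroup_name is not None:
            snames = [f"{self.subgroup_name}[{lv}]" for lv in self.subgroup_levels[1:]]
            names += snames
            names += [f"{e}:{s}" for e in enames for s in snames]
        for name, kind, levels in self.covariates:
            if kind == "categorical":
                names += [f"{name}[{lv}]" for lv in levels[1:]]
            else:
                names.append(name)
        return names


def build_design(
    table: CohortTable,
    spec: AnalysisSpec,
    centering_value: float | None = None,
) -> DesignInfo:
    """Derive the model design from a validated (table, spec) pair.

    ``centering_value`` overrides the sample-mean center for a numeric
    exposure; the bootstrap passes the center computed on the original data
    so every replicate contrasts the same raw exposure values.
    """
    df = table.data
    xname = spec.exposure_name
    xkind = table.kinds[xname]
    if xkind == "numeric":
        if df[xname].nunique() < 2:
            raise ValidationError(f"exposure {xname!r} is constant")
        if centering_value is not None:
            center = float(centering_value)
        elif spec.exposure_center is True:
            center = float(df[xname].mean())
        elif spec.exposure_center is False:
            center = 0.0
        else:
            center = float(spec.exposure_center)
        levels = None
        kind = "numeric"
    else:
        levels = table.levels(xname)
        counts = df[xname].value_counts()
        if (counts > 0).sum() < 2:
            raise ValidationError(f"exposure {xname!r} takes a single observed level")
        center, kind = 0.0, "categorical"

    covariates = []
    for name in spec.covariate_names:
        ckind = table.kinds[name]
        if ckind == "categorical":
            covariates.append((name, "categorical", table.levels(name)))
        else:
            covariates.append((name, "numeric", None))

    sg_levels = table.levels(spec.subgroup_name) if spec.subgroup_name else None
    info = DesignInfo(
        outcome_name=spec.outcome_name,
        exposure_name=xname,
        exposure_kind=kind,
        exposure_levels=levels,
        center=center,
        scalar=float(spec.exposure_scalar),
        covariates=covariates,
        subgroup_name=spec.subgroup_name,
        subgroup_levels=sg_levels,
        offset_name=spec.offset_name,
    )
    info.column_names = info._make_column_names()
    return info


@dataclass
class FittedOutcomeModel:
    """A fitted outcome regression.

    ``coefficients`` maps design-column names to link-scale estimates.
    ``nb_dispersion`` is the negative-binomial theta (present only for the
    ``*_nb`` families).  Predictions from a non-converged model must not be
    consumed downstream; :func:`fit_glm` raises instead of returning one.
    """

    outcome_type: str
    params: np.ndarray
    coefficients: dict[str, float]
    family_name: str
    link_name: str
    nb_dispersion: float | None
    converged: bool
    design_info: DesignInfo
    n_obs: int

    @property
    def family(self):
        return _family(self.outcome_type, self.nb_dispersion)

    def predict(self, X: np.ndarray, offset_log: np.ndarray | float | None = None) -> np.ndarray:
        eta = X @ self.params
        if offset_log is not None:
            eta = eta + offset_log
        return self.family.link.inverse(eta)


def _family(outcome_type: str, theta: float | None = None):
    if outcome_type == "binary":
        return sm.families.Binomial()
    if outcome_type in ("count", "rate"):
        return sm.families.Poisson()
    if outcome_type in ("count_nb", "rate_nb"):
        return sm.families.NegativeBinomial(alpha=1.0 / theta if theta else 1.0)
    if outcome_type == "continuous":
        return sm.families.Gaussian()
    raise ValidationError(f"unknown outcome_type {outcome_type!r}")


def _nb_loglik_theta(theta: float, y: np.ndarray, mu: np.ndarray) -> float:
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            + theta * np.log(theta)
            + y * np.log(mu)
            - (y + theta) * np.log(theta + mu)
        )
    )


def _estimate_theta(y: np.ndarray, mu: np.ndarray) -> float:
    """ML estimate of the NB dispersion theta at fixed means."""
    res = optimize.minimize_scalar(
        lambda lt: -_nb_loglik_theta(np.exp(lt), y, mu),
        bounds=(np.log(1e-3), np.log(1e6)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x))


def _check_rank(X: np.ndarray, column_names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise FitError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns); "
            "perfectly aliased terms must be removed"
        )


def fit_glm(
    y: np.ndarray,
    X: np.ndarray,
    outcome_type: str,
    offset_log: np.ndarray | None = None,
    design_info: DesignInfo | None = None,
    check_rank: bool = True,
) -> FittedOutcomeModel:
    """Maximum-likelihood GLM fit for one outcome type.

    Raises :class:`FitError` on non-convergence or rank deficiency; emits a
    warning (but still returns) when a coefficient exceeds
    ``SEPARATION_BOUND`` on the link scale, the signature of separation.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    names = design_info.column_names if design_info else [f"x{j}" for j in range(X.shape[1])]
    if check_rank:
        _check_rank(X, names)

    theta: float | None = None
    if outcome_type in ("count_nb", "rate_nb"):
        params, theta = _fit_negative_binomial(y, X, offset_log)
        converged = True
    else:
        fam = _family(outcome_type)
        res = sm.GLM(y, X, family=fam, offset=offset_log).fit(
            maxiter=IRLS_MAXITER, tol=IRLS_TOL
        )
        if not res.converged:
            raise FitError(
                f"{outcome_type} GLM did not converge in {IRLS_MAXITER} IRLS iterations"
            )
        params, converged = np.asarray(res.params), True

    if outcome_type != "continuous" and np.any(np.abs(params) > SEPARATION_BOUND):
        warnings.warn(
            "some coefficients exceed |{:g}| on the link scale; possible separation "
            "or an extremely sparse stratum".format(SEPARATION_BOUND),
            RuntimeWarning,
            stacklevel=2,
        )
    fam = _family(outcome_type, theta)
    return FittedOutcomeModel(
        outcome_type=outcome_type,
        params=params,
        coefficients=dict(zip(names, map(float, params))),
        family_name=fam.__class__.__name__,
        link_name=fam.link.__class__.__name__,
        nb_dispersion=theta,
        converged=converged,
        design_info=design_info,
        n_obs=len(y),
    )


def _fit_negative_binomial(
    y: np.ndarray, X: np.ndarray, offset_log: np.ndarray | None
) -> tuple[np.ndarray, float]:
    """Alternate GLM-at-fixed-theta with ML-theta-at-fixed-mean."""
    pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset_log).fit(
        maxiter=IRLS_MAXITER, tol=IRLS_TOL
    )
    params = np.asarray(pois.params)
    mu = pois.fittedvalues
    theta = _estimate_theta(y, mu)
    ll_prev = _nb_loglik_theta(theta, y, np.maximum(mu, 1e-300))
    for _ in range(NB_MAX_ALTERNATIONS):
        res = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=1.0 / theta), offset=offset_log
        ).fit(maxiter=IRLS_MAXITER, tol=IRLS_TOL, start_params=params)
        if not res.converged:
            raise FitError("negative-binomial GLM did not converge at fixed theta")
        params = np.asarray(res.params)
        mu = res.fittedvalues
        theta = _estimate_theta(y, mu)
        ll = _nb_loglik_theta(theta, y, np.maximum(mu, 1e-300))
        if abs(ll - ll_prev) < 1e-8 * (abs(ll_prev) + 0.1):
            return params, theta
        ll_prev = ll
    raise FitError(
        f"negative-binomial theta alternation did not converge in {NB_MAX_ALTERNATIONS} rounds"
    )


def predict_response(
    model: FittedOutcomeModel,
    df: pd.DataFrame,
    regime=None,
    offset_override: float | None = None,
) -> np.ndarray:
    """Response-scale predictions for the rows of ``df``.

    ``regime`` forces the exposure to one level (counterfactual prediction);
    ``offset_override`` replaces the person-time offset with a constant
    reporting denominator (e.g. the rate multiplier), entering the linear
    predictor as its natural log.
    """
    info = model.design_info
    if info is None:
        raise ValidationError("model carries no design info; cannot predict from a frame")
    needed = [info.exposure_name] + [c[0] for c in info.covariates]
    if info.subgroup_name:
        needed.append(info.subgroup_name)
    missing = [c for c in needed if c not in df.columns and not (c == info.exposure_name and regime is not None)]
    if missing:
        raise ValidationError(f"rows are missing design column(s) {missing}")
    X = info.matrix(df, regime=regime)
    offset_log = None
    if info.offset_name is not None:
        if offset_override is not None:
            offset_log = np.log(float(offset_override))
        else:
            offset_log = np.log(df[info.offset_name].to_numpy(float))
    return model.predict(X, offset_log=offset_log)
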