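"""The g-computation engine.

A point estimate is produced in three steps:

1. fit the outcome GLM on the observed data;
2. predict every observation's outcome under each exposure regime
   (the whole table is "cloned" with the exposure forced to each level —
   for rate outcomes the person-time offset is simultaneously set to the
   reporting denominator, the rate multiplier);
3. average the predictions per regime (the marginal mean outcome,
   standardized to the empirical covariate distribution) and contrast the
   averages.

With a subgroup variable, a *single* model with an exposure-by-subgroup
interaction is fit on the full data and steps 2-3 are carried out within
each subgroup's rows, so each subgroup effect is standardized over that
subgroup's own covariate distribution.

Effect measures by outcome type: binary — risk difference, risk ratio,
odds ratio and number needed to treat/harm; count and rate — incidence
rate difference and ratio (on the rate-multiplier scale); continuous —
mean difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import AnalysisSpec, CohortTable, ValidationError, COUNT_LIKE
from .models import DesignInfo, FittedOutcomeModel, build_design, fit_glm

RISK_DIFFERENCE = "Risk Difference"
RISK_RATIO = "Risk Ratio"
ODDS_RATIO = "Odds Ratio"
NNT = "Number Needed to Treat/Harm"
RATE_DIFFERENCE = "Incidence Rate Difference"
RATE_RATIO = "Incidence Rate Ratio"
MEAN_DIFFERENCE = "Mean Difference"

#: measures whose bootstrap percentiles are taken on the natural-log scale
RATIO_MEASURES = frozenset({RISK_RATIO, ODDS_RATIO, RATE_RATIO})
#: measures that get a bootstrap CI (NNT never does)
CI_MEASURES = {
    "binary": (RISK_DIFFERENCE, RISK_RATIO, ODDS_RATIO),
    "count": (RATE_DIFFERENCE, RATE_RATIO),
    "count_nb": (RATE_DIFFERENCE, RATE_RATIO),
    "rate": (RATE_DIFFERENCE, RATE_RATIO),
    "rate_nb": (RATE_DIFFERENCE, RATE_RATIO),
    "continuous": (MEAN_DIFFERENCE,),
}

OVERALL = "overall"


@dataclass
class CounterfactualSet:
    """Per-observation predictions under every exposure regime.

    ``predictions[i, k]`` is observation i's predicted mean outcome with the
    exposure forced to regime k (referent first);  ``marginal_means[k]`` is
    the arithmetic mean of column k.
    """

    predictions: np.ndarray
    regimes: list[str]
    marginal_means: np.ndarray
    subgroup_label: str | None = None


@dataclass
class EffectEstimates:
    """Marginal effect measures for one exposure contrast."""

    contrast: str  # "index vs referent", raw exposure values
    index_level: str
    referent: str
    measures: dict[str, float]
    nnt_direction: str | None = None


def _binary_measures(p1: float, p0: float) -> tuple[dict[str, float], str]:
    rd = p1 - p0
    rr = p1 / p0 if p0 > 0 else math.nan
    if 0 < p0 < 1 and 0 < p1 < 1:
        orat = (p1 / (1 - p1)) / (p0 / (1 - p0))
    else:
        orat = math.nan
    if rd == 0:
        nnt, direction = math.inf, "null"
    else:
        nnt = abs(1.0 / rd)
        direction = "harm" if rd > 0 else "benefit"
    return (
        {RISK_DIFFERENCE: rd, RISK_RATIO: rr, ODDS_RATIO: orat, NNT: nnt},
        direction,
    )


def measures_from_means(
    means: np.ndarray,
    regimes: list[str],
    outcome_type: str,
) -> list[EffectEstimates]:
    """Contrast each non-referent regime's marginal mean with the referent's."""
    if len(means) < 2:
        raise ValidationError("at least two exposure regimes are required")
    out = []
    m0 = float(means[0])
    for k in range(1, len(means)):
        mk = float(means[k])
        direction = None
        if outcome_type == "binary":
            measures, direction = _binary_measures(mk, m0)
        elif outcome_type in COUNT_LIKE:
            measures = {
                RATE_DIFFERENCE: mk - m0,
                RATE_RATIO: mk / m0 if m0 > 0 else math.nan,
            }
        else:
            measures = {MEAN_DIFFERENCE: mk - m0}
        out.append(
            EffectEstimates(
                contrast=f"{regimes[k]} vs {regimes[0]}",
                index_level=regimes[k],
                referent=regimes[0],
                measures=measures,
                nnt_direction=direction,
            )
        )
    return out


def marginal_contrast(cfs: CounterfactualSet, outcome_type: str) -> list[EffectEstimates]:
    """Effect measures from a counterfactual set's marginal means."""
    return measures_from_means(cfs.marginal_means, cfs.regimes, outcome_type)


def subgroup_split(table: CohortTable, spec: AnalysisSpec) -> dict[str, CohortTable]:
    """Per-level row subsets of the subgroup column (labels are strings).

    Estimation itself fits one interaction model on the full table; the
    split is exposed for stratified summaries and cross-checks.
    """
    if spec.subgroup_name is None:
        raise ValidationError("spec has no subgroup")
    levels = table.levels(spec.subgroup_name)
    out = {}
    for lv in levels:
        mask = (table.data[spec.subgroup_name] == lv).to_numpy()
        if mask.sum() < 2:
            raise ValidationError(f"subgroup level {lv!r} has fewer than 2 rows")
        out[str(lv)] = table.subset(mask)
    return out


# ---------------------------------------------------------------------------
# array core (shared by the point estimate and every bootstrap replicate)


@dataclass
class _ArrayTask:
    """Pre-built arrays for one analysis, indexable by bootstrap rows."""

    y: np.ndarray
    X_obs: np.ndarray
    regime_mats: list[np.ndarray]
    regimes: list[str]
    offset_log_obs: np.ndarray | None
    offset_log_pred: float | None
    pred_scale: float
    outcome_type: str
    design_info: DesignInfo
    group_labels: list[str]
    group_masks: np.ndarray  # n_groups x n_obs boolean

    def take(self, idx: np.ndarray) -> "_ArrayTask":
        return _ArrayTask(
            y=self.y[idx],
            X_obs=self.X_obs[idx],
            regime_mats=[m[idx] for m in self.regime_mats],
            regimes=self.regimes,
            offset_log_obs=None if self.offset_log_obs is None else self.offset_log_obs[idx],
            offset_log_pred=self.offset_log_pred,
            pred_scale=self.pred_scale,
            outcome_type=self.outcome_type,
            design_info=self.design_info,
            group_labels=self.group_labels,
            group_masks=self.group_masks[:, idx],
        )


def _build_task(table: CohortTable, spec: AnalysisSpec, info: DesignInfo) -> _ArrayTask:
    df = table.data
    y = df[spec.outcome_name].to_numpy(float)
    X_obs = info.matrix(df)
    regimes = info.regimes()
    regime_mats = [info.matrix(df, regime=r) for r in regimes]
    regime_labels = [info.regime_label(r) for r in regimes]

    offset_log_obs = None
    offset_log_pred = None
    pred_scale = 1.0
    if spec.outcome_type in COUNT_LIKE:
        if spec.offset_name is not None:
            offset_log_obs = np.log(df[spec.offset_name].to_numpy(float))
            offset_log_pred = float(np.log(spec.rate_multiplier))
        else:
            # counts without person-time: per-observation expected counts,
            # rate multiplier acts as a pure display scale
            pred_scale = float(spec.rate_multiplier)

    if spec.subgroup_name is not None:
        levels = table.levels(spec.subgroup_name)
        labels = [str(lv) for lv in levels]
        masks = np.stack([(df[spec.subgroup_name] == lv).to_numpy() for lv in levels])
        for lv, m in zip(levels, masks):
            if m.sum() < 2:
                raise ValidationError(f"subgroup level {lv!r} has fewer than 2 rows")
    else:
        labels = [OVERALL]
        masks = np.ones((1, len(df)), dtype=bool)

    return _ArrayTask(
        y=y,
        X_obs=X_obs,
        regime_mats=regime_mats,
        regimes=regime_labels,
        offset_log_obs=offset_log_obs,
        offset_log_pred=offset_log_pred,
        pred_scale=pred_scale,
        outcome_type=spec.outcome_type,
        design_info=info,
        group_labels=labels,
        group_masks=masks,
    )


def _run_task(task: _ArrayTask, check_rank: bool = True):
    """Fit + counterfactual predict + per-group marginal means."""
    model = fit_glm(
        task.y,
        task.X_obs,
        task.outcome_type,
        offset_log=task.offset_log_obs,
        design_info=task.design_info,
        check_rank=check_rank,
    )
    preds = np.column_stack(
        [model.predict(m, offset_log=task.offset_log_pred) for m in task.regime_mats]
    )
    if task.pred_scale != 1.0:
        preds = preds * task.pred_scale
    means = {}
    for label, mask in zip(task.group_labels, task.group_masks):
        if mask.sum() == 0:
            means[label] = np.full(preds.shape[1], math.nan)
        else:
            means[label] = preds[mask].mean(axis=0)
    return model, preds, means


# ---------------------------------------------------------------------------
# public point estimate


@dataclass
class PointEstimate:
    """Result of one g-computation pass over one dataset."""

    model: FittedOutcomeModel
    counterfactuals: dict[str, CounterfactualSet]
    effects: dict[str, list[EffectEstimates]]
    centering_value_used: float | None
    group_labels: list[str] = field(default_factory=list)

    @property
    def marginal_means(self) -> dict[str, dict[str, float]]:
        return {
            g: dict(zip(cfs.regimes, map(float, cfs.marginal_means)))
            for g, cfs in self.counterfactuals.items()
        }


def point_estimate(
    table: CohortTable,
    spec: AnalysisSpec,
    centering_value: float | None = None,
) -> PointEstimate:
    """Three-step g-computation point estimate on a validated (table, spec).

    ``centering_value`` fixes the numeric-exposure centering constant (used
    by the bootstrap so every replicate contrasts the same raw exposure
    values); by default the sample mean is used.
    """
    info = build_design(table, spec, centering_value=centering_value)
    task = _build_task(table, spec, info)
    model, preds, means = _run_task(task)

    counterfactuals, effects = {}, {}
    for label, mask in zip(task.group_labels, task.group_masks):
        cfs = CounterfactualSet(
            predictions=preds[mask],
            regimes=list(task.regimes),
            marginal_means=means[label],
            subgroup_label=None if label == OVERALL else label,
        )
        counterfactuals[label] = cfs
        effects[label] = measures_from_means(means[label], task.regimes, spec.outcome_type)

    center_used = info.center if info.exposure_kind == "numeric" else None
    return PointEstimate(
        model=model,
        counterfactuals=counterfactuals,
        effects=effects,
        centering_value_used=center_used,
        group_labels=list(task.group_labels),
    )
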