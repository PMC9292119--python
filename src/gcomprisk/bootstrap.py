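"""Percentile-bootstrap inference around the g-computation point estimate.

The sampling distribution of the marginal effect measures is approximated
by refitting the whole g-computation pipeline on resamples of the data:
rows are drawn with replacement (or whole clusters, when a cluster
identifier is supplied — every drawn cluster contributes all of its rows,
so resampled tables can differ in size).  The 95% confidence interval for
each measure is the (2.5th, 97.5th) percentile pair of the successful
replicate estimates; ratio measures are summarized on the natural-log
scale and exponentiated, since their bootstrap distributions are
log-symmetric.  No interval is reported for the number needed to
treat/harm — interval methods for the NNT are not standardized and the
reciprocal transform misbehaves when the risk-difference interval spans 0.

Reproducibility contract: one root seed spawns one independent RNG
substream per replicate, so results are bit-identical for a given seed
regardless of how many workers execute the replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from .cohort import AnalysisSpec, CohortTable, ValidationError, validate_spec
from .engine import (
    CI_MEASURES,
    NNT,
    OVERALL,
    RATIO_MEASURES,
    _build_task,
    _run_task,
    measures_from_means,
    point_estimate,
)
from .models import FitError, build_design
from .results import ESTIMATE_COLUMNS, GCompResult

#: abort when more than this fraction of bootstrap replicates fail
MAX_FAILURE_FRACTION = 0.10

KEY_SEP = "|"


@dataclass
class BootstrapPlan:
    """Resampling plan: how many replicates, at what unit, from which seed."""

    n_boot: int
    unit: str = "row"  # "row" | "cluster"
    cluster_id_name: str | None = None
    seed: int = 0
    worker_count: int = 1
    max_failure_fraction: float = MAX_FAILURE_FRACTION

    def __post_init__(self) -> None:
        if (self.unit == "cluster") != (self.cluster_id_name is not None):
            raise ValidationError("unit='cluster' if and only if cluster_id_name is set")


def plan_from_spec(spec: AnalysisSpec) -> BootstrapPlan:
    return BootstrapPlan(
        n_boot=spec.n_boot,
        unit="cluster" if spec.cluster_id_name else "row",
        cluster_id_name=spec.cluster_id_name,
        seed=spec.seed,
        worker_count=spec.parallel_workers,
    )


def _replicate_rng(seed: int, replicate_index: int) -> np.random.Generator:
    child = np.random.SeedSequence(seed).spawn(replicate_index + 1)[replicate_index]
    return np.random.default_rng(child)


def _cluster_members(cluster_col: np.ndarray) -> list[np.ndarray]:
    order = pd.unique(cluster_col)  # first-appearance order: deterministic
    return [np.flatnonzero(cluster_col == c) for c in order]


def _resample_indices(
    rng: np.random.Generator,
    n_obs: int,
    cluster_members: list[np.ndarray] | None,
) -> np.ndarray:
    if cluster_members is None:
        return rng.integers(0, n_obs, size=n_obs)
    draws = rng.integers(0, len(cluster_members), size=len(cluster_members))
    return np.concatenate([cluster_members[c] for c in draws])


def resample(table: CohortTable, plan: BootstrapPlan, replicate_index: int) -> CohortTable:
    """Resample a table for one bootstrap replicate.

    Row mode draws ``n_obs`` rows with replacement; cluster mode draws
    clusters with replacement and keeps each drawn cluster intact, so the
    resampled table may differ in row count.  ``replicate_index`` selects an
    independent substream of the plan's seed, so the sequence of resamples
    is deterministic and independent of execution order.
    """
    if plan.unit == "cluster":
        col = table.data[plan.cluster_id_name].to_numpy()
        members = _cluster_members(col)
        if len(members) < 2:
            raise ValidationError("cluster resampling requires at least 2 clusters")
    else:
        if table.n_obs < 2:
            raise ValidationError("resampling requires at least 2 observations")
        members = None
    rng = _replicate_rng(plan.seed, replicate_index)
    idx = _resample_indices(rng, table.n_obs, members)
    out = table.data.iloc[idx].reset_index(drop=True)
    return CohortTable(out, dict(table.kinds))


def _draw_key(group: str, contrast: str, measure: str) -> str:
    return KEY_SEP.join((group, contrast, measure))


def _one_replicate(task, seed_child, n_obs, cluster_members):
    """One bootstrap replicate; returns draw values or None on failure."""
    rng = np.random.default_rng(seed_child)
    idx = _resample_indices(rng, n_obs, cluster_members)
    sub = task.take(idx)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation warnings are expected in resamples
            _, _, means = _run_task(sub, check_rank=False)
    except (FitError, np.linalg.LinAlgError, ValueError):
        return None
    values = []
    for g in sub.group_labels:
        for eff in measures_from_means(means[g], sub.regimes, sub.outcome_type):
            for m in CI_MEASURES[sub.outcome_type]:
                values.append(eff.measures[m])
    if not all(math.isfinite(v) for v in values):
        return None
    return values


def percentile_ci(draws: np.ndarray, log_scale: bool = False) -> tuple[float, float]:
    """(2.5th, 97.5th) percentile interval, linear interpolation between
    order statistics; on the natural-log scale for ratio measures."""
    if log_scale:
        lo, hi = np.percentile(np.log(draws), [2.5, 97.5])
        return float(np.exp(lo)), float(np.exp(hi))
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(lo), float(hi)


def gcomp(
    table: CohortTable,
    spec: AnalysisSpec,
    drop_missing: bool = False,
) -> GCompResult:
    """Full g-computation analysis: point estimate + percentile-bootstrap CIs.

    The exposure centering value computed on the original data is reused in
    every replicate, so all bootstrap contrasts refer to the same raw
    exposure values.  Replicates whose model fit fails (or yields a
    non-finite measure) are dropped and counted; the run aborts when more
    than ``MAX_FAILURE_FRACTION`` of replicates fail.
    """
    table, spec = validate_spec(table, spec, drop_missing=drop_missing)
    point = point_estimate(table, spec)

    info = build_design(table, spec, centering_value=point.centering_value_used)
    task = _build_task(table, spec, info)

    plan = plan_from_spec(spec)
    if plan.unit == "cluster":
        members = _cluster_members(table.data[plan.cluster_id_name].to_numpy())
        if len(members) < 2:
            raise ValidationError("cluster resampling requires at least 2 clusters")
    else:
        members = None

    keys = [
        _draw_key(g, eff.contrast, m)
        for g in point.group_labels
        for eff in point.effects[g]
        for m in CI_MEASURES[spec.outcome_type]
    ]

    children = np.random.SeedSequence(spec.seed).spawn(plan.n_boot)
    if plan.worker_count > 1:
        rows = Parallel(n_jobs=plan.worker_count)(
            delayed(_one_replicate)(task, c, table.n_obs, members) for c in children
        )
    else:
        rows = [_one_replicate(task, c, table.n_obs, members) for c in children]

    ok = [r for r in rows if r is not None]
    n_failed = plan.n_boot - len(ok)
    if n_failed > plan.max_failure_fraction * plan.n_boot:
        raise FitError(
            f"{n_failed}/{plan.n_boot} bootstrap replicates failed "
            f"(> {plan.max_failure_fraction:.0%} ceiling); the model is too fragile "
            "for these data — simplify it or inspect sparse strata"
        )
    draws = pd.DataFrame(ok, columns=keys)

    records = []
    for g in point.group_labels:
        for eff in point.effects[g]:
            for measure, value in eff.measures.items():
                note = ""
                if measure == NNT:
                    lo = hi = math.nan  # no interval for the NNT, by design
                    note = eff.nnt_direction or ""
                else:
                    col = draws[_draw_key(g, eff.contrast, measure)].to_numpy()
                    if len(col) == 0:
                        lo = hi = math.nan
                    else:
                        lo, hi = percentile_ci(col, log_scale=measure in RATIO_MEASURES)
                records.append(
                    {
                        "subgroup": g,
                        "contrast": eff.contrast,
                        "measure": measure,
                        "estimate": value,
                        "ci_lower": lo,
                        "ci_upper": hi,
                        "note": note,
                    }
                )
    estimates = pd.DataFrame(records, columns=ESTIMATE_COLUMNS)

    model_summary = {
        "family": point.model.family_name,
        "link": point.model.link_name,
        "coefficients": point.model.coefficients,
        "nb_dispersion": point.model.nb_dispersion,
        "converged": point.model.converged,
        "n_obs": point.model.n_obs,
    }
    return GCompResult(
        estimates=estimates,
        marginal_means=point.marginal_means,
        boot_draws=draws,
        n_boot_failed=n_failed,
        spec_echo=spec,
        centering_value_used=point.centering_value_used,
        model_summary=model_summary,
    )


def gcomp_with_ci(table: CohortTable, spec: AnalysisSpec, **kw) -> GCompResult:
    """Alias for :func:`gcomp`."""
    return gcomp(table, spec, **kw)


# ---------------------------------------------------------------------------
# diagnostics


def diagnostics(result: GCompResult, bins: int = 20) -> dict[str, dict]:
    """Histogram and Q-Q arrays for each bootstrapped measure.

    Ratio measures are transformed to the natural log before binning.  The
    Q-Q pairs compare the sorted, standardized draws against standard-normal
    quantiles, so normally distributed bootstrap estimates lie on the
    identity line.
    """
    n = len(result.boot_draws)
    if n < 10:
        raise ValidationError(f"insufficient replicates for diagnostics ({n} < 10)")
    out = {}
    for key in result.boot_draws.columns:
        measure = key.split(KEY_SEP)[-1]
        values = result.boot_draws[key].to_numpy(float)
        log_scale = measure in RATIO_MEASURES
        if log_scale:
            values = np.log(values)
        counts, edges = np.histogram(values, bins=bins)
        sd = values.std(ddof=1)
        standardized = (values - values.mean()) / (sd if sd > 0 else 1.0)
        probs = (np.arange(1, n + 1) - 0.5) / n
        out[key] = {
            "measure": measure,
            "log_scale": log_scale,
            "hist_counts": counts,
            "hist_bin_edges": edges,
            "qq_theoretical": stats.norm.ppf(probs),
            "qq_sample": np.sort(standardized),
        }
    return out


def plot_diagnostics(result: GCompResult, path: str, bins: int = 20) -> str:
    """Render the diagnostics grid (histogram + Q-Q per measure) to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    diag = diagnostics(result, bins=bins)
    keys = list(diag)
    fig, axes = plt.subplots(len(keys), 2, figsize=(8, 2.6 * len(keys)), squeeze=False)
    for i, key in enumerate(keys):
        d = diag[key]
        label = f"log({d['measure']})" if d["log_scale"] else d["measure"]
        axes[i, 0].stairs(d["hist_counts"], d["hist_bin_edges"], fill=True)
        axes[i, 0].set_xlabel(label)
        axes[i, 0].set_ylabel("count")
        axes[i, 1].plot(d["qq_theoretical"], d["qq_sample"], "o", ms=2)
        lim = [d["qq_theoretical"][0], d["qq_theoretical"][-1]]
        axes[i, 1].plot(lim, lim, "r--", lw=1)
        axes[i, 1].set_xlabel("normal quantile")
        axes[i, 1].set_ylabel("standardized draw")
        axes[i, 1].set_title(key, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
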