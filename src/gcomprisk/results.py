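"""Result container and serialization.

A :class:`GCompResult` bundles the point estimates, the bootstrap draws,
the percentile confidence limits and enough provenance (spec echo, seed,
centering value, percentile convention) to reproduce the run.

Two output formats:

``tabular``
    CSV with one row per (subgroup, contrast, measure):
    estimate / ci_lower / ci_upper (NNT rows have empty CI cells).
``structured-report``
    JSON echoing the spec, seed, number of failed bootstrap replicates,
    centering value and fitted-model metadata alongside the estimates.
    Writing and re-reading a report preserves every estimate to machine
    precision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import AnalysisSpec, ValidationError

#: how bootstrap percentiles interpolate between order statistics
PERCENTILE_CONVENTION = "linear interpolation at h = (n-1)p + 1; ratio measures on the natural-log scale"

ESTIMATE_COLUMNS = ["subgroup", "contrast", "measure", "estimate", "ci_lower", "ci_upper", "note"]


@dataclass
class GCompResult:
    """Point estimates plus percentile-bootstrap confidence intervals."""

    estimates: pd.DataFrame  # columns = ESTIMATE_COLUMNS
    marginal_means: dict[str, dict[str, float]]  # subgroup -> regime -> mean
    boot_draws: pd.DataFrame  # successful replicates x "subgroup|contrast|measure"
    n_boot_failed: int
    spec_echo: AnalysisSpec
    centering_value_used: float | None
    model_summary: dict

    def estimate(self, measure: str, subgroup: str = "overall", contrast: str | None = None) -> float:
        """Look up one point estimate (first contrast by default)."""
        rows = self.estimates
        sel = rows[(rows["measure"] == measure) & (rows["subgroup"] == subgroup)]
        if contrast is not None:
            sel = sel[sel["contrast"] == contrast]
        if len(sel) == 0:
            raise KeyError((measure, subgroup, contrast))
        return float(sel["estimate"].iloc[0])

    def interval(self, measure: str, subgroup: str = "overall", contrast: str | None = None) -> tuple[float, float]:
        rows = self.estimates
        sel = rows[(rows["measure"] == measure) & (rows["subgroup"] == subgroup)]
        if contrast is not None:
            sel = sel[sel["contrast"] == contrast]
        if len(sel) == 0:
            raise KeyError((measure, subgroup, contrast))
        lo, hi = sel["ci_lower"].iloc[0], sel["ci_upper"].iloc[0]
        return float(lo), float(hi)


def _spec_to_dict(spec: AnalysisSpec) -> dict:
    d = dataclasses.asdict(spec)
    return d


def write_result(result: GCompResult, path: str | Path, format: str = "tabular") -> Path:
    """Write a result as CSV (``tabular``) or JSON (``structured-report``)."""
    path = Path(path)
    if format == "tabular":
        result.estimates.to_csv(path, index=False)
    elif format == "structured-report":
        report = {
            "spec": _spec_to_dict(result.spec_echo),
            "seed": result.spec_echo.seed,
            "n_boot": result.spec_echo.n_boot,
            "n_boot_failed": result.n_boot_failed,
            "centering_value_used": result.centering_value_used,
            "percentile_convention": PERCENTILE_CONVENTION,
            "marginal_means": result.marginal_means,
            "model": result.model_summary,
            "estimates": result.estimates.replace({np.nan: None}).to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2)
    else:
        raise ValidationError(f"unknown result format {format!r}")
    return path


def read_report(path: str | Path) -> dict:
    """Re-read a structured JSON report (estimates round-trip losslessly)."""
    with open(path) as fh:
        report = json.load(fh)
    report["estimates"] = pd.DataFrame(
        report["estimates"], columns=ESTIMATE_COLUMNS
    ).astype({"estimate": float})
    return report
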