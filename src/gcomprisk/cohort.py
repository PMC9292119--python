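"""Tabular data model: typed cohort tables and analysis specifications.

A :class:`CohortTable` wraps a pandas DataFrame in which every column has an
explicit kind:

``binary01``
    integer column containing only 0/1 values;
``categorical``
    factor with an explicit ordered level list — the *first* level is the
    referent for all contrasts;
``numeric``
    continuous measurement;
``text``
    free text that has deliberately not been converted to a factor.  Text
    columns may not appear in a model.

An :class:`AnalysisSpec` describes one g-computation run: which column is
the outcome, which is the exposure, which covariates to adjust for, the
outcome family, and the bootstrap settings.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gcomprisk")

OUTCOME_TYPES = ("binary", "count", "count_nb", "rate", "rate_nb", "continuous")
#: outcome types modelled with a log link on counts (offset allowed)
COUNT_LIKE = ("count", "count_nb", "rate", "rate_nb")
COLUMN_KINDS = ("binary01", "categorical", "numeric", "text")


class ValidationError(ValueError):
    """Raised when a table or analysis specification is malformed."""


@dataclass
class CohortTable:
    """A validated observation table.

    Parameters
    ----------
    data
        The observations.  Categorical columns are stored as ordered
        ``pd.Categorical`` so the referent (first level) is unambiguous.
    kinds
        Column name -> kind (one of :data:`COLUMN_KINDS`).
    """

    data: pd.DataFrame
    kinds: dict[str, str]

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def levels(self, column: str) -> list:
        """Ordered level list of a categorical column (first = referent)."""
        if self.kinds.get(column) != "categorical":
            raise ValidationError(f"column {column!r} is not categorical")
        return list(self.data[column].cat.categories)

    def subset(self, mask: np.ndarray) -> "CohortTable":
        return CohortTable(self.data.loc[mask].reset_index(drop=True), dict(self.kinds))

    def __post_init__(self) -> None:
        for name, kind in self.kinds.items():
            if kind not in COLUMN_KINDS:
                raise ValidationError(f"unknown column kind {kind!r} for {name!r}")


@dataclass
class AnalysisSpec:
    """Configuration of one g-computation analysis.

    Exactly one of ``formula`` or ``outcome_name``+``exposure_name`` must be
    given.  ``formula`` is Wilkinson-style additive only
    (``Y ~ X + Z1 + Z2``); interaction syntax is rejected because subgroup
    analysis inserts the only interaction the model supports.
    """

    outcome_name: str | None = None
    exposure_name: str | None = None
    covariate_names: list[str] = field(default_factory=list)
    outcome_type: str = "binary"
    formula: str | None = None
    subgroup_name: str | None = None
    offset_name: str | None = None
    rate_multiplier: float = 1.0
    exposure_scalar: float = 1.0
    exposure_center: bool | float = True
    n_boot: int = 200
    cluster_id_name: str | None = None
    seed: int = 0
    parallel_workers: int = 1

    def referenced_columns(self) -> list[str]:
        cols = [self.outcome_name, self.exposure_name, *self.covariate_names]
        for extra in (self.subgroup_name, self.offset_name, self.cluster_id_name):
            if extra is not None:
                cols.append(extra)
        return [c for c in cols if c is not None]


# ---------------------------------------------------------------------------
# ingest


def _infer_kind(series: pd.Series) -> str:
    if series.dtype == object or pd.api.types.is_string_dtype(series):
        return "categorical"
    if pd.api.types.is_bool_dtype(series):
        return "binary01"
    values = series.dropna().unique()
    if pd.api.types.is_integer_dtype(series) and set(values) <= {0, 1}:
        return "binary01"
    if pd.api.types.is_float_dtype(series):
        nonnull = series.dropna()
        if len(nonnull) and (nonnull == nonnull.astype(np.int64)).all() and set(nonnull.unique()) <= {0.0, 1.0}:
            return "binary01"
    return "numeric"


def _as_categorical(series: pd.Series, levels: Sequence | None = None) -> pd.Series:
    if levels is None:
        levels = sorted(series.dropna().unique().tolist())
    cat = pd.Categorical(series, categories=list(levels), ordered=True)
    if series.notna().any() and pd.isna(cat).sum() > series.isna().sum():
        raise ValidationError("values outside the supplied level list")
    return pd.Series(cat, index=series.index, name=series.name)


def read_cohort(
    path: str | Path,
    column_types: Mapping[str, str | Sequence] | None = None,
) -> CohortTable:
    """Read a CSV file into a typed :class:`CohortTable`.

    ``column_types`` overrides inference per column.  A value may be a kind
    name (``"categorical"``, ``"numeric"``, ``"binary01"``, ``"text"``) or an
    explicit ordered level list, which forces a categorical with that order
    (first level = referent).  Without an override, string columns become
    categoricals with ascending-sorted levels, {0,1}-valued integer columns
    become ``binary01`` and everything else numeric.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh), None)
    if header is None:
        raise ValidationError(f"{path}: empty file")
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise ValidationError(f"{path}: duplicate column names {sorted(dupes)}")
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValidationError(f"{path}: empty table (header only)")
    return build_cohort(df, column_types)


def build_cohort(
    df: pd.DataFrame,
    column_types: Mapping[str, str | Sequence] | None = None,
) -> CohortTable:
    """Type an in-memory DataFrame exactly like :func:`read_cohort` would."""
    column_types = dict(column_types or {})
    unknown = set(column_types) - set(df.columns)
    if unknown:
        raise ValidationError(f"column_types refer to unknown columns {sorted(unknown)}")
    df = df.copy()
    kinds: dict[str, str] = {}
    for name in df.columns:
        override = column_types.get(name)
        if override is None:
            kind = _infer_kind(df[name])
            if kind == "categorical":
                df[name] = _as_categorical(df[name])
            kinds[name] = kind
        elif isinstance(override, str):
            if override not in COLUMN_KINDS:
                raise ValidationError(f"unknown column kind {override!r}")
            if override == "categorical":
                df[name] = _as_categorical(df[name])
            elif override == "binary01":
                vals = set(pd.Series(df[name]).dropna().unique())
                if not vals <= {0, 1, 0.0, 1.0, True, False}:
                    raise ValidationError(f"column {name!r} is not coded 0/1")
                df[name] = df[name].astype("Int64").astype("float").astype("Int64")
            kinds[name] = override
        else:  # explicit level list
            df[name] = _as_categorical(df[name], levels=override)
            kinds[name] = "categorical"
    return CohortTable(df, kinds)


# ---------------------------------------------------------------------------
# formula handling

_FORMULA_RE = re.compile(r"^\s*(?P<lhs>[^~]+?)\s*~\s*(?P<rhs>.+?)\s*$")


def parse_formula(formula: str) -> tuple[str, str, list[str]]:
    """Split ``Y ~ X + Z1 + Z2`` into (outcome, exposure, covariates).

    The first right-hand-side term is taken as the exposure.  ``*`` and
    ``:`` are rejected: the only interaction the model ever contains is the
    exposure-by-subgroup term added internally for subgroup analyses.
    """
    m = _FORMULA_RE.match(formula)
    if not m:
        raise ValidationError(f"cannot parse formula {formula!r}")
    rhs = m.group("rhs")
    if "*" in rhs or ":" in rhs:
        raise ValidationError("interaction terms ('*' or ':') are not allowed in the model formula")
    terms = [t.strip() for t in rhs.split("+")]
    if any(not t for t in terms):
        raise ValidationError(f"malformed formula right-hand side {rhs!r}")
    return m.group("lhs"), terms[0], terms[1:]


# ---------------------------------------------------------------------------
# validation


def _coerce_binary_outcome(series: pd.Series, kind: str) -> pd.Series:
    """Map a binary outcome column to float 0/1 (first level -> 0)."""
    if kind == "binary01":
        return series.astype(float)
    if kind == "categorical":
        levels = series.cat.categories
        if len(levels) != 2:
            raise ValidationError(
                f"binary outcome {series.name!r} has {len(levels)} levels; expected 2"
            )
        return (series.cat.codes == 1).astype(float)
    if kind == "numeric":
        vals = set(series.dropna().unique())
        if not vals <= {0.0, 1.0}:
            raise ValidationError(f"binary outcome {series.name!r} is not coded 0/1")
        return series.astype(float)
    raise ValidationError(f"outcome {series.name!r} is free text; not usable as binary outcome")


def validate_spec(
    table: CohortTable,
    spec: AnalysisSpec,
    drop_missing: bool = False,
) -> tuple[CohortTable, AnalysisSpec]:
    """Check an (table, spec) pair and return a normalized copy of both.

    Normalizations: a formula is resolved into outcome/exposure/covariate
    names; binary01 exposures become two-level factors (referent 0); the
    subgroup column is coerced to a factor; a binary outcome is coerced to
    float 0/1.  Validation is idempotent — validating the returned pair
    again is a no-op.

    Rows with missing values in any referenced column are rejected with a
    counted error unless ``drop_missing`` is set, in which case they are
    removed and the count logged.
    """
    spec = replace(spec, covariate_names=list(spec.covariate_names))
    if spec.outcome_type not in OUTCOME_TYPES:
        raise ValidationError(
            f"unknown outcome_type {spec.outcome_type!r}; expected one of {OUTCOME_TYPES}"
        )
    if spec.formula is not None:
        if spec.outcome_name is not None or spec.exposure_name is not None:
            raise ValidationError("provide either a formula or outcome/exposure names, not both")
        y, x, z = parse_formula(spec.formula)
        spec = replace(spec, outcome_name=y, exposure_name=x, covariate_names=z, formula=None)
    if spec.outcome_name is None or spec.exposure_name is None:
        raise ValidationError("both an outcome and an exposure column are required")
    for name in spec.covariate_names:
        if "*" in name or ":" in name:
            raise ValidationError("interaction terms ('*' or ':') are not allowed in covariates")

    df = table.data
    kinds = dict(table.kinds)
    missing_cols = [c for c in spec.referenced_columns() if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"unknown column name(s): {missing_cols}")

    # missing data: loud failure, opt-in listwise deletion with a logged count
    ref = spec.referenced_columns()
    na_mask = df[ref].isna().any(axis=1).to_numpy()
    if na_mask.any():
        if not drop_missing:
            raise ValidationError(
                f"{int(na_mask.sum())} row(s) have missing values in referenced columns "
                f"{ref}; pass drop_missing=True to delete them listwise"
            )
        logger.info("dropping %d row(s) with missing values in referenced columns", int(na_mask.sum()))
        df = df.loc[~na_mask].reset_index(drop=True)
    else:
        df = df.copy()
    if len(df) == 0:
        raise ValidationError("no rows remain after removing missing data")

    # exposure: factor (referent first) or numeric
    xkind = kinds[spec.exposure_name]
    if xkind == "text":
        raise ValidationError(
            f"exposure {spec.exposure_name!r} is free text; supply it as a factor "
            "(categorical with ordered levels) or a numeric column"
        )
    if xkind == "binary01":
        df[spec.exposure_name] = _as_categorical(df[spec.exposure_name], levels=[0, 1])
        kinds[spec.exposure_name] = "categorical"
        xkind = "categorical"
    if xkind == "categorical":
        observed = df[spec.exposure_name].cat.categories
        if len(observed) < 2:
            raise ValidationError(f"exposure {spec.exposure_name!r} has fewer than 2 levels")
        if spec.exposure_scalar != 1.0 or spec.exposure_center is not True:
            raise ValidationError(
                "exposure_scalar / exposure_center apply to numeric exposures only"
            )

    # covariates must be modelable
    for name in spec.covariate_names:
        if kinds[name] == "text":
            raise ValidationError(f"covariate {name!r} is free text; not usable in a model")

    # offset / rate multiplier legality
    if spec.outcome_type not in COUNT_LIKE:
        if spec.offset_name is not None:
            raise ValidationError(f"offset is only legal for rate/count outcomes, not {spec.outcome_type!r}")
        if spec.rate_multiplier != 1.0:
            raise ValidationError("rate_multiplier is only legal for rate/count outcomes")
    if spec.outcome_type in ("rate", "rate_nb") and spec.offset_name is None:
        raise ValidationError("offset (person-time column) required for rate outcomes")
    if spec.offset_name is not None:
        off = df[spec.offset_name]
        if kinds[spec.offset_name] not in ("numeric", "binary01") or not (off > 0).all():
            raise ValidationError(f"offset {spec.offset_name!r} must be strictly positive numeric")
        kinds[spec.offset_name] = "numeric"
        df[spec.offset_name] = off.astype(float)
    if spec.rate_multiplier <= 0:
        raise ValidationError("rate_multiplier must be positive")
    if spec.exposure_scalar <= 0:
        raise ValidationError("exposure_scalar must be positive")
    if spec.n_boot < 1:
        raise ValidationError("n_boot must be at least 1")

    # subgroup -> factor
    if spec.subgroup_name is not None:
        sg = spec.subgroup_name
        if kinds[sg] != "categorical":
            df[sg] = _as_categorical(df[sg])
            kinds[sg] = "categorical"

    # outcome coercion
    ykind = kinds[spec.outcome_name]
    yname = spec.outcome_name
    if spec.outcome_type == "binary":
        df[yname] = _coerce_binary_outcome(df[yname], ykind)
        kinds[yname] = "numeric"
    elif spec.outcome_type in COUNT_LIKE:
        if ykind == "categorical":
            df[yname] = pd.to_numeric(df[yname].astype(str))
            kinds[yname] = "numeric"
        elif ykind == "text":
            raise ValidationError(f"count outcome {yname!r} is free text")
        y = df[yname].astype(float)
        if (y < 0).any() or not np.allclose(y, np.round(y)):
            raise ValidationError(f"count outcome {yname!r} must be non-negative integers")
        df[yname] = y
        kinds[yname] = "numeric"
    else:  # continuous
        if ykind in ("categorical", "text"):
            raise ValidationError(f"continuous outcome {yname!r} must be numeric")
        df[yname] = df[yname].astype(float)
        kinds[yname] = "numeric"

    return CohortTable(df, kinds), spec
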