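"""Tabular cohort handling: loading, exclusion rules, outcome derivation,
min-max scaling, and stratified train/validation splitting.

A cohort is a subjects-by-features numeric matrix plus a binary high/low
CHD-risk outcome.  Categorical features are stored as level indices; the
CSV dialect uses level labels.  Missing entries (empty cell or the literal
``Null``) and under-age records are excluded at load time with an auditable
:class:`ExclusionReport`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .exceptions import DegenerateInputError, SchemaError, ValidationError

KIND_CONTINUOUS = "continuous"
KIND_BINARY = "binary"
KIND_ORDINAL = "ordinal"
_KINDS = (KIND_CONTINUOUS, KIND_BINARY, KIND_ORDINAL)

#: tokens treated as missing in the CSV dialect
MISSING_TOKENS = ("", "Null")

#: default split seed used across the package
DEFAULT_SPLIT_SEED = 20170906

#: component conditions whose presence defines high CHD risk
COMPONENT_DISEASES = (
    "hypertension",
    "dyslipidemia",
    "stroke",
    "myocardial_infarction",
    "angina",
)


@dataclass(frozen=True)
class FeatureSpec:
    """Schema for one feature column.

    ``levels`` orders the categorical labels (index = numeric code);
    ``valid_range`` gives inclusive plausibility bounds for continuous
    features and is used only for flagging, never for exclusion.
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None
    valid_range: tuple[float, float] | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.kind == KIND_CONTINUOUS:
            if self.valid_range is not None and not self.valid_range[0] < self.valid_range[1]:
                raise ValidationError(f"{self.name}: valid_range low must be < high")
        else:
            if self.levels is None or len(self.levels) < 2:
                raise ValidationError(f"{self.name}: categorical feature needs >= 2 levels")
            if self.kind == KIND_BINARY and len(self.levels) != 2:
                raise ValidationError(f"{self.name}: binary feature needs exactly 2 levels")

    @property
    def n_levels(self) -> int:
        return 0 if self.levels is None else len(self.levels)

    @property
    def is_continuous(self) -> bool:
        return self.kind == KIND_CONTINUOUS


@dataclass
class CohortTable:
    """N records x F features with a binary outcome (1 = high CHD risk)."""

    specs: tuple[FeatureSpec, ...]
    values: np.ndarray
    outcome: np.ndarray
    ids: np.ndarray
    range_violations: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=np.int8)
        self.ids = np.asarray(self.ids)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, f = self.values.shape
        if f != len(self.specs):
            raise ValidationError("values width does not match number of specs")
        if n == 0:
            raise DegenerateInputError("cohort has no records")
        if self.outcome.shape != (n,) or self.ids.shape != (n,):
            raise ValidationError("outcome/ids length mismatch")
        if not np.isfinite(self.values).all():
            raise ValidationError("cohort contains non-finite values")
        if not np.isin(self.outcome, (0, 1)).all():
            raise ValidationError("outcome must be binary 0/1")

    # -- basic introspection -------------------------------------------------
    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    def index(self, feature: str) -> int:
        try:
            return self.feature_names.index(feature)
        except ValueError:
            raise KeyError(f"unknown feature {feature!r}") from None

    def column(self, feature: str) -> np.ndarray:
        return self.values[:, self.index(feature)]

    def has_both_classes(self) -> bool:
        return bool(self.outcome.min() == 0 and self.outcome.max() == 1)

    # -- derived tables ------------------------------------------------------
    def with_values(self, values: np.ndarray) -> "CohortTable":
        return CohortTable(self.specs, values, self.outcome.copy(), self.ids.copy(),
                           dict(self.range_violations))

    def select_features(self, names: Sequence[str]) -> "CohortTable":
        idx = [self.index(n) for n in names]
        specs = tuple(self.specs[i] for i in idx)
        return CohortTable(specs, self.values[:, idx].copy(), self.outcome.copy(),
                           self.ids.copy())

    def subset(self, rows: np.ndarray) -> "CohortTable":
        return CohortTable(self.specs, self.values[rows].copy(), self.outcome[rows].copy(),
                           self.ids[rows].copy(), dict(self.range_violations))

    def to_dataframe(self, labels: bool = False) -> pd.DataFrame:
        """Tabular view; with ``labels=True`` categoricals use level labels."""
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        if labels:
            for s in self.specs:
                if s.levels is not None:
                    codes = df[s.name].round().astype(int).clip(0, s.n_levels - 1)
                    df[s.name] = [s.levels[c] for c in codes]
        df.insert(0, "id", self.ids)
        df["chd_risk"] = self.outcome
        return df

    def to_csv(self, path: str | Path, labels: bool = True) -> None:
        self.to_dataframe(labels=labels).to_csv(path, index=False)


@dataclass(frozen=True)
class ExclusionReport:
    """Record-level exclusion audit; missing-first, then age."""

    n_raw: int
    n_excluded_missing: int
    n_excluded_age: int
    n_final: int

    def __post_init__(self) -> None:
        counts = (self.n_raw, self.n_excluded_missing, self.n_excluded_age, self.n_final)
        if any(c < 0 for c in counts):
            raise ValidationError("exclusion counts must be nonnegative")
        if self.n_final != self.n_raw - self.n_excluded_missing - self.n_excluded_age:
            raise ValidationError("exclusion counts do not sum")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature parameters for the min-max transform to [0, 1]."""

    bounds: dict[str, tuple[float, float]]
    n_levels: dict[str, int]
    constant_features: tuple[str, ...] = ()


def specs_to_json(specs: Iterable[FeatureSpec]) -> str:
    return json.dumps([dataclasses.asdict(s) for s in specs], indent=2)


def specs_from_json(text: str) -> tuple[FeatureSpec, ...]:
    out = []
    for d in json.loads(text):
        d = dict(d)
        if d.get("levels") is not None:
            d["levels"] = tuple(d["levels"])
        if d.get("valid_range") is not None:
            d["valid_range"] = tuple(d["valid_range"])
        out.append(FeatureSpec(**d))
    return tuple(out)


def derive_outcome(component_flags: np.ndarray) -> np.ndarray:
    """High risk (1) iff any of the five component conditions is present."""
    flags = np.asarray(component_flags)
    if flags.ndim != 2 or flags.shape[1] != len(COMPONENT_DISEASES):
        raise ValidationError(f"expected an N x {len(COMPONENT_DISEASES)} flag matrix")
    if not np.isin(flags, (0, 1)).all():
        raise ValidationError("component flags must be 0/1")
    return (flags.max(axis=1) > 0).astype(np.int8)


def _parse_column(raw: pd.Series, spec: FeatureSpec) -> np.ndarray:
    if spec.is_continuous:
        try:
            return raw.astype(float).to_numpy()
        except ValueError as exc:
            raise ValidationError(f"{spec.name}: non-numeric value ({exc})") from exc
    mapping = {lab: i for i, lab in enumerate(spec.levels or ())}
    out = np.empty(len(raw), dtype=float)
    for pos, v in enumerate(raw):
        if v in mapping:
            out[pos] = mapping[v]
            continue
        try:
            code = int(float(v))
        except ValueError:
            raise ValidationError(f"{spec.name}: unknown level {v!r}") from None
        if not 0 <= code < spec.n_levels:
            raise ValidationError(f"{spec.name}: level code {code} out of range")
        out[pos] = code
    return out


def load_cohort(
    path: str | Path,
    specs: Sequence[FeatureSpec],
    *,
    outcome_column: str | None = "chd_risk",
    component_columns: Sequence[str] | None = None,
    age_column: str = "age",
    min_age: float = 30.0,
    id_column: str = "id",
) -> tuple[CohortTable, ExclusionReport]:
    """Load a cohort CSV, applying the missing-then-age exclusion rules.

    Records with any missing spec'd or outcome field are excluded first; of
    the remainder, records with age below ``min_age`` are excluded.  Each
    record is counted once, in the first rule it violates.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    specs = tuple(specs)

    needed = [s.name for s in specs]
    if component_columns is not None:
        needed += list(component_columns)
    elif outcome_column is not None:
        if outcome_column not in df.columns:
            # fall back to the five component-disease columns
            if all(c in df.columns for c in COMPONENT_DISEASES):
                component_columns = COMPONENT_DISEASES
                needed += list(COMPONENT_DISEASES)
            else:
                raise SchemaError(f"outcome column {outcome_column!r} not in file")
        else:
            needed += [outcome_column]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"columns missing from file: {missing_cols}")

    n_raw = len(df)
    is_missing = pd.DataFrame(
        {c: df[c].isin(MISSING_TOKENS) for c in needed}
    ).any(axis=1)
    n_missing = int(is_missing.sum())
    kept = df.loc[~is_missing]

    if age_column in kept.columns:
        ages = kept[age_column].astype(float)
        underage = ages < min_age
    else:
        underage = pd.Series(False, index=kept.index)
    n_age = int(underage.sum())
    final = kept.loc[~underage]
    n_final = len(final)
    report = ExclusionReport(n_raw, n_missing, n_age, n_final)
    if n_final == 0:
        raise DegenerateInputError("no records remain after exclusions")

    values = np.column_stack([_parse_column(final[s.name], s) for s in specs])
    if component_columns is not None:
        flags = np.column_stack(
            [final[c].astype(float).round().astype(int) for c in component_columns]
        )
        outcome = derive_outcome(flags)
    else:
        outcome = final[outcome_column].astype(float).round().astype(np.int8).to_numpy()
        if not np.isin(outcome, (0, 1)).all():
            raise ValidationError("outcome column must be binary 0/1")
    ids = (final[id_column].to_numpy() if id_column in final.columns
           else final.index.to_numpy())

    table = CohortTable(specs, values, outcome, ids)
    # plausibility flags, not exclusions
    for s in specs:
        if s.is_continuous and s.valid_range is not None:
            col = table.column(s.name)
            bad = int(((col < s.valid_range[0]) | (col > s.valid_range[1])).sum())
            if bad:
                table.range_violations[s.name] = bad
    return table, report


def scale_features(
    table: CohortTable, params: ScalingParams | None = None
) -> tuple[CohortTable, ScalingParams]:
    """Min-max scale continuous features to [0, 1]; categoricals to
    level_index / (n_levels - 1).

    When ``params`` is given (e.g. bounds learned on the training split) it
    is reused, so validation data is scaled consistently.  Constant
    continuous features scale to 0 and are flagged.
    """
    values = table.values.copy()
    bounds: dict[str, tuple[float, float]] = {}
    n_levels: dict[str, int] = {}
    constant: list[str] = []
    for j, s in enumerate(table.specs):
        col = values[:, j]
        if s.is_continuous:
            if params is not None:
                lo, hi = params.bounds[s.name]
            else:
                lo, hi = float(col.min()), float(col.max())
            bounds[s.name] = (lo, hi)
            if hi == lo:
                values[:, j] = 0.0
                constant.append(s.name)
            else:
                values[:, j] = (col - lo) / (hi - lo)
        else:
            levels = params.n_levels[s.name] if params is not None else s.n_levels
            n_levels[s.name] = levels
            values[:, j] = col / (levels - 1)
    if params is not None:
        constant = list(params.constant_features)
    return table.with_values(values), ScalingParams(bounds, n_levels, tuple(constant))


def split_train_validation(
    table: CohortTable, fraction: float = 0.7, seed: int = DEFAULT_SPLIT_SEED
) -> tuple[CohortTable, CohortTable]:
    """Stratified, reproducible split into (training, validation) tables."""
    if not 0.0 < fraction < 1.0:
        raise ValidationError("fraction must be in (0, 1)")
    if not table.has_both_classes():
        raise DegenerateInputError("both outcome classes required for a stratified split")
    idx = np.arange(table.n_records)
    train_idx, val_idx = train_test_split(
        idx, train_size=fraction, random_state=seed, stratify=table.outcome
    )
    return table.subset(np.sort(train_idx)), table.subset(np.sort(val_idx))
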