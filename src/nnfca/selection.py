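"""Stepwise elimination of the least-sensitive feature with retraining.

At each stage a dense network is trained on the remaining features, the
sensitivity profile is computed, the lowest-ranked feature is removed, the
network is retrained, and validation accuracy is recorded.  The full
accuracy-vs-removals curve is kept; the selected subset is the stage with
the best accuracy (ties favour fewer removals).  Both early-stopping
variants — stop when accuracy drops below the previous stage, or below the
all-features baseline — are available behind ``stop_rule``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort_io import (DEFAULT_SPLIT_SEED, CohortTable, split_train_validation)
from .exceptions import StageError, ValidationError
from .masked_mlp import TrainingConfig, fit_network
from .sensitivity import PerturbationSpec, sensitivity_profile

#: packaged reference elimination curve (published 16-feature CHD analysis)
REFERENCE_CURVE_RESOURCE = "chd_elimination_curve.csv"

#: the 16 input features of the reference CHD analysis, in printed order
CHD_FEATURES = (
    "age", "sex", "BMI", "To_chole", "HDL", "SBP", "DBP", "triglyceride",
    "hemoglobin", "TD", "CRF", "H_B", "H_C", "cirrhosis", "smoking", "diabetes",
)


@dataclass(frozen=True)
class Stage:
    removed: tuple[str, ...]  # cumulative removed set, oldest first
    accuracy: float           # percent on the validation split


@dataclass
class EliminationTrace:
    feature_names: tuple[str, ...]
    stages: tuple[Stage, ...]
    baseline_accuracy: float | None = None

    def __post_init__(self) -> None:
        prev: tuple[str, ...] = ()
        for k, st in enumerate(self.stages, start=1):
            if len(st.removed) != k:
                raise ValidationError(f"stage {k} must have exactly {k} removed features")
            if st.removed[:-1] != prev:
                raise ValidationError("removed sets must be nested")
            if st.removed[-1] not in self.feature_names:
                raise ValidationError(f"unknown feature {st.removed[-1]!r} in trace")
            prev = st.removed

    @classmethod
    def from_accuracies(
        cls,
        feature_names: Sequence[str],
        removal_order: Sequence[str],
        accuracies: Sequence[float],
        baseline_accuracy: float | None = None,
    ) -> "EliminationTrace":
        """Build a trace from a recorded removal order and accuracy curve
        (replay mode for published or externally computed curves)."""
        if len(removal_order) != len(accuracies):
            raise ValidationError("removal_order and accuracies length mismatch")
        stages = tuple(
            Stage(tuple(removal_order[: k + 1]), float(a))
            for k, a in enumerate(accuracies)
        )
        return cls(tuple(feature_names), stages, baseline_accuracy)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"stage": k + 1, "removed_feature": st.removed[-1],
                 "cumulative_removed": ";".join(st.removed),
                 "accuracy": st.accuracy}
                for k, st in enumerate(self.stages)]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self) -> str:
        return json.dumps({
            "feature_names": list(self.feature_names),
            "baseline_accuracy": self.baseline_accuracy,
            "stages": [{"removed": list(s.removed), "accuracy": s.accuracy}
                       for s in self.stages],
        })


@dataclass(frozen=True)
class BestStage:
    selected_features: tuple[str, ...]
    n_removed: int
    accuracy: float


def _default_fit_score(
    train_table: CohortTable,
    val_table: CohortTable,
    config: TrainingConfig,
    n_hidden: int,
    threshold: float = 0.5,
):
    net = fit_network(train_table, config, n_hidden=n_hidden)
    pred = net.predict(val_table.values, threshold=threshold)
    acc = 100.0 * float(np.mean(pred == val_table.outcome))
    return net, acc


def stepwise_eliminate(
    table: CohortTable,
    train_config: TrainingConfig,
    pert: PerturbationSpec,
    max_remove: int,
    *,
    val_table: CohortTable | None = None,
    split_fraction: float = 0.7,
    split_seed: int = DEFAULT_SPLIT_SEED,
    n_hidden: int = 4,
    stop_rule: str = "full",
    fit_score: Callable | None = None,
    rank_scores: Callable | None = None,
) -> EliminationTrace:
    """Train / rank / remove-lowest / retrain for up to ``max_remove`` stages.

    ``table`` must already be scaled to [0, 1].  When ``val_table`` is None
    the table is split internally (stratified ``split_fraction``).  Hooks:
    ``fit_score(train, val) -> (net, accuracy%)`` replaces training and
    scoring, ``rank_scores(net, train) -> SensitivityProfile`` replaces the
    sensitivity computation — with deterministic hooks the loop is a pure
    function of its inputs.
    """
    if stop_rule not in ("full", "previous", "original"):
        raise ValidationError(f"unknown stop_rule {stop_rule!r}")
    if max_remove >= table.n_features:
        raise ValidationError("max_remove must be smaller than the feature count")
    if val_table is None:
        train_table, val_table = split_train_validation(table, split_fraction, split_seed)
    else:
        train_table = table
    if fit_score is None:
        fit_score = lambda tr, va: _default_fit_score(tr, va, train_config, n_hidden)
    if rank_scores is None:
        rank_scores = lambda net, tr: sensitivity_profile(net, tr, pert)

    remaining = list(table.feature_names)
    net, baseline_acc = fit_score(train_table, val_table)
    stages: list[Stage] = []
    removed: list[str] = []
    prev_acc = baseline_acc
    for _ in range(max_remove):
        cur_train = train_table.select_features(remaining)
        if not cur_train.has_both_classes():
            raise StageError(f"class collapse with features {remaining}")
        profile = rank_scores(net, cur_train)
        victim = profile.lowest_ranked()
        remaining.remove(victim)
        removed.append(victim)
        new_train = train_table.select_features(remaining)
        new_val = val_table.select_features(remaining)
        net, acc = fit_score(new_train, new_val)
        stages.append(Stage(tuple(removed), acc))
        if stop_rule == "previous" and acc < prev_acc:
            break
        if stop_rule == "original" and acc < baseline_acc:
            break
        prev_acc = acc
    return EliminationTrace(table.feature_names, tuple(stages), baseline_acc)


def select_best_stage(trace: EliminationTrace) -> BestStage:
    """Stage with maximum accuracy; ties resolved toward fewer removals."""
    candidates: list[tuple[int, tuple[str, ...], float]] = []
    if trace.baseline_accuracy is not None:
        candidates.append((0, (), trace.baseline_accuracy))
    for st in trace.stages:
        candidates.append((len(st.removed), st.removed, st.accuracy))
    if not candidates:
        raise ValidationError("trace is empty")
    best = max(candidates, key=lambda c: (c[2], -c[0]))
    n_removed, removed, acc = best
    selected = tuple(f for f in trace.feature_names if f not in removed)
    return BestStage(selected, n_removed, acc)


def load_reference_curve() -> EliminationTrace:
    """Packaged elimination curve of the published 16-feature CHD analysis
    (removal order + accuracy per stage; no baseline accuracy was printed)."""
    resource = files("nnfca.data").joinpath(REFERENCE_CURVE_RESOURCE)
    with resource.open("r") as fh:
        df = pd.read_csv(fh)
    return EliminationTrace.from_accuracies(
        CHD_FEATURES, df["removed_feature"].tolist(), df["accuracy"].tolist()
    )
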