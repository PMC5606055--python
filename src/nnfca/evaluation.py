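"""Confusion-matrix metrics, ROC AUC with bootstrap CI, and the logistic
baseline comparator.

PPV = TP/(TP+FP), NPV = TN/(TN+FN), accuracy = (TP+TN)/N, each reported as
a percentage; AUC by the rank (Mann-Whitney) construction with half credit
for ties; the 95% CI is a seeded percentile bootstrap over records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .cohort_io import CohortTable
from .exceptions import DegenerateInputError, ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """Percent-scale predictive values; AUC on [0, 1] when computed."""

    ppv: float
    npv: float
    accuracy: float
    ppv_defined: bool = True
    npv_defined: bool = True
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    flags: tuple[str, ...] = ()

    def to_json(self) -> str:
        d = asdict(self)
        d["flags"] = list(self.flags)
        return json.dumps(d)


def _check_aligned(labels, scores):
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValidationError("labels and scores must be aligned 1-D arrays")
    if not np.isin(labels, (0, 1)).all():
        raise ValidationError("labels must be binary 0/1")
    return labels, scores


def confusion_metrics(
    labels, scores, threshold: float = 0.5
) -> tuple[ConfusionCounts, MetricsReport]:
    """Counts and percent metrics at ``score >= threshold`` positivity."""
    if not 0 < threshold < 1:
        raise ValidationError("threshold must be in (0, 1)")
    labels, scores = _check_aligned(labels, scores)
    pred = scores >= threshold
    pos = labels == 1
    counts = ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
    )
    ppv_def = counts.tp + counts.fp > 0
    npv_def = counts.tn + counts.fn > 0
    report = MetricsReport(
        ppv=100.0 * counts.tp / (counts.tp + counts.fp) if ppv_def else float("nan"),
        npv=100.0 * counts.tn / (counts.tn + counts.fn) if npv_def else float("nan"),
        accuracy=100.0 * (counts.tp + counts.tn) / counts.n,
        ppv_defined=ppv_def,
        npv_defined=npv_def,
    )
    return counts, report


def roc_auc(labels, scores) -> float:
    """AUC = P(random positive outscores random negative), ties count 1/2."""
    labels, scores = _check_aligned(labels, scores)
    if labels.min() == labels.max():
        raise DegenerateInputError("both classes required for ROC AUC")
    return float(roc_auc_score(labels, scores))


def auc_ci(labels, scores, n_boot: int = 1000, seed: int = 0) -> tuple[float, float]:
    """95% percentile-bootstrap interval for the AUC (resampling records).

    Single-class resamples are skipped; requires n_boot >= 100.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    labels, scores = _check_aligned(labels, scores)
    rng = np.random.default_rng(seed)
    n = len(labels)
    stats = []
    while len(stats) < n_boot:
        idx = rng.integers(0, n, size=n)
        lb = labels[idx]
        if lb.min() == lb.max():
            continue
        stats.append(roc_auc_score(lb, scores[idx]))
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


def evaluate_scores(
    labels, scores, threshold: float = 0.5, n_boot: int = 1000, seed: int = 0
) -> MetricsReport:
    """Confusion metrics plus AUC and its bootstrap CI, in one report."""
    _, report = confusion_metrics(labels, scores, threshold)
    report.auc = roc_auc(labels, scores)
    report.auc_ci = auc_ci(labels, scores, n_boot=n_boot, seed=seed)
    return report


def fit_logistic_baseline(
    train: CohortTable,
    validate: CohortTable,
    threshold: float = 0.5,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[MetricsReport, LogisticRegression]:
    """Unpenalised maximum-likelihood logistic comparator.

    Metrics are computed on the validation table; a ``separation`` flag is
    raised when the model classifies the training data perfectly (its
    coefficients are then unbounded in principle).
    """
    if not train.has_both_classes():
        raise DegenerateInputError("training table must contain both classes")
    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
    model.fit(train.values, train.outcome)
    train_acc = float(np.mean(model.predict(train.values) == train.outcome))
    scores = model.predict_proba(validate.values)[:, 1]
    report = evaluate_scores(validate.outcome, scores, threshold, n_boot, seed)
    if train_acc == 1.0:
        report.flags = report.flags + ("separation",)
    return report, model


def render_comparison(results: dict[str, tuple[MetricsReport, MetricsReport]]) -> str:
    """Text table of (training, validation) PPV / NPV / accuracy per model."""
    header = (f"{'Model':<10}{'PPV(tr)':>9}{'NPV(tr)':>9}{'Acc(tr)':>9}"
              f"{'PPV(va)':>9}{'NPV(va)':>9}{'Acc(va)':>9}{'AUC(va)':>9}")
    lines = [header, "-" * len(header)]
    for name, (tr, va) in results.items():
        auc = f"{va.auc:.3f}" if va.auc is not None else "-"
        lines.append(
            f"{name:<10}{tr.ppv:>9.2f}{tr.npv:>9.2f}{tr.accuracy:>9.2f}"
            f"{va.ppv:>9.2f}{va.npv:>9.2f}{va.accuracy:>9.2f}{auc:>9}"
        )
    return "\n".join(lines)
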