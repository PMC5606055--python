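"""Feature-correlation analysis from amplification-induced sensitivity
changes.

Amplifying one feature j (adding a small delta to it across the whole
dataset) shifts the sensitivities of the other features.  The F x F grid of
absolute sensitivity changes is thresholded column-wise at the column
average: features whose change under amplification of j meets the average
are *candidates* for correlation with j.  Two features are declared
correlated only if each is a candidate under amplification of the other
(mutuality).  Correlated groups are then wired to shared hidden-unit blocks
in a coupled-connection network mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cohort_io import CohortTable
from .exceptions import ValidationError
from .masked_mlp import NetworkSpec, TrainedNetwork
from .sensitivity import (_STREAM_AMP, PerturbationSpec, feature_sensitivity,
                          perturb_feature)

#: packaged 9-feature reference matrix (published CHD cohort analysis)
REFERENCE_MATRIX_RESOURCE = "chd_sensitivity_change_matrix.csv"

#: slack absorbing 3-decimal rounding when thresholding PRINTED fixtures;
#: freshly computed matrices are exact and use no slack
PRINTED_ROUNDING_TOL = 5e-4
DEFAULT_CANDIDATE_TOL = 0.0


@dataclass
class SensitivityChangeMatrix:
    """cells[i, j] = |Sen of feature i after amplifying j  -  baseline Sen of i|.

    ``column_means`` (mean over all F rows, diagonal included) is the
    candidacy threshold per amplified feature.  It is recomputed from the
    cells unless explicitly supplied — a loaded fixture keeps its printed
    averages, which is what its published candidate decisions were based on.
    """

    feature_names: tuple[str, ...]
    cells: np.ndarray
    column_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        f = len(self.feature_names)
        if self.cells.shape != (f, f):
            raise ValidationError("cells must be F x F")
        if (self.cells < 0).any():
            raise ValidationError("sensitivity changes must be nonnegative")
        if self.column_means is None:
            self.column_means = self.cells.mean(axis=0)
        else:
            self.column_means = np.asarray(self.column_means, dtype=float)
            if self.column_means.shape != (f,):
                raise ValidationError("column_means length mismatch")

    def validate_means(self, tol: float = 1e-3) -> None:
        """Check stored means against recomputed ones (rounding slack tol)."""
        if np.abs(self.column_means - self.cells.mean(axis=0)).max() > tol:
            raise ValidationError("column_means inconsistent with cells")

    def index(self, feature: str) -> int:
        return self.feature_names.index(feature)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.cells, columns=list(self.feature_names))
        df.insert(0, "feature", list(self.feature_names))
        return df

    def to_csv(self, path: str | Path, decimals: int | None = None) -> None:
        df = self.to_dataframe()
        avg = pd.DataFrame([["Average", *self.column_means]], columns=df.columns)
        out = pd.concat([df, avg], ignore_index=True)
        if decimals is not None:
            for c in self.feature_names:
                out[c] = out[c].round(decimals)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SensitivityChangeMatrix":
        """Read the feature-by-amplified-feature layout; an optional trailing
        ``Average`` row becomes the stored column means."""
        df = pd.read_csv(path)
        names = tuple(df.columns[1:])
        labels = df.iloc[:, 0].tolist()
        means = None
        if labels and str(labels[-1]).lower() == "average":
            means = df.iloc[-1, 1:].to_numpy(dtype=float)
            df = df.iloc[:-1]
            labels = labels[:-1]
        if tuple(labels) != names:
            raise ValidationError("row labels must match column feature names")
        return cls(names, df.iloc[:, 1:].to_numpy(dtype=float), means)

    @classmethod
    def reference(cls) -> "SensitivityChangeMatrix":
        """The packaged 9-feature reference matrix."""
        return load_reference_matrix()


@dataclass
class CandidateSets:
    """Per amplified feature j: features whose change met the column mean."""

    feature_names: tuple[str, ...]
    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for j, cand in self.sets.items():
            if j in cand:
                raise ValidationError("a feature cannot be its own candidate")

    def to_json(self) -> str:
        return json.dumps({k: sorted(v) for k, v in self.sets.items()})


@dataclass
class CorrelationGraph:
    """Mutually confirmed pairs and their connected-component groups."""

    feature_names: tuple[str, ...]
    pairs: frozenset[frozenset[str]]
    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        seen = [f for g in self.groups for f in g]
        if sorted(seen) != sorted(self.feature_names):
            raise ValidationError("groups must partition the feature set")
        for p in self.pairs:
            if not any(set(p) <= set(g) for g in self.groups):
                raise ValidationError("every pair must lie inside one group")

    def pair_tuples(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(p)) for p in self.pairs)

    def to_json(self) -> str:
        return json.dumps({"pairs": self.pair_tuples(),
                           "groups": [list(g) for g in self.groups]})


def sensitivity_change_matrix(
    net: TrainedNetwork,
    table: CohortTable,
    pert: PerturbationSpec,
    amp_delta: float | None = None,
) -> SensitivityChangeMatrix:
    """Compute the full F x F sensitivity-change grid.

    Each feature i keeps the same seeded delta for its baseline and
    amplified sensitivity, so the measured change isolates the effect of
    amplifying j.  ``amp_delta`` forces a fixed amplification delta (tests).
    """
    names = table.feature_names
    f = len(names)
    sens_deltas = [pert.draw(0, i, table.n_records) for i in range(f)]
    baseline_out = np.asarray(net.forward(table.values))
    base_sen = np.array([
        feature_sensitivity(net, table, names[i], pert, delta=sens_deltas[i],
                            baseline=baseline_out)
        for i in range(f)
    ])
    cells = np.empty((f, f))
    for j in range(f):
        dj = pert.draw(_STREAM_AMP, j, table.n_records) if amp_delta is None else amp_delta
        amped = perturb_feature(table, names[j], dj)
        amped_out = np.asarray(net.forward(amped.values))
        for i in range(f):
            sen_amp = feature_sensitivity(net, amped, names[i], pert,
                                          delta=sens_deltas[i], baseline=amped_out)
            cells[i, j] = abs(sen_amp - base_sen[i])
    return SensitivityChangeMatrix(names, cells)


def column_candidates(
    matrix: SensitivityChangeMatrix, tol: float = DEFAULT_CANDIDATE_TOL
) -> CandidateSets:
    """Features meeting their column's average change (diagonal excluded).

    ``tol`` loosens the threshold to ``column_mean - tol``; pass
    :data:`PRINTED_ROUNDING_TOL` when the matrix holds 3-decimal rounded
    published values, so candidacy decisions made on unrounded internals
    survive the rounding.
    """
    names = matrix.feature_names
    sets: dict[str, frozenset[str]] = {}
    for j, amplified in enumerate(names):
        # tiny absolute guard so exact ties survive summation rounding
        thr = matrix.column_means[j] - tol - 1e-12
        sets[amplified] = frozenset(
            names[i] for i in range(len(names))
            if i != j and matrix.cells[i, j] >= thr
        )
    return CandidateSets(names, sets)


def mutual_pairs(candidates: CandidateSets) -> CorrelationGraph:
    """Keep pair {i, j} only when each is a candidate of the other; group
    features by connected components of the resulting pair graph."""
    names = candidates.feature_names
    g = nx.Graph()
    g.add_nodes_from(names)
    for j, cand in candidates.sets.items():
        for i in cand:
            if j in candidates.sets.get(i, frozenset()):
                g.add_edge(i, j)
    pairs = frozenset(frozenset(e) for e in g.edges)
    order = {n: k for k, n in enumerate(names)}
    comps = [tuple(sorted(c, key=order.get)) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: order[c[0]])
    return CorrelationGraph(names, pairs, tuple(comps))


def build_group_mask(graph: CorrelationGraph, hidden_per_group: int = 1) -> NetworkSpec:
    """Coupled-connection mask: one hidden block per correlated group.

    A group's features connect only to that group's ``hidden_per_group``
    hidden units; all hidden units feed the single output.
    """
    if hidden_per_group < 1:
        raise ValidationError("hidden_per_group must be >= 1")
    if not graph.feature_names:
        raise ValidationError("cannot build a mask for an empty feature set")
    f = len(graph.feature_names)
    idx = {n: k for k, n in enumerate(graph.feature_names)}
    n_hidden = hidden_per_group * len(graph.groups)
    mask = np.zeros((f, n_hidden), dtype=np.int8)
    for g_num, group in enumerate(graph.groups):
        cols = slice(g_num * hidden_per_group, (g_num + 1) * hidden_per_group)
        for name in group:
            mask[idx[name], cols] = 1
    return NetworkSpec(f, n_hidden, mask)


def load_reference_matrix() -> SensitivityChangeMatrix:
    """Packaged 9-feature reference sensitivity-change matrix (printed
    3-decimal values and averages from the published CHD cohort analysis)."""
    resource = files("nnfca.data").joinpath(REFERENCE_MATRIX_RESOURCE)
    with resource.open("r") as fh:
        return SensitivityChangeMatrix.from_csv(fh)
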