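"""Single-hidden-layer perceptron with an explicit input-to-hidden
connectivity mask, trained by full-batch backpropagation.

The mask is the substrate for the coupled-connection predictor: correlated
features share a hidden-unit block, uncorrelated features are wired to
disjoint blocks.  Masked weights are hard zeros — zero at initialisation,
zero gradients during training — so the connectivity contract is exact.

Model: p(x) = sigma( w_out . sigma(W^T x + b_h) + b_out ) with logistic
sigma, trained on cross-entropy by plain gradient descent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.special import expit

from .cohort_io import CohortTable
from .exceptions import DegenerateInputError, TrainingError, ValidationError


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1.0
    epochs: int = 2000
    seed: int = 0
    init_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.init_scale <= 0:
            raise ValidationError("learning_rate and init_scale must be positive")
        if self.epochs < 0:
            raise ValidationError("epochs must be nonnegative")


@dataclass(frozen=True)
class NetworkSpec:
    """Topology plus an n_input x n_hidden binary connectivity mask."""

    n_input: int
    n_hidden: int
    mask: np.ndarray
    activation: str = "logistic"

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=np.int8)
        object.__setattr__(self, "mask", mask)
        if mask.shape != (self.n_input, self.n_hidden):
            raise ValidationError("mask shape must be (n_input, n_hidden)")
        if not np.isin(mask, (0, 1)).all():
            raise ValidationError("mask must be binary")
        if (mask.sum(axis=0) == 0).any():
            raise ValidationError("every hidden unit needs >= 1 incoming connection")
        if self.activation != "logistic":
            raise ValidationError("only the logistic activation is supported")

    @classmethod
    def dense(cls, n_input: int, n_hidden: int) -> "NetworkSpec":
        return cls(n_input, n_hidden, np.ones((n_input, n_hidden), dtype=np.int8))

    def all_inputs_reach_output(self) -> bool:
        """False when some input row is fully masked (a dead input)."""
        return bool((self.mask.sum(axis=1) > 0).all())


@dataclass
class TrainedNetwork:
    """Weights of a (possibly masked) 1-hidden-layer logistic network."""

    spec: NetworkSpec
    w_in: np.ndarray      # (n_input, n_hidden); zero wherever mask is zero
    b_hidden: np.ndarray  # (n_hidden,)
    w_out: np.ndarray     # (n_hidden,)
    b_out: float
    loss_history: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.b_hidden = np.asarray(self.b_hidden, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        if self.w_in.shape != (self.spec.n_input, self.spec.n_hidden):
            raise ValidationError("w_in shape mismatch")
        if (self.w_in[self.spec.mask == 0] != 0).any():
            raise ValidationError("masked positions must hold exactly-zero weights")

    def forward(self, x: np.ndarray | CohortTable) -> np.ndarray | float:
        """Predicted high-risk probability for one record or a matrix."""
        if isinstance(x, CohortTable):
            x = x.values
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = x[None, :] if single else x
        if X.shape[1] != self.spec.n_input:
            raise ValidationError("record length does not match n_input")
        hidden = expit(X @ self.w_in + self.b_hidden)
        out = expit(hidden @ self.w_out + self.b_out)
        return float(out[0]) if single else out

    def predict(self, x, threshold: float = 0.5) -> np.ndarray:
        return (np.asarray(self.forward(x)) >= threshold).astype(np.int8)

    # -- serialization -------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "n_input": self.spec.n_input,
            "n_hidden": self.spec.n_hidden,
            "mask": self.spec.mask.tolist(),
            "activation": self.spec.activation,
            "w_in": self.w_in.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out,
        })

    @classmethod
    def from_json(cls, text: str) -> "TrainedNetwork":
        d = json.loads(text)
        spec = NetworkSpec(d["n_input"], d["n_hidden"], np.array(d["mask"]),
                           d.get("activation", "logistic"))
        return cls(spec, np.array(d["w_in"]), np.array(d["b_hidden"]),
                   np.array(d["w_out"]), float(d["b_out"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "TrainedNetwork":
        return cls.from_json(Path(path).read_text())


def init_network(spec: NetworkSpec, config: TrainingConfig) -> TrainedNetwork:
    """Seeded uniform(+/- init_scale) weights; masked entries exactly zero.

    Rejects masks with a dead input row: a network built for training should
    let every feature reach the output.
    """
    if not spec.all_inputs_reach_output():
        raise ValidationError("mask leaves an input disconnected from the output")
    rng = np.random.default_rng(config.seed)
    s = config.init_scale
    w_in = rng.uniform(-s, s, size=(spec.n_input, spec.n_hidden)) * spec.mask
    b_hidden = rng.uniform(-s, s, size=spec.n_hidden)
    w_out = rng.uniform(-s, s, size=spec.n_hidden)
    b_out = float(rng.uniform(-s, s))
    return TrainedNetwork(spec, w_in, b_hidden, w_out, b_out)


def _as_xy(data, outcome=None):
    if isinstance(data, CohortTable):
        return data.values, data.outcome.astype(float)
    return np.asarray(data, dtype=float), np.asarray(outcome, dtype=float)


def cross_entropy(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def loss_and_gradients(net: TrainedNetwork, X: np.ndarray, y: np.ndarray):
    """Cross-entropy loss and analytic backprop gradients (mask applied).

    Exposed separately so finite-difference checks can probe the same code
    path the trainer uses.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    hidden = expit(X @ net.w_in + net.b_hidden)
    p = expit(hidden @ net.w_out + net.b_out)
    loss = cross_entropy(p, y)
    d_logit = (p - y) / n                       # d loss / d output-logit
    g_w_out = hidden.T @ d_logit
    g_b_out = float(d_logit.sum())
    d_hidden = np.outer(d_logit, net.w_out) * hidden * (1 - hidden)
    g_w_in = (X.T @ d_hidden) * net.spec.mask   # masked gradients are hard zeros
    g_b_hidden = d_hidden.sum(axis=0)
    return loss, {"w_in": g_w_in, "b_hidden": g_b_hidden,
                  "w_out": g_w_out, "b_out": g_b_out}


def train(net: TrainedNetwork, data, config: TrainingConfig,
          outcome=None) -> TrainedNetwork:
    """Full-batch gradient descent for ``config.epochs`` epochs.

    Returns a new network; the input network is untouched.  Raises
    :class:`TrainingError` naming the epoch if the loss becomes non-finite.
    """
    X, y = _as_xy(data, outcome)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("training data must contain both classes")
    w_in = net.w_in.copy()
    b_hidden = net.b_hidden.copy()
    w_out = net.w_out.copy()
    b_out = net.b_out
    current = TrainedNetwork(net.spec, w_in, b_hidden, w_out, b_out)
    losses = np.empty(config.epochs + 1)
    lr = config.learning_rate
    for epoch in range(config.epochs):
        loss, g = loss_and_gradients(current, X, y)
        if not np.isfinite(loss):
            raise TrainingError(f"loss became non-finite at epoch {epoch}", epoch=epoch)
        losses[epoch] = loss
        w_in -= lr * g["w_in"]
        b_hidden -= lr * g["b_hidden"]
        w_out -= lr * g["w_out"]
        b_out -= lr * g["b_out"]
        current = TrainedNetwork(net.spec, w_in, b_hidden, w_out, b_out)
    final_loss, _ = loss_and_gradients(current, X, y)
    losses[config.epochs] = final_loss
    current.loss_history = losses
    return current


def fit_network(data, config: TrainingConfig, spec: NetworkSpec | None = None,
                n_hidden: int = 4, outcome=None) -> TrainedNetwork:
    """Convenience: init + train a (dense by default) network on a cohort."""
    X, y = _as_xy(data, outcome)
    if spec is None:
        spec = NetworkSpec.dense(X.shape[1], n_hidden)
    return train(init_network(spec, config), X, config, outcome=y)
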