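"""Synthetic KNHANES-like cohorts with known ground truth.

Generation follows a Gaussian-copula scheme: one correlated standard-normal
latent per feature (planted pairwise correlations enter the latent
correlation matrix), transformed marginally into truncated-normal
continuous features, threshold-coded binaries, or quantile-cut ordinals.
The binary high-risk outcome is Bernoulli with

    logit = intercept + sum_i beta_i * z_i + sum_(a,b) gamma_ab * z_a * z_b

on the latent (per-SD) scale, so effects are log-odds per standard
deviation and a planted pair can carry both a marginal correlation rho and
a joint interaction gamma.  The intercept is calibrated by bisection to a
target outcome prevalence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from scipy.special import expit
from scipy.stats import norm, truncnorm

from .cohort_io import (KIND_BINARY, KIND_CONTINUOUS, KIND_ORDINAL,
                        CohortTable, FeatureSpec)
from .exceptions import ConfigurationError, ValidationError

#: high-risk prevalence of the reference CHD cohort (1115 of 4146 subjects)
REFERENCE_PREVALENCE = 1115 / 4146

#: reference cohort size after exclusions
REFERENCE_N = 4146


@dataclass(frozen=True)
class ContinuousSpec:
    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValidationError("sd must be positive")
        if not self.low < self.high:
            raise ValidationError("low must be < high")


@dataclass(frozen=True)
class CorrelatedPair:
    feature_a: str
    feature_b: str
    rho: float
    interaction: float = 0.0

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValidationError("|rho| must be < 1")


@dataclass
class SimulationConfig:
    n_records: int
    feature_order: tuple[str, ...]
    continuous: dict[str, ContinuousSpec] = field(default_factory=dict)
    binary: dict[str, float] = field(default_factory=dict)           # prevalence
    ordinal: dict[str, tuple[float, ...]] = field(default_factory=dict)  # level probs
    effects: dict[str, float] = field(default_factory=dict)          # log-odds per SD
    correlated_pairs: tuple[CorrelatedPair, ...] = ()
    intercept: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 50:
            raise ValidationError("n_records must be >= 50")
        declared = set(self.continuous) | set(self.binary) | set(self.ordinal)
        if declared != set(self.feature_order):
            raise ValidationError("feature_order must cover exactly the declared features")
        for name, p in self.binary.items():
            if not 0 < p < 1:
                raise ValidationError(f"{name}: prevalence must be in (0, 1)")
        for name, probs in self.ordinal.items():
            if len(probs) < 2 or any(p <= 0 for p in probs) or abs(sum(probs) - 1) > 1e-9:
                raise ValidationError(f"{name}: ordinal probs must be positive and sum to 1")
        for name in self.effects:
            if name not in declared:
                raise ValidationError(f"effect on unknown feature {name!r}")
        for pair in self.correlated_pairs:
            if pair.feature_a not in declared or pair.feature_b not in declared:
                raise ValidationError("correlated pair references unknown feature")

    # -- serialization -------------------------------------------------------
    def to_json(self) -> str:
        d = asdict(self)
        d["feature_order"] = list(self.feature_order)
        d["continuous"] = {k: asdict(v) for k, v in self.continuous.items()}
        d["ordinal"] = {k: list(v) for k, v in self.ordinal.items()}
        d["correlated_pairs"] = [asdict(p) for p in self.correlated_pairs]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        return cls(
            n_records=d["n_records"],
            feature_order=tuple(d["feature_order"]),
            continuous={k: ContinuousSpec(**v) for k, v in d["continuous"].items()},
            binary=d["binary"],
            ordinal={k: tuple(v) for k, v in d["ordinal"].items()},
            effects=d["effects"],
            correlated_pairs=tuple(CorrelatedPair(**p) for p in d["correlated_pairs"]),
            intercept=d["intercept"],
            seed=d["seed"],
        )


def latent_correlation(config: SimulationConfig) -> np.ndarray:
    f = len(config.feature_order)
    idx = {n: i for i, n in enumerate(config.feature_order)}
    corr = np.eye(f)
    for pair in config.correlated_pairs:
        a, b = idx[pair.feature_a], idx[pair.feature_b]
        corr[a, b] = corr[b, a] = pair.rho
    return corr


def _draw_latents(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    corr = latent_correlation(config)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("correlation structure is not positive definite") from exc
    return rng.standard_normal((n, corr.shape[0])) @ chol.T


def _logit(config: SimulationConfig, z: np.ndarray) -> np.ndarray:
    idx = {n: i for i, n in enumerate(config.feature_order)}
    logit = np.full(z.shape[0], config.intercept)
    for name, beta in config.effects.items():
        if beta:
            logit += beta * z[:, idx[name]]
    for pair in config.correlated_pairs:
        if pair.interaction:
            logit += pair.interaction * z[:, idx[pair.feature_a]] * z[:, idx[pair.feature_b]]
    return logit


def _marginal(config: SimulationConfig, name: str, z: np.ndarray) -> tuple[np.ndarray, FeatureSpec]:
    if name in config.continuous:
        c = config.continuous[name]
        a = (c.low - c.mean) / c.sd
        b = (c.high - c.mean) / c.sd
        x = truncnorm.ppf(np.clip(norm.cdf(z), 1e-12, 1 - 1e-12), a, b,
                          loc=c.mean, scale=c.sd)
        spec = FeatureSpec(name, KIND_CONTINUOUS, valid_range=(c.low, c.high))
        return x, spec
    if name in config.binary:
        p = config.binary[name]
        x = (z > norm.ppf(1 - p)).astype(float)
        return x, FeatureSpec(name, KIND_BINARY, levels=("no", "yes"))
    probs = config.ordinal[name]
    cuts = norm.ppf(np.cumsum(probs)[:-1])
    x = np.searchsorted(cuts, z).astype(float)
    levels = tuple(f"level_{k}" for k in range(len(probs)))
    if name == "diabetes" and len(probs) == 3:
        levels = ("no", "impaired_fasting_glucose", "diabetes")
    return x, FeatureSpec(name, KIND_ORDINAL, levels=levels)


def simulate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[CohortTable, dict]:
    """Draw a cohort and its ground-truth sidecar.

    The sidecar records the planted informative features (nonzero main
    effects), planted pairs, intercept and realised prevalence, so recovery
    tests never need to re-derive the truth.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    z = _draw_latents(config, config.n_records, rng)
    cols, specs = [], []
    for i, name in enumerate(config.feature_order):
        x, spec = _marginal(config, name, z[:, i])
        cols.append(x)
        specs.append(spec)
    values = np.column_stack(cols)
    outcome = (rng.random(config.n_records) < expit(_logit(config, z))).astype(np.int8)
    ids = np.array([f"r{k:06d}" for k in range(config.n_records)])
    table = CohortTable(tuple(specs), values, outcome, ids)
    truth = {
        "informative_features": sorted(n for n, b in config.effects.items() if b != 0),
        "planted_pairs": [
            {"pair": sorted((p.feature_a, p.feature_b)), "rho": p.rho,
             "interaction": p.interaction}
            for p in config.correlated_pairs
        ],
        "intercept": config.intercept,
        "prevalence": float(outcome.mean()),
    }
    return table, truth


def calibrate_intercept(
    config: SimulationConfig,
    target_prevalence: float,
    tol: float = 0.01,
    n_probe: int = 20000,
    seed: int = 12345,
) -> float:
    """Bisection on the intercept until the expected outcome prevalence on a
    probe latent sample is within ``tol`` of the target."""
    if not 0 < target_prevalence < 1:
        raise ValidationError("target prevalence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    z = _draw_latents(config, n_probe, rng)
    base = _logit(replace(config, intercept=0.0), z)

    def prevalence(c: float) -> float:
        return float(expit(base + c).mean())

    lo, hi = -20.0, 20.0
    for _ in range(200):
        mid = (lo + hi) / 2
        p = prevalence(mid)
        if abs(p - target_prevalence) <= tol / 2:
            return mid
        if p < target_prevalence:
            lo = mid
        else:
            hi = mid
    raise ConfigurationError("intercept calibration did not converge")


def default_knhanes_like_config(
    n_records: int = REFERENCE_N, seed: int = 20170906
) -> SimulationConfig:
    """Nine-feature cohort at the reference marginal scales.

    Main effects on age, SBP and diabetes; a planted SBP-DBP pair with
    rho = 0.7 and a joint log-odds interaction of 0.5 (the correlation
    analysis targets features that contribute jointly to the outcome);
    intercept calibrated to the reference high-risk prevalence (~0.269).
    """
    config = SimulationConfig(
        n_records=n_records,
        feature_order=("age", "BMI", "To_chole", "HDL", "SBP", "DBP",
                       "triglyceride", "smoking", "diabetes"),
        continuous={
            "age": ContinuousSpec(52.5, 13.0, 30.0, 92.0),
            "BMI": ContinuousSpec(23.97, 3.2, 15.3, 41.3),
            "To_chole": ContinuousSpec(190.97, 36.0, 79.0, 525.0),
            "HDL": ContinuousSpec(51.84, 12.0, 22.0, 118.0),
            "SBP": ContinuousSpec(118.98, 16.0, 75.0, 219.0),
            "DBP": ContinuousSpec(75.82, 10.0, 10.0, 137.0),
            "triglyceride": ContinuousSpec(139.24, 90.0, 20.0, 1868.0),
        },
        binary={"smoking": 824 / 4146},
        ordinal={"diabetes": (2625 / 4146, 994 / 4146, 527 / 4146)},
        effects={"age": 0.8, "SBP": 1.0, "diabetes": 0.7},
        correlated_pairs=(CorrelatedPair("SBP", "DBP", 0.7, 0.5),),
        intercept=0.0,
        seed=seed,
    )
    intercept = calibrate_intercept(config, REFERENCE_PREVALENCE)
    return replace(config, intercept=intercept)


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2))
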