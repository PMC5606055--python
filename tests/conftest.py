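import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nnfca

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_table():
    """Six records, one informative continuous feature, one binary."""
    specs = (
        nnfca.FeatureSpec("age", "continuous", valid_range=(30.0, 92.0)),
        nnfca.FeatureSpec("smoking", "binary", levels=("no", "yes")),
    )
    values = np.array([
        [0.0, 0.0], [0.1, 1.0], [0.2, 0.0],
        [0.8, 1.0], [0.9, 0.0], [1.0, 1.0],
    ])
    outcome = np.array([0, 0, 0, 1, 1, 1])
    ids = np.array([f"r{i}" for i in range(6)])
    return nnfca.CohortTable(specs, values, outcome, ids)


@pytest.fixture
def hand_net_111():
    """1-input, 1-hidden network with unit weight, zero biases."""
    spec = nnfca.NetworkSpec(1, 1, np.ones((1, 1)))
    return nnfca.TrainedNetwork(spec, np.array([[1.0]]), np.zeros(1),
                                np.array([1.0]), 0.0)


def toy_signal_noise_config(seed, n_records=600):
    """Two informative + three pure-noise continuous features."""
    names = ("f_signal_a", "f_signal_b", "f_noise_1", "f_noise_2", "f_noise_3")
    return nnfca.SimulationConfig(
        n_records=n_records,
        feature_order=names,
        continuous={n: nnfca.ContinuousSpec(0.0, 1.0, -4.0, 4.0) for n in names},
        effects={"f_signal_a": 1.5, "f_signal_b": 1.2},
        intercept=0.0,
        seed=seed,
    )
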