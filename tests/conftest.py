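import numpy as np
import pytest

import tpslearn as t


@pytest.fixture(scope="session")
def double_well():
    return t.QuarticDoubleWell(h=4.0, x0=1.0)


@pytest.fixture(scope="session")
def dw_states():
    return [t.half_line_state("A", -0.8, "le"), t.half_line_state("B", 0.8, "ge")]


@pytest.fixture(scope="session")
def overdamped():
    return t.EngineParams(kind="overdamped", timestep=0.005, friction=1.0,
                          kT=1.0, max_steps=200_000)


@pytest.fixture(scope="session")
def analytic_oracle(double_well):
    return t.AnalyticCommittor1D(double_well, kT=1.0, a=-0.8, b=0.8)


@pytest.fixture(scope="session")
def logistic_data():
    """Planted logistic shooting data: p_B = sigmoid(4x - 2), n = 5000."""
    from tpslearn.datasets import logistic_records

    X, s, manifest = logistic_records(5000, np.array([4.0]), -2.0, rng=42)
    return X, s, manifest


@pytest.fixture(scope="session")
def trained_toy_model(logistic_data):
    """Small pyramid net fitted to the planted logistic data."""
    X, s, _ = logistic_data
    model = t.NeuralCommittor(1, t.build_pyramid(8, 2, 4, 0.0), seed=1)
    model.fit(X, s, epochs=300, learning_rate=3e-3, seed=1)
    return model
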