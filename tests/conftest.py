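import numpy as np
import pytest

from gmaic import IPDTrial, ScenarioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_trial():
    """Four participants, one binary covariate."""
    return IPDTrial(
        y=np.array([0, 1, 0, 1]),
        t=np.array([0, 0, 1, 1]),
        X=np.array([[0.0], [0.0], [1.0], [1.0]]),
        covariate_names=["x1"],
    )


@pytest.fixture
def normal_high_config():
    return ScenarioConfig(n_ipd=600, overlap="high", structure="normal")


def make_two_by_two_trial(events_active, n_active, events_comp, n_comp, x_value=0.5):
    """IPD trial realizing a given 2x2 outcome table, constant covariate."""
    y = np.concatenate(
        [
            np.ones(events_active),
            np.zeros(n_active - events_active),
            np.ones(events_comp),
            np.zeros(n_comp - events_comp),
        ]
    ).astype(int)
    t = np.concatenate([np.ones(n_active), np.zeros(n_comp)]).astype(int)
    X = np.full((n_active + n_comp, 1), x_value)
    return IPDTrial(y=y, t=t, X=X, covariate_names=["x1"])
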