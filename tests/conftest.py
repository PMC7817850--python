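import sys
from pathlib import Path

import numpy as np
import pytest

from actinf import GenerativeModel, enumerate_policies, make_random_model

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def identity_2x2_model():
    """2-state model with identity likelihood and uniform prior."""
    return GenerativeModel(
        A=np.eye(2),
        B=np.stack([np.eye(2), np.array([[0.0, 1.0], [1.0, 0.0]])]),
        D=np.array([0.5, 0.5]),
        lnC=np.log(np.array([[0.5, 0.5], [0.5, 0.5]])),
        policies=enumerate_policies(2, 2),
        horizon=2,
    )


@pytest.fixture
def random_model_factory():
    def make(seed, n_states=3, n_outcomes=3, n_actions=2, horizon=2, **kw):
        return make_random_model(n_states, n_outcomes, n_actions, horizon,
                                 seed=seed, **kw)
    return make


def random_belief(rng, n):
    return rng.dirichlet(np.ones(n))
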