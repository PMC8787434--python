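import numpy as np
import pytest

from h12msm import (
    MarkovStateModel,
    make_metastable_chain,
    sample_discrete_chain,
)
from h12msm.msm import TransitionModel


@pytest.fixture(scope="session")
def planted_chain():
    """The 5-macrostate, 50-microstate metastable reference chain."""
    return make_metastable_chain(
        n_macro=5, micro_per_macro=10, intra_p=0.2, inter_p=0.002, seed=1
    )


@pytest.fixture(scope="session")
def planted_dtrajs(planted_chain):
    """A moderate sample from the reference chain for estimator tests."""
    return sample_discrete_chain(planted_chain, n_trajs=20, n_steps=5000, seed=3)


@pytest.fixture(scope="session")
def planted_model(planted_dtrajs):
    return MarkovStateModel(lag=1).fit(planted_dtrajs)


@pytest.fixture
def three_state_model():
    """The hand-solvable 3-state birth-death chain (q+ = (0, 0.5, 1))."""
    T = np.array([[0.8, 0.2, 0.0], [0.1, 0.8, 0.1], [0.0, 0.2, 0.8]])
    pi = np.array([0.25, 0.5, 0.25])
    return TransitionModel(transition_matrix=T, stationary=pi, reversible=True)


def random_reversible_model(n: int, rng: np.random.Generator) -> TransitionModel:
    """Random reversible chain from a symmetric positive weight matrix."""
    W = rng.random((n, n)) + 0.05
    W = 0.5 * (W + W.T)
    T = W / W.sum(axis=1, keepdims=True)
    pi = W.sum(axis=1) / W.sum()
    return TransitionModel(transition_matrix=T, stationary=pi, reversible=True)
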