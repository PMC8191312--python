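import numpy as np
import pytest

from bridgemsm.msm import CountMatrix, estimate_markov_model


def model_from_T(T: np.ndarray, frame_interval: float = 1.0):
    """A MarkovModel whose transition matrix is exactly the given T.

    Builds (real-valued) counts proportional to pi_i T_ij; for a
    reversible T the reversible estimator reproduces T to machine
    precision.
    """
    T = np.asarray(T, dtype=float)
    evals, evecs = np.linalg.eig(T.T)
    pi = np.abs(np.real(evecs[:, np.argmax(np.real(evals))]))
    pi = pi / pi.sum()
    counts = pi[:, None] * T * 1e6
    cm = CountMatrix(counts, 1, np.arange(len(T)), len(T))
    return estimate_markov_model(cm, frame_interval, reversible=True)


@pytest.fixture
def two_state_T():
    return np.array([[0.9, 0.1], [0.2, 0.8]])


@pytest.fixture
def two_state_model(two_state_T):
    return model_from_T(two_state_T)


def random_reversible_T(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random reversible row-stochastic matrix from a symmetric weight matrix."""
    S = rng.random((n, n)) + n * np.eye(n)  # diagonally dominant -> metastable-ish
    S = 0.5 * (S + S.T)
    return S / S.sum(axis=1)[:, None]
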