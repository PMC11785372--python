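import numpy as np
import pytest

from hmmkernels.hmm import HMMParams, sample_hmm


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_hmm():
    """K=2, M=2 HMM with well-separated states."""
    pi = np.array([0.6, 0.4])
    A = np.array([[0.9, 0.1], [0.2, 0.8]])
    mu = np.array([[0.0, 0.0], [3.0, -3.0]])
    sigma = np.stack([np.eye(2), np.array([[1.0, 0.3], [0.3, 1.5]])])
    return HMMParams(pi, A, mu, sigma)


@pytest.fixture
def small_hmm_3d():
    """K=2, M=3 HMM used for gradient checks."""
    rng = np.random.default_rng(7)
    mu = rng.standard_normal((2, 3))
    sigma = np.empty((2, 3, 3))
    for k in range(2):
        W = rng.standard_normal((3, 8))
        S = W @ W.T / 8 + 0.5 * np.eye(3)
        sigma[k] = S
    pi = np.array([0.55, 0.45])
    A = np.array([[0.85, 0.15], [0.25, 0.75]])
    return HMMParams(pi, A, mu, sigma)


@pytest.fixture
def sampled_series(tiny_hmm):
    """Five subjects sampled from the tiny HMM."""
    return [sample_hmm(tiny_hmm, 300, rng=seed)[0] for seed in range(5)]
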