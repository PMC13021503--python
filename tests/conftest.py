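import numpy as np
import pytest

from twinmorph.likelihood import pair_sigma
from twinmorph.pairs import PairData


def exact_moment_pairs(A, C, E, n_mz=200, n_dz=200, seed=0, mean=0.0):
    """Pair data whose per-group sample moments (MLE denominator) equal the
    implied twin-model moments exactly; at such data the ML optimum sits at
    the generating parameters."""
    A, C, E = (np.atleast_2d(np.asarray(m, float)) for m in (A, C, E))
    k2 = 2 * A.shape[0]
    rng = np.random.default_rng(seed)
    groups = {}
    for z, n in (("MZ", n_mz), ("DZ", n_dz)):
        sigma = pair_sigma(A, C, E, z)
        X = rng.standard_normal((n, k2))
        X -= X.mean(axis=0)
        S = (X.T @ X) / n
        W = np.linalg.cholesky(S)
        L = np.linalg.cholesky(sigma + 1e-12 * np.eye(k2))
        groups[z] = X @ np.linalg.inv(W).T @ L.T + mean
    traits = tuple(f"t{i}" for i in range(A.shape[0]))
    return PairData(traits, groups)


def simulated_pairs(A, C, E, n_mz, n_dz, seed=0):
    """Plain multivariate-normal pair draws from the implied structure."""
    A, C, E = (np.atleast_2d(np.asarray(m, float)) for m in (A, C, E))
    k2 = 2 * A.shape[0]
    rng = np.random.default_rng(seed)
    groups = {
        z: rng.multivariate_normal(np.zeros(k2), pair_sigma(A, C, E, z), size=n)
        for z, n in (("MZ", n_mz), ("DZ", n_dz))
    }
    return PairData(tuple(f"t{i}" for i in range(A.shape[0])), groups)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
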