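import numpy as np
import pytest

from phyloxylem import Phylogeny
from phyloxylem.simulate import SimConfig, simulate_dataset, simulate_tree


@pytest.fixture
def three_taxon_tree():
    """((A:1,B:1):1,C:2); — the hand-checkable worked example."""
    return Phylogeny.from_string("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def yule150():
    """A 150-tip ultrametric Yule tree of depth 100 My, shared across tests."""
    return simulate_tree(SimConfig(n_tips=150, seed=42))


@pytest.fixture(scope="session")
def cov150(yule150):
    return yule150.vcv(yule150.tip_labels)


@pytest.fixture(scope="session")
def dataset200():
    """Default-condition synthetic dataset (200 species), shared read-only."""
    return simulate_dataset(SimConfig(n_tips=200, seed=7))


def brownian_traits(C, lam, sigma2, rng, size=1):
    """Independent oracle generator: MVN draws with covariance
    sigma2 * (lam * C_offdiag + C_diag), via Cholesky."""
    m = C.matrix if hasattr(C, "matrix") else np.asarray(C)
    V = lam * m + (1 - lam) * np.diag(np.diag(m))
    L = np.linalg.cholesky(sigma2 * V + 1e-12 * np.eye(len(m)))
    return L @ rng.standard_normal((len(m), size))
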