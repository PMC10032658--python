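import numpy as np
import pytest

from coevoscan import synthdata
from coevoscan.tree import Phylogeny


@pytest.fixture
def three_taxon_tree() -> Phylogeny:
    """((A:1,B:1):1,C:2); -- depths 2 everywhere, MRCA(A,B) at depth 1."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def yule30() -> Phylogeny:
    return synthdata.simulate_tree(30, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def star_tree(n: int, length: float = 1.0) -> Phylogeny:
    """All tips attached to the root with equal branch lengths."""
    parent = np.array([-1] + [0] * n)
    lengths = np.array([0.0] + [length] * n)
    labels = [None] + [f"s{i}" for i in range(n)]
    return Phylogeny(parent=parent, lengths=lengths, labels=labels)


def simulate_brownian_tips(tree: Phylogeny, cov_chol, rng) -> np.ndarray:
    """One Brownian realisation over the tips given a Cholesky factor of the
    Brownian covariance (independent oracle for the tree-walk simulators)."""
    return cov_chol @ rng.standard_normal(cov_chol.shape[0])
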