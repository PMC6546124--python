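import numpy as np
import pytest

from bdfam.family_events import load_drosophila_tree, load_far_fixture
from bdfam.treestats import parse_newick


def random_newick(rng: np.random.Generator, n_tips: int, prefix: str = "T") -> str:
    """A random rooted binary tree with uniform(0.1, 2) branch lengths."""
    labels = [f"{prefix}{i}" for i in range(n_tips)]
    labels = [labels[i] for i in rng.permutation(n_tips)]

    def build(lbls):
        if len(lbls) == 1:
            return lbls[0]
        k = int(rng.integers(1, len(lbls)))
        return (
            f"({build(lbls[:k])}:{rng.uniform(0.1, 2.0):.4f},"
            f"{build(lbls[k:])}:{rng.uniform(0.1, 2.0):.4f})"
        )

    return build(labels) + ";"


def random_tree(rng, n_tips, prefix="T"):
    return parse_newick(random_newick(rng, n_tips, prefix))


@pytest.fixture(scope="session")
def far_fixture():
    return load_far_fixture()


@pytest.fixture(scope="session")
def drosophila_tree():
    return load_drosophila_tree()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240711)
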