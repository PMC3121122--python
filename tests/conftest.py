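import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from hiersvm import build_tree_from_labels, glass_tree


@pytest.fixture
def glass():
    """Two-family / three-leaf tree: leaves 1='1.1', 2='2.1', 3='2.2',
    internal 4='1', 5='2'."""
    return glass_tree()


@pytest.fixture
def ec1_labels():
    """The eight oxidoreductase sub-subfamily labels (two share subfamily 1.6)."""
    return ["1.1.1", "1.2.1", "1.3.1", "1.5.1", "1.6.5", "1.6.99", "1.9.3", "1.11.1"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_instance(rng, max_l=30, max_q=4):
    """A random small training instance over a random small label tree."""
    shapes = [
        ["1.1", "2.1"],
        ["1.1", "1.2", "2.1"],
        ["1.1", "1.2", "2.1", "2.2"],
        ["1.1.1", "1.1.2", "1.2.1"],
    ]
    labels = shapes[rng.integers(len(shapes))][: max_q]
    tree = build_tree_from_labels(labels)
    l = int(rng.integers(5, max_l + 1))
    d = int(rng.integers(2, 6))
    X = rng.normal(size=(l, d))
    y = list(rng.choice(tree.leaf_names, size=l))
    while len(set(y)) < 2:
        y = list(rng.choice(tree.leaf_names, size=l))
    C = float(rng.choice([0.1, 1.0, 10.0]))
    return tree, X, y, C
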