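import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cladeshift.simulate import simulate_yule
from cladeshift.tree import parse_newick


@pytest.fixture
def three_taxon_tree():
    """The worked 3-taxon example tree."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def three_taxon_values():
    return pd.Series({"A": 1.0, "B": 3.0, "C": 5.0}, name="x")


@pytest.fixture
def quartet_tree():
    return parse_newick("((A:1,B:1)x:1,(C:1,D:1)y:1)r;")


def random_yule_trees(n_trees, n_range, seed):
    """Seeded list of random Yule trees with tip counts drawn from n_range."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_trees):
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        out.append(simulate_yule(n, seed=int(rng.integers(2**31 - 1))))
    return out


@pytest.fixture(scope="session")
def small_trees():
    """30 random trees with 4-6 tips for enumeration-oracle comparisons."""
    return random_yule_trees(30, (4, 6), seed=1234)
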