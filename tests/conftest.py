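import numpy as np
import pytest

from paralogon.model import SpeciesTree
from paralogon.simulate import emit_fixture_matrix


@pytest.fixture
def fixture_matrix():
    """The 11-gene rhodopsin-region worked-example matrix."""
    return emit_fixture_matrix()


@pytest.fixture
def three_lineage_tree():
    """Eel + arowana sister lineages with gar as outgroup."""
    return SpeciesTree.from_newick("((eel,arowana)teleost,gar)root;")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_rooted_newick(rng, n_tips: int) -> str:
    """Random rooted binary tree over t1..tn by sequential joining; the root
    node is labelled 'root'."""
    nodes = [f"t{i+1}" for i in range(n_tips)]
    k = 0
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})n{k}")
        k += 1
    if len(nodes) == 2:
        return f"({nodes[0]},{nodes[1]})root;"
    return f"({nodes[0]})root;"
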