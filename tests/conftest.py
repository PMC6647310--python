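import numpy as np
import pytest

from tbekit import (
    PhyloTree,
    balanced_tree,
    caterpillar_tree,
    pda_tree,
    yule_tree,
)


def make_model_tree(model: str, n: int, rng) -> PhyloTree:
    if model == "caterpillar":
        return caterpillar_tree(n)
    if model == "balanced":
        h = n.bit_length() - 1
        assert 2 ** h == n, "balanced needs n = 2**h"
        return balanced_tree(h)
    if model == "pda":
        return pda_tree(n, rng)
    if model == "yule":
        return yule_tree(n, rng)
    raise ValueError(model)


ALL_MODELS = ("caterpillar", "balanced", "pda", "yule")


def reroot_on_edge(tree: PhyloTree, edge_index: int) -> PhyloTree:
    """Copy of the tree with a degree-2 root subdividing the chosen edge."""
    adj = {u: list(vs) for u, vs in tree._adj.items()}
    child, parent, _ = tree.clade_masks()[edge_index % len(tree.clade_masks())]
    root = max(adj) + 1
    adj[child].remove(parent)
    adj[parent].remove(child)
    adj[root] = [child, parent]
    adj[child].append(root)
    adj[parent].append(root)
    return PhyloTree(adj, tree._leaf_labels, rooted=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
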