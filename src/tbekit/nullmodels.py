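"""Null tree models and random reference bipartitions.

Four topology models for "signal-free" trees on ``n`` labelled tips:

* caterpillar — the unique maximally imbalanced shape, internal vertices
  forming a path; tips labelled 1..n along the path with cherries
  {1, 2} and {n-1, n};
* fully balanced — rooted complete binary tree with ``n = 2**h`` tips,
  all at depth ``h``;
* PDA (proportional to distinguishable arrangements) — the uniform
  distribution over the ``(2n - 5)!!`` unrooted binary labelled
  topologies, realised by sequential uniform edge attachment;
* Yule--Harding — growth by uniform splitting of pendant lineages,
  with uniformly random tip labelling.

Reference bipartitions are drawn as uniform ``p``-subsets of the taxa
(black = light side).  All randomness flows through an explicit
:class:`numpy.random.Generator` (PCG64); equal seeds give byte-identical
output.
"""

from __future__ import annotations

import numpy as np

from .treeio import Bicoloration, PhyloTree

__all__ = [
    "ensure_rng",
    "caterpillar_tree",
    "balanced_tree",
    "pda_tree",
    "yule_tree",
    "random_bicoloration",
]

RNG_ALGORITHM = "numpy.random.Generator(PCG64)"


def ensure_rng(seed) -> np.random.Generator:
    """Coerce an int seed (or pass through a Generator) to a PCG64 RNG."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _labels(n: int) -> list[str]:
    return [str(i) for i in range(1, n + 1)]


def caterpillar_tree(n: int) -> PhyloTree:
    """Caterpillar on tips 1..n ordered along the internal path."""
    if n < 4:
        raise ValueError("need n >= 4")
    # leaves 0..n-1 labelled "1".."n"; internal path vertices n..2n-3
    adjacency: dict[int, list[int]] = {i: [] for i in range(2 * n - 2)}

    def link(u: int, v: int) -> None:
        adjacency[u].append(v)
        adjacency[v].append(u)

    internals = list(range(n, 2 * n - 2))  # n - 2 of them, in path order
    link(0, internals[0])
    link(1, internals[0])
    for k in range(1, n - 2):
        link(internals[k - 1], internals[k])
        if k < n - 3:
            link(k + 1, internals[k])  # leaf labelled k + 2
    link(n - 2, internals[-1])
    link(n - 1, internals[-1])
    labels = {i: str(i + 1) for i in range(n)}
    return PhyloTree(adjacency, labels, rooted=False)


def balanced_tree(h: int) -> PhyloTree:
    """Rooted complete binary tree of depth ``h`` with ``2**h`` tips."""
    if h < 2:
        raise ValueError("need h >= 2")
    n = 2 ** h
    adjacency: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    next_id = [0]

    def new_node() -> int:
        v = next_id[0]
        next_id[0] += 1
        adjacency[v] = []
        return v

    def build(depth: int) -> int:
        v = new_node()
        if depth == h:
            labels[v] = str(len(labels) + 1)
            return v
        for _ in range(2):
            c = build(depth + 1)
            adjacency[v].append(c)
            adjacency[c].append(v)
        return v

    build(0)
    return PhyloTree(adjacency, labels, rooted=True)


def pda_tree(n: int, rng) -> PhyloTree:
    """Uniform unrooted binary labelled topology on ``n`` tips.

    Tip ``k + 1`` attaches to an edge chosen uniformly among the
    ``2k - 3`` edges of the current tree, which makes every topology in
    the PDA ensemble equally likely.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    rng = ensure_rng(rng)
    # leaves 0..n-1 labelled "1".."n"; first internal vertex is n
    adjacency: dict[int, list[int]] = {0: [n], 1: [n], 2: [n], n: [0, 1, 2]}
    edges: list[tuple[int, int]] = [(0, n), (1, n), (2, n)]
    next_internal = n + 1
    for k in range(3, n):
        i = int(rng.integers(len(edges)))
        u, v = edges[i]
        w = next_internal
        next_internal += 1
        adjacency[u].remove(v)
        adjacency[v].remove(u)
        adjacency[w] = [u, v, k]
        adjacency[u].append(w)
        adjacency[v].append(w)
        adjacency[k] = [w]
        edges[i] = (u, w)
        edges.append((w, v))
        edges.append((w, k))
    labels = {i: str(i + 1) for i in range(n)}
    return PhyloTree(adjacency, labels, rooted=False)


def yule_tree(n: int, rng) -> PhyloTree:
    """Yule--Harding tree: start from a cherry, repeatedly split a
    uniformly chosen pendant lineage, then label tips by a uniform
    random permutation.  Returned rooted; rooting never affects the
    transfer index."""
    if n < 4:
        raise ValueError("need n >= 4")
    rng = ensure_rng(rng)
    adjacency: dict[int, list[int]] = {0: [1, 2], 1: [0], 2: [0]}
    pendant = [1, 2]
    next_id = 3
    while len(pendant) < n:
        i = int(rng.integers(len(pendant)))
        v = pendant[i]
        c1, c2 = next_id, next_id + 1
        next_id += 2
        adjacency[v].extend([c1, c2])
        adjacency[c1] = [v]
        adjacency[c2] = [v]
        pendant[i] = c1
        pendant.append(c2)
    perm = rng.permutation(n)
    labels = {leaf: str(perm[i] + 1) for i, leaf in enumerate(pendant)}
    return PhyloTree(adjacency, labels, rooted=True)


def random_bicoloration(n: int, p: int, rng) -> Bicoloration:
    """Uniform reference bipartition: a ``p``-subset of taxa painted
    black, sampled without replacement."""
    if not 2 <= p <= n // 2:
        raise ValueError("need 2 <= p <= n/2")
    rng = ensure_rng(rng)
    chosen = rng.choice(n, size=p, replace=False)
    labels = _labels(n)
    return Bicoloration.from_black_labels(labels, [labels[i] for i in chosen])
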