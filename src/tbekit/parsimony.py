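"""Parsimony score of a binary character and its relation to the
transfer index.

The parsimony score of a tip bicoloration is the minimum, over all
extensions of the colouring to internal vertices, of the number of
bichromatic edges.  It lower-bounds the transfer index via
``ps <= phi + 1``: moving the minimising branch's mismatched taxa across
it and adding one change on the branch itself is a valid extension.
That inequality in turn yields a distribution-free lower bound on
``P(phi = p - 1)`` for a uniform bicoloration of any fixed binary tree:
when black tips are pairwise farther than four edges apart the score is
exactly ``p``, which happens with probability at least
``1 - 4 p (p-1) / (n-1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .transfer import transfer_index
from .treeio import Bicoloration, PhyloTree, TreeValidationError

__all__ = ["ParsimonyResult", "fitch_score", "parsimony_bound_holds", "cap_probability_bound"]

BLACK = True
WHITE = False


@dataclass(frozen=True)
class ParsimonyResult:
    """Minimum number of colour changes and one optimal extension.

    ``extension`` maps every node id (leaves included) to True for black.
    """

    score: int
    extension: dict[int, bool]


def fitch_score(chi: Bicoloration, tree: PhyloTree) -> ParsimonyResult:
    """Exact parsimony score of a two-state character on a binary tree.

    Implemented as the Fitch--Hartigan two-pass scheme rooted at an
    arbitrary internal vertex; the score counts bichromatic edges and is
    invariant to the rooting device.  Non-binary trees are rejected.
    """
    tree.require_binary()
    if chi.taxa != tree.taxa:
        raise TreeValidationError("bicoloration and tree taxa differ")

    leaf_labels = tree._leaf_labels
    idx = tree.taxon_index
    black = chi.black_mask
    children = tree.postorder_children()
    order = tree.postorder()

    # bottom-up: optimal state sets, as 2-bit masks (1 = white, 2 = black)
    sets: dict[int, int] = {}
    score = 0
    for v, _ in order:
        if v in leaf_labels:
            sets[v] = 2 if (black >> idx[leaf_labels[v]]) & 1 else 1
            continue
        ch = children[v]
        votes_w = sum(1 for w in ch if sets[w] & 1)
        votes_b = sum(1 for w in ch if sets[w] & 2)
        top = max(votes_w, votes_b)
        s = 0
        if votes_w == top:
            s |= 1
        if votes_b == top:
            s |= 2
        sets[v] = s
        score += len(ch) - top

    # top-down: pick parent's colour when allowed, black on free ties
    extension: dict[int, bool] = {}
    for v, parent in reversed(order):
        s = sets[v]
        if parent == -1:
            extension[v] = bool(s & 2)
        else:
            pcol = extension[parent]
            want = 2 if pcol else 1
            extension[v] = pcol if s & want else bool(s & 2)
    return ParsimonyResult(score=score, extension=extension)


def parsimony_bound_holds(chi: Bicoloration, tree: PhyloTree) -> bool:
    """True iff the parsimony score is at most the transfer index plus one."""
    ps = fitch_score(chi, tree).score
    phi = transfer_index(chi, tree).phi
    return ps <= phi + 1


def cap_probability_bound(n: int, p: int) -> float:
    """Lower bound on ``P(phi = p - 1)`` for a uniform bicoloration with
    ``p`` black tips on any fixed binary tree with ``n`` tips:
    ``max(0, 1 - 4 n p (p-1) / (n (n-1)))``.  Clamped at zero where
    vacuous; tends to 1 for fixed ``p`` as ``n`` grows."""
    if not 2 <= p <= n // 2:
        raise ValueError("need 2 <= p <= n/2")
    return max(0.0, 1.0 - 4.0 * p * (p - 1) / (n - 1))
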