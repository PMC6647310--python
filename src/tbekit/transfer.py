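"""Transfer distance, transfer index, transfer support, and TBE.

The transfer distance between a reference bipartition (encoded as a
bicoloration with ``p`` black taxa on its light side) and a branch ``b``
is the minimum Hamming distance between the 0/1 encodings over the two
orientations of ``b``.  Equivalently, with ``B_s``/``W_s`` the black and
white tip counts on side ``s`` of the branch,

    delta = min(W_l + B_h, W_h + B_l),

i.e. the number of taxa that must cross the branch to recreate the
reference split.  The transfer index ``phi`` minimises delta over every
branch of a tree (pendant branches included — a pendant branch at a
black tip caps ``phi`` at ``p - 1``), and the transfer support is
``TS = 1 - phi/(p - 1)``.  TBE averages TS over a set of bootstrap
trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .treeio import (
    Bicoloration,
    Bipartition,
    PhyloTree,
    TreeValidationError,
    bicoloration_from_branch,
)

__all__ = [
    "SideCounts",
    "TransferResult",
    "hamming",
    "transfer_distance",
    "transfer_index",
    "transfer_index_naive",
    "transfer_index_batch",
    "transfer_support",
    "tbe",
]


@dataclass(frozen=True)
class SideCounts:
    """Black/white tip counts on the light and heavy sides of a branch."""

    B_l: int
    W_l: int
    B_h: int
    W_h: int

    @property
    def q_l(self) -> int:
        return self.B_l + self.W_l

    @property
    def q_h(self) -> int:
        return self.B_h + self.W_h

    def delta(self) -> int:
        return min(self.W_l + self.B_h, self.W_h + self.B_l)


@dataclass(frozen=True)
class TransferResult:
    phi: int
    ts: float
    argmin_branch: Bipartition
    per_branch_delta: tuple[int, ...] | None = None


def hamming(u: Sequence[int], v: Sequence[int]) -> int:
    """Hamming distance between two equal-length 0/1 vectors."""
    if len(u) != len(v):
        raise ValueError(f"length mismatch: {len(u)} != {len(v)}")
    return int(sum(1 for a, b in zip(u, v) if bool(a) != bool(b)))


def _check_universe(chi: Bicoloration, n: int, taxa) -> None:
    if chi.taxa != tuple(taxa):
        raise TreeValidationError("bicoloration and bipartition taxa differ")


def transfer_distance(chi: Bicoloration, b: Bipartition) -> int:
    """min over the two orientations of the Hamming distance between the
    bicoloration's encoding and the branch's encoding; zero iff they
    define the same bipartition."""
    if chi.n != b.n:
        raise TreeValidationError("taxon universe mismatch")
    h = (chi.black_mask ^ b.mask).bit_count()
    return min(h, b.n - h)


def _require_p(chi: Bicoloration) -> int:
    p = chi.p
    if p < 2:
        raise TreeValidationError("transfer support undefined for p < 2")
    if 2 * p > chi.n:
        raise TreeValidationError("black side must be the light side (p <= n/2)")
    return p


def transfer_index(
    chi: Bicoloration,
    tree: PhyloTree,
    keep_deltas: bool = False,
) -> TransferResult:
    """Minimum transfer distance over all branches, by a single O(n)
    postorder traversal accumulating black-tip counts per clade.

    Ties among minimising branches resolve to the first edge in the
    deterministic postorder enumeration.
    """
    if chi.taxa != tree.taxa:
        raise TreeValidationError("bicoloration and tree taxa differ")
    p = _require_p(chi)
    n = tree.n
    black = chi.black_mask
    leaf_labels = tree._leaf_labels
    idx = tree.taxon_index
    children = tree.postorder_children()

    counts: dict[int, int] = {}
    sizes: dict[int, int] = {}
    best = None  # (delta, edge position, child node)
    deltas: list[int] = []
    for pos, (v, parent) in enumerate(tree.postorder()):
        if v in leaf_labels:
            c = (black >> idx[leaf_labels[v]]) & 1
            s = 1
        else:
            c = sum(counts[w] for w in children[v])
            s = sum(sizes[w] for w in children[v])
        counts[v] = c
        sizes[v] = s
        if parent == -1:
            continue
        # clade side: s tips of which c black; other side: n-s tips, p-c black
        d = min((s - c) + (p - c), c + (n - p - s + c))
        if keep_deltas:
            deltas.append(d)
        if best is None or d < best[0]:
            best = (d, pos, v)
    assert best is not None
    phi = best[0]
    mask = next(m for v, _, m in tree.clade_masks() if v == best[2])
    return TransferResult(
        phi=phi,
        ts=1.0 - phi / (p - 1),
        argmin_branch=Bipartition(mask, n),
        per_branch_delta=tuple(deltas) if keep_deltas else None,
    )


def transfer_index_naive(chi: Bicoloration, tree: PhyloTree) -> int:
    """Oracle: recompute the Hamming-based transfer distance per edge."""
    if chi.taxa != tree.taxa:
        raise TreeValidationError("bicoloration and tree taxa differ")
    _require_p(chi)
    return min(
        transfer_distance(chi, Bipartition(mask, tree.n))
        for _, _, mask in tree.clade_masks()
    )


def side_counts(chi: Bicoloration, tree: PhyloTree, mask: int) -> SideCounts:
    """Black/white tallies for the branch whose clade-side mask is given."""
    n, p = tree.n, chi.p
    s = mask.bit_count()
    c = (mask & chi.black_mask).bit_count()
    if s <= n - s:
        return SideCounts(B_l=c, W_l=s - c, B_h=p - c, W_h=(n - s) - (p - c))
    return SideCounts(B_l=p - c, W_l=(n - s) - (p - c), B_h=c, W_h=s - c)


def transfer_index_batch(tree: PhyloTree, black_matrix: np.ndarray) -> np.ndarray:
    """Transfer index of many bicolorations against one tree.

    Parameters
    ----------
    black_matrix:
        boolean array of shape ``(m, n)``: row = one bicoloration, column
        order = the tree's canonical taxon order; every row must have the
        same number ``p`` of black taxa, ``2 <= p <= n/2``.

    Returns
    -------
    integer array of shape ``(m,)`` with the ``m`` transfer indices.
    """
    black_matrix = np.asarray(black_matrix, dtype=bool)
    m, n = black_matrix.shape
    if n != tree.n:
        raise TreeValidationError("column count must equal the taxon count")
    ps = black_matrix.sum(axis=1)
    if m == 0:
        return np.zeros(0, dtype=np.int64)
    p = int(ps[0])
    if not np.all(ps == p):
        raise TreeValidationError("all rows must have the same p")
    if p < 2 or 2 * p > n:
        raise TreeValidationError("need 2 <= p <= n/2")

    order = tree.postorder()
    children = tree.postorder_children()
    leaf_labels = tree._leaf_labels
    idx = tree.taxon_index
    counts: dict[int, np.ndarray] = {}
    sizes: dict[int, int] = {}
    best = np.full(m, p - 1, dtype=np.int64)  # pendant black tip bound
    for v, parent in order:
        if v in leaf_labels:
            c = black_matrix[:, idx[leaf_labels[v]]].astype(np.int64)
            s = 1
        else:
            ch = children[v]
            c = counts[ch[0]].copy()
            s = sizes[ch[0]]
            for w in ch[1:]:
                c += counts[w]
                s += sizes[w]
        counts[v] = c
        sizes[v] = s
        if parent == -1:
            continue
        d = np.minimum((s - c) + (p - c), c + (n - p - s + c))
        np.minimum(best, d, out=best)
    return best


def transfer_support(chi: Bicoloration, tree: PhyloTree) -> float:
    """``TS = 1 - phi/(p - 1)``, in [0, 1]."""
    res = transfer_index(chi, tree)
    return res.ts


def tbe(
    ref_tree: PhyloTree,
    branch: Bipartition,
    boot_trees: Iterable[PhyloTree],
) -> float:
    """Transfer bootstrap expectation of a reference branch.

    The mean of the transfer support of the branch over the bootstrap
    trees; identical to applying the ``1 - mean(phi)/(p-1)``
    normalisation to the mean transfer index.
    """
    boot = list(boot_trees)
    if not boot:
        raise ValueError("empty bootstrap tree set")
    chi = bicoloration_from_branch(ref_tree, branch)
    vals = []
    for t in boot:
        if t.taxa != ref_tree.taxa:
            raise TreeValidationError("bootstrap tree taxa differ from reference")
        vals.append(transfer_support(chi, t))
    return float(np.mean(vals))
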