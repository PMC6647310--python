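"""Newick I/O, bipartitions, and bicolorations.

Trees are undirected graphs whose leaves carry taxon labels.  All
bipartitions and bicolorations are encoded as integer bitmasks over a
*canonical taxon order*: the lexicographic order of the leaf labels,
fixed once per tree/analysis.  Bit ``i`` of a mask refers to the
``i``-th taxon in that order.  Newick parsing and serialisation are
delegated to :mod:`dendropy`; everything downstream operates on the
lightweight :class:`PhyloTree` graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "NewickParseError",
    "TreeValidationError",
    "Bipartition",
    "Bicoloration",
    "PhyloTree",
    "parse_newick",
    "write_newick",
    "read_newick_file",
    "write_newick_file",
    "bipartitions",
    "bicoloration_from_branch",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a tree violates a structural precondition."""


def _popcount(x: int) -> int:
    return x.bit_count()


@dataclass(frozen=True)
class Bipartition:
    """A split of the taxon set, identified with its complement.

    The stored ``mask`` is the canonical orientation: the numerically
    smaller of the two complementary bitmasks, so that a bipartition and
    its complement compare and hash equal.
    """

    mask: int
    n: int

    def __post_init__(self) -> None:
        full = (1 << self.n) - 1
        if not 0 < self.mask < full:
            raise TreeValidationError(
                "bipartition must have at least one taxon on each side"
            )
        canon = min(self.mask, self.mask ^ full)
        object.__setattr__(self, "mask", canon)

    @property
    def light_size(self) -> int:
        k = _popcount(self.mask)
        return min(k, self.n - k)

    @property
    def light_mask(self) -> int:
        """Mask of the smaller side; ties go to the side holding taxon 0."""
        full = (1 << self.n) - 1
        k = _popcount(self.mask)
        if 2 * k < self.n:
            return self.mask
        if 2 * k > self.n:
            return self.mask ^ full
        return self.mask if self.mask & 1 else self.mask ^ full

    def is_trivial(self) -> bool:
        return self.light_size == 1

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Bipartition(mask={self.mask:#x}, n={self.n})"


@dataclass(frozen=True)
class Bicoloration:
    """A black/white colouring of the taxa encoding a reference split.

    By convention black marks the light side of the reference
    bipartition, so ``p = popcount(black_mask)`` is the light-side size.
    """

    taxa: tuple[str, ...]
    black_mask: int

    @property
    def n(self) -> int:
        return len(self.taxa)

    @property
    def p(self) -> int:
        return _popcount(self.black_mask)

    @classmethod
    def from_black_labels(
        cls, taxa: Iterable[str], black: Iterable[str]
    ) -> "Bicoloration":
        order = tuple(sorted(taxa))
        index = {t: i for i, t in enumerate(order)}
        mask = 0
        for lab in black:
            if lab not in index:
                raise TreeValidationError(f"unknown taxon {lab!r}")
            mask |= 1 << index[lab]
        return cls(order, mask)

    def is_black(self, label: str) -> bool:
        try:
            i = self.taxa.index(label)
        except ValueError:
            raise TreeValidationError(f"unknown taxon {label!r}") from None
        return bool((self.black_mask >> i) & 1)

    def black_labels(self) -> tuple[str, ...]:
        return tuple(t for i, t in enumerate(self.taxa) if (self.black_mask >> i) & 1)

    def colors_in_tip_order(self, order: Sequence[str] | None = None) -> list[bool]:
        """Colours (True = black) scanned along ``order``.

        With no explicit order, labels are sorted numerically when they
        all look like integers (the caterpillar tip convention),
        lexicographically otherwise.
        """
        if order is None:
            try:
                order = sorted(self.taxa, key=int)
            except ValueError:
                order = list(self.taxa)
        index = {t: i for i, t in enumerate(self.taxa)}
        return [bool((self.black_mask >> index[t]) & 1) for t in order]

    def as_bipartition(self) -> Bipartition:
        return Bipartition(self.black_mask, self.n)


class PhyloTree:
    """Phylogenetic tree on labelled leaves.

    Parameters
    ----------
    adjacency:
        ``{node: [neighbours]}`` for an undirected tree; node ids are
        arbitrary hashable ints.
    leaf_labels:
        ``{leaf node: taxon label}``; every degree-1 node must appear.
    rooted:
        Whether the unique degree-2 vertex (if any) is a root.  Rooting
        is support-neutral: both root-adjacent branches induce the same
        bipartition.
    """

    def __init__(
        self,
        adjacency: dict[int, list[int]],
        leaf_labels: dict[int, str],
        rooted: bool = False,
    ) -> None:
        self._adj = {u: list(vs) for u, vs in adjacency.items()}
        self._leaf_labels = dict(leaf_labels)
        self.rooted = rooted
        self.taxa: tuple[str, ...] = tuple(sorted(self._leaf_labels.values()))
        self.taxon_index = {t: i for i, t in enumerate(self.taxa)}
        self._cache: dict[str, object] = {}
        self._validate_basic()

    # ------------------------------------------------------------------
    # structure
    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.taxa)

    def degree(self, v: int) -> int:
        return len(self._adj[v])

    def leaves(self) -> list[int]:
        return sorted(self._leaf_labels, key=lambda v: self._leaf_labels[v])

    def _validate_basic(self) -> None:
        labels = list(self._leaf_labels.values())
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeValidationError(f"duplicate leaf labels: {dup}")
        nodes = set(self._adj)
        nedges = sum(len(v) for v in self._adj.values())
        if nedges % 2 or nedges // 2 != len(nodes) - 1:
            raise TreeValidationError("graph is not a tree (wrong edge count)")
        for v, label in self._leaf_labels.items():
            if len(self._adj[v]) != 1:
                raise TreeValidationError(f"leaf {label!r} has degree != 1")
        for v in nodes:
            if v not in self._leaf_labels and len(self._adj[v]) < 2:
                raise TreeValidationError("unlabeled degree-1 vertex")
        # connectivity
        seen = set()
        stack = [next(iter(nodes))]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(self._adj[u])
        if seen != nodes:
            raise TreeValidationError("graph is not connected")

    def is_binary(self) -> bool:
        root_seen = False
        for v in self._adj:
            if v in self._leaf_labels:
                continue
            d = len(self._adj[v])
            if d == 3:
                continue
            if d == 2 and not root_seen:
                root_seen = True
                continue
            return False
        return True

    def require_binary(self) -> None:
        if not self.is_binary():
            raise TreeValidationError("tree is not binary")

    # ------------------------------------------------------------------
    # traversal (deterministic postorder rooted at a fixed vertex)
    # ------------------------------------------------------------------
    def traversal_root(self) -> int:
        """Degree-2 root if rooted, else the internal vertex adjacent to
        the lexicographically first leaf."""
        if self.rooted:
            for v in self._adj:
                if v not in self._leaf_labels and len(self._adj[v]) == 2:
                    return v
        first_leaf = min(self._leaf_labels, key=lambda v: self._leaf_labels[v])
        return self._adj[first_leaf][0]

    def postorder(self) -> list[tuple[int, int]]:
        """``(node, parent)`` pairs, children before parents; the
        traversal root appears last with parent ``-1``.  Every non-root
        entry corresponds to one edge of the tree."""
        cached = self._cache.get("postorder")
        if cached is not None:
            return cached  # type: ignore[return-value]
        root = self.traversal_root()
        order: list[tuple[int, int]] = []
        stack = [(root, -1)]
        while stack:
            v, parent = stack.pop()
            order.append((v, parent))
            for w in self._adj[v]:
                if w != parent:
                    stack.append((w, v))
        order.reverse()
        self._cache["postorder"] = order
        return order

    def postorder_children(self) -> dict[int, list[int]]:
        cached = self._cache.get("children")
        if cached is None:
            cached = {v: [] for v, _ in self.postorder()}
            for v, parent in self.postorder():
                if parent != -1:
                    cached[parent].append(v)
            self._cache["children"] = cached
        return cached  # type: ignore[return-value]

    def clade_masks(self) -> list[tuple[int, int, int]]:
        """Per edge ``(child, parent, mask)`` in postorder, where mask
        covers the taxa on the child side, in canonical taxon order."""
        cached = self._cache.get("clade_masks")
        if cached is not None:
            return cached  # type: ignore[return-value]
        masks: dict[int, int] = {}
        out: list[tuple[int, int, int]] = []
        for v, parent in self.postorder():
            if v in self._leaf_labels:
                masks[v] = 1 << self.taxon_index[self._leaf_labels[v]]
            else:
                m = 0
                for w in self._adj[v]:
                    if w != parent:
                        m |= masks[w]
                masks[v] = m
            if parent != -1:
                out.append((v, parent, masks[v]))
        self._cache["clade_masks"] = out
        return out

    # ------------------------------------------------------------------
    # serialisation helpers
    # ------------------------------------------------------------------
    def _to_dendropy(self) -> dendropy.Tree:
        ns = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=ns)
        root = self.traversal_root()

        def build(v: int, parent: int) -> dendropy.Node:
            node = dendropy.Node()
            if v in self._leaf_labels:
                node.taxon = ns.require_taxon(label=self._leaf_labels[v])
            for w in self._adj[v]:
                if w != parent:
                    node.add_child(build(w, v))
            return node

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 4 * len(self._adj) + 100))
        try:
            tree.seed_node = build(root, -1)
        finally:
            sys.setrecursionlimit(old)
        tree.is_rooted = self.rooted
        return tree

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "rooted" if self.rooted else "unrooted"
        return f"PhyloTree(n={self.n}, {kind})"


# ----------------------------------------------------------------------
# module-level operations
# ----------------------------------------------------------------------
def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Branch lengths and internal node labels are accepted and discarded:
    all transfer-distance machinery is purely topological.  A rooted
    input (degree-2 basal vertex) is kept rooted; rooting never affects
    any distance value.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick string: {exc}") from None

    adjacency: dict[int, list[int]] = {}
    leaf_labels: dict[int, str] = {}
    ids: dict[dendropy.Node, int] = {}
    for node in dtree.preorder_node_iter():
        ids[node] = len(ids)
        adjacency[ids[node]] = []
    for node in dtree.preorder_node_iter():
        for child in node.child_nodes():
            adjacency[ids[node]].append(ids[child])
            adjacency[ids[child]].append(ids[node])
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise NewickParseError("leaf without a label")
            leaf_labels[ids[node]] = node.taxon.label
    labels = list(leaf_labels.values())
    if len(set(labels)) != len(labels):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickParseError(f"duplicate leaf labels: {dup}")
    rooted = len(dtree.seed_node.child_nodes()) == 2
    return PhyloTree(adjacency, leaf_labels, rooted=rooted)


def write_newick(tree: PhyloTree) -> str:
    """Serialise to a Newick string (topology only)."""
    dtree = tree._to_dendropy()
    s = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_edge_lengths=True,
        unquoted_underscores=True,
    )
    return s.strip()


def read_newick_file(path) -> list[PhyloTree]:
    """Read a file with one Newick tree per line."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


def write_newick_file(path, trees: Iterable[PhyloTree]) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")


def bipartitions(tree: PhyloTree) -> list[Bipartition]:
    """All bipartitions induced by the branches, pendant edges included.

    For an unrooted binary tree this yields ``2n - 3`` splits; the two
    root-adjacent edges of a rooted tree induce the same split and are
    deduplicated.
    """
    if tree.n < 4:
        raise TreeValidationError("need n >= 4 taxa")
    seen: set[Bipartition] = set()
    out: list[Bipartition] = []
    for _, _, mask in tree.clade_masks():
        bp = Bipartition(mask, tree.n)
        if bp not in seen:
            seen.add(bp)
            out.append(bp)
    return out


def bicoloration_from_branch(tree: PhyloTree, branch: Bipartition) -> Bicoloration:
    """Reference bicoloration of a branch: black = light side.

    When the two sides tie (``n`` even, ``p = n/2``) black is the side
    containing the first taxon in canonical order; the transfer distance
    is complement-symmetric so the choice is inconsequential.
    """
    if branch.n != tree.n:
        raise TreeValidationError("branch does not match the tree's taxon set")
    light = branch.light_mask
    if _popcount(light) < 2:
        raise TreeValidationError(
            "transfer support undefined for a trivial branch (p < 2)"
        )
    return Bicoloration(tree.taxa, light)
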