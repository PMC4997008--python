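"""Rooted cladograms: Newick I/O, topology generators, shape metrics.

All congruence indices downstream are functions of topology and fossil
first-occurrence (FO) dates only; branch lengths in input Newick are parsed
and discarded.  Trees are rooted, tips carry unique labels, and internal
nodes may be polytomies (>2 children) until resolved against stratigraphy
with :func:`resolve_polytomies`.
"""

from __future__ import annotations

import itertools
import logging
from io import StringIO
from typing import Iterable, Iterator, Sequence

import dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "TreeError",
    "NewickParseError",
    "PolytomyError",
    "Node",
    "Cladogram",
    "parse_newick",
    "write_newick",
    "generate_pectinate",
    "generate_balanced",
    "enumerate_topologies",
    "colless_index",
    "percent_resolution",
    "resolve_polytomies",
    "cladogram_from_tuples",
]


class TreeError(ValueError):
    """Invalid tree structure or unsupported tree for an operation."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class PolytomyError(TreeError):
    """Operation requires a fully bifurcating tree; resolve polytomies first."""


class Node:
    """A node of a rooted cladogram.

    Tips carry a non-empty ``label``; internal nodes have >=2 ordered
    children.  Child order is preserved from input but is semantically
    irrelevant to every index.
    """

    __slots__ = ("label", "children", "parent")

    def __init__(self, label: str | None = None) -> None:
        self.label = label
        self.children: list[Node] = []
        self.parent: Node | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r})" if self.is_leaf else f"Node(<{len(self.children)} children>)"


class Cladogram:
    """A rooted tree with uniquely labelled tips; polytomies permitted."""

    def __init__(self, root: Node) -> None:
        self.root = root
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        labels: list[str] = []
        for node in self.postorder():
            if node.is_leaf:
                if not node.label:
                    raise TreeError("tip without a label")
                labels.append(node.label)
            elif len(node.children) < 2:
                raise TreeError("internal node with a single child")
            for child in node.children:
                if child.parent is not node:
                    raise TreeError("broken parent link")
        if len(labels) < 2:
            raise TreeError("a cladogram needs at least two tips")
        dup = {x for x in labels if labels.count(x) > 1}
        if dup:
            raise TreeError(f"duplicate tip labels: {sorted(dup)}")

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]  # type: ignore[misc]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def copy(self) -> "Cladogram":
        def clone(node: Node) -> Node:
            new = Node(node.label)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Cladogram(clone(self.root))

    def topology_equal(self, other: "Cladogram") -> bool:
        """True if the two trees are identical up to child reordering."""
        return write_newick(self) == write_newick(other)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Cladogram({write_newick(self)})"


# -- Newick I/O -------------------------------------------------------------


def parse_newick(text: str) -> Cladogram:
    """Parse a single rooted Newick statement into a :class:`Cladogram`.

    Branch lengths and internal-node labels are accepted and discarded.
    Raises :class:`NewickParseError` on malformed input, duplicate or empty
    tip labels, or an empty tree.
    """
    stripped = text.strip()
    if not stripped:
        raise NewickParseError("empty Newick string")
    if stripped.count(";") != 1 or not stripped.endswith(";"):
        raise NewickParseError("expected exactly one ';'-terminated Newick statement")
    try:
        dtree = dendropy.Tree.get(
            file=StringIO(stripped),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode: dendropy.Node) -> Node:
        if not dnode.child_nodes():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            if not label:
                raise NewickParseError("tip without a label")
            return Node(str(label))
        node = Node()
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    if root.is_leaf:
        raise NewickParseError("tree has a single tip; at least two required")
    try:
        return Cladogram(root)
    except TreeError as exc:
        raise NewickParseError(str(exc)) from exc


def _min_tip_label(node: Node) -> str:
    if node.is_leaf:
        return node.label  # type: ignore[return-value]
    return min(_min_tip_label(c) for c in node.children)


def write_newick(tree: Cladogram) -> str:
    """Emit labels-only Newick with canonical (alphabetical) child order."""

    def emit(node: Node) -> str:
        if node.is_leaf:
            return node.label  # type: ignore[return-value]
        parts = sorted(node.children, key=_min_tip_label)
        return "(" + ",".join(emit(c) for c in parts) + ")"

    return emit(tree.root) + ";"


# -- generators and enumeration ---------------------------------------------


def generate_pectinate(labels: Sequence[str]) -> Cladogram:
    """Maximally pectinate (ladder) binary tree; first label deepest."""
    if len(labels) < 2:
        raise TreeError("need at least two labels")
    node = Node()
    node.add_child(Node(labels[0]))
    node.add_child(Node(labels[1]))
    for label in labels[2:]:
        new_root = Node()
        new_root.add_child(node)
        new_root.add_child(Node(label))
        node = new_root
    return Cladogram(node)


def generate_balanced(labels: Sequence[str]) -> Cladogram:
    """Maximally balanced binary tree (perfect for 2**k labels).

    Label sets are split ceil/floor recursively, so for non-powers of two the
    result is the most even split obtainable at each node.
    """
    if len(labels) < 2:
        raise TreeError("need at least two labels")

    def build(chunk: Sequence[str]) -> Node:
        if len(chunk) == 1:
            return Node(chunk[0])
        mid = (len(chunk) + 1) // 2
        node = Node()
        node.add_child(build(chunk[:mid]))
        node.add_child(build(chunk[mid:]))
        return node

    return Cladogram(build(list(labels)))


def _enumerate_tuples(labels: Sequence[str]) -> Iterator[tuple]:
    """All rooted binary labelled topologies as nested 2-tuples."""

    def insertions(t, leaf):
        yield (t, leaf)
        if isinstance(t, tuple):
            for left in insertions(t[0], leaf):
                yield (left, t[1])
            for right in insertions(t[1], leaf):
                yield (t[0], right)

    trees: list = [(labels[0], labels[1])]
    for leaf in labels[2:]:
        trees = [grown for t in trees for grown in insertions(t, leaf)]
    yield from trees


def cladogram_from_tuples(t: tuple) -> Cladogram:
    """Build a Cladogram from nested 2-tuples of labels, e.g. ``(('A','B'),'C')``."""

    def build(x) -> Node:
        if isinstance(x, tuple):
            node = Node()
            for part in x:
                node.add_child(build(part))
            return node
        return Node(str(x))

    return Cladogram(build(t))


def enumerate_topologies(labels: Sequence[str]) -> Iterator[Cladogram]:
    """Yield every labelled rooted binary topology on ``labels`` exactly once.

    The count is the double factorial (2n-3)!!; restricted to 2 <= n <= 7 to
    keep exhaustive searches tractable (10395 topologies at n = 7).
    """
    n = len(labels)
    if not 2 <= n <= 7:
        raise TreeError(f"enumeration supported for 2..7 labels, got {n}")
    for t in _enumerate_tuples(labels):
        yield cladogram_from_tuples(t)


# -- shape metrics ----------------------------------------------------------


def _tip_counts(tree: Cladogram) -> dict[Node, int]:
    counts: dict[Node, int] = {}
    for node in tree.postorder():
        counts[node] = 1 if node.is_leaf else sum(counts[c] for c in node.children)
    return counts


def colless_index(tree: Cladogram) -> float:
    """Colless imbalance Ic, scaled to [0, 1].

    Ic = sum over internal nodes of |L - R| (tip counts of the two child
    clades), divided by (n-1)(n-2)/2; 1.0 for a maximally pectinate tree and
    0.0 for a perfectly balanced tree on 2**k tips.
    """
    if not tree.is_binary:
        raise PolytomyError(
            "Colless index requires a binary tree; use resolve_polytomies first"
        )
    n = tree.n_tips
    if n < 3:
        raise TreeError("Colless index undefined for fewer than 3 tips")
    counts = _tip_counts(tree)
    total = sum(
        abs(counts[node.children[0]] - counts[node.children[1]])
        for node in tree.internal_nodes()
    )
    return total / ((n - 1) * (n - 2) / 2)


def percent_resolution(tree: Cladogram) -> float:
    """Percentage of resolved nodes: r/(n-2)*100 with the root excluded from r.

    A fully bifurcating rooted tree has n-1 internal nodes, n-2 of them
    non-root, so full resolution returns exactly 100; a star tree returns 0.
    """
    n = tree.n_tips
    if n < 3:
        raise TreeError("resolution undefined for fewer than 3 tips")
    r = len(tree.internal_nodes()) - 1
    return r / (n - 2) * 100.0


# -- polytomy resolution ----------------------------------------------------


def resolve_polytomies(tree: Cladogram, fo, mode: str = "hard") -> Cladogram:
    """Resolve every polytomy into a ladder ranked by clade-oldest FO date.

    ``mode='soft'`` places the oldest child as the earliest divergence, so the
    only implied gaps within the polytomy are the consecutive FO gaps (the
    stratigraphically most congruent resolution).  ``mode='hard'`` nests the
    oldest child deepest, maximizing the implied gap, so a fully unresolved
    tree yields congruence indices at their theoretical minima.

    Ties in clade-oldest FO preserve input child order (logged).
    ``fo`` is any object with an ``age_of(label) -> float`` method
    (see :class:`stratcong.stratigraphy.FOTable`).
    """
    if mode not in ("hard", "soft"):
        raise ValueError(f"mode must be 'hard' or 'soft', got {mode!r}")
    out = tree.copy()

    def clade_oldest(node: Node) -> float:
        if node.is_leaf:
            return float(fo.age_of(node.label))
        return max(clade_oldest(c) for c in node.children)

    def ladder(children: list[Node]) -> Node:
        # children ordered from earliest-diverging to deepest-nested pair
        if len(children) == 2:
            node = Node()
            node.add_child(children[0])
            node.add_child(children[1])
            return node
        node = Node()
        node.add_child(children[0])
        node.add_child(ladder(children[1:]))
        return node

    for node in list(out.postorder()):
        if len(node.children) <= 2:
            continue
        keyed = [(clade_oldest(c), i, c) for i, c in enumerate(node.children)]
        ages = [k[0] for k in keyed]
        if len(set(ages)) < len(ages):
            logger.info(
                "tie in clade-oldest FO while resolving a %d-way polytomy; "
                "input child order preserved",
                len(node.children),
            )
        # stable sort: oldest first for soft (earliest divergence),
        # youngest first for hard (oldest ends up most nested)
        reverse = mode == "soft"
        keyed.sort(key=lambda k: -k[0] if reverse else k[0])
        ordered = [k[2] for k in keyed]
        replacement = ladder(ordered)
        if node.parent is None:
            out.root = replacement
            replacement.parent = None
        else:
            idx = node.parent.children.index(node)
            node.parent.children[idx] = replacement
            replacement.parent = node.parent
    return Cladogram(out.root)
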