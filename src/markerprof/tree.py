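"""Edge-numbered phylogenetic trees in the jplace newick dialect.

Phylogenetic placement tools identify tree edges by an integer written in
curly braces after the branch length, e.g. ``(A:0.1{0},B:0.2{1}):0.3{2};``.
This module wraps :mod:`dendropy` trees with that numbering: parsing rewrites
``{N}`` tags into metadata comments that dendropy attaches to nodes, and
serialization is a small recursive writer so tag placement and float
round-tripping stay exact.

Multifurcations are preserved; both ``:0.1{5}`` and a bare ``{5}`` (length
defaulting to 0) are accepted on read.
"""

from __future__ import annotations

import re
from typing import Dict, FrozenSet, Iterable, List, Optional

import dendropy

_EDGE_TAG = re.compile(r"\{(\d+)\}")


class TreeError(ValueError):
    """Raised for malformed or inconsistent edge-numbered trees."""


class EdgeNumberedTree:
    """A rooted tree whose edges carry unique non-negative integer numbers.

    Every non-root edge carries a number; a number on the root edge is
    accepted on input and preserved.  Leaf labels are unique.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._index_edges()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "EdgeNumberedTree":
        """Parse a newick string with ``{N}`` edge numbers."""
        converted = _EDGE_TAG.sub(r"[&edge=\1]", newick)
        try:
            dtree = dendropy.Tree.get(
                data=converted,
                schema="newick",
                suppress_internal_node_taxa=True,
                extract_comment_metadata=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"cannot parse newick: {exc}") from exc
        for node in dtree:
            values = node.annotations.values_as_dict()
            if "edge" in values:
                node.edge.edge_num = int(values["edge"])
            node.annotations.clear()
        return cls(dtree)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree, number_edges: bool = False) -> "EdgeNumberedTree":
        if number_edges:
            num = 0
            for node in dtree.preorder_node_iter():
                if node.parent_node is None:
                    node.edge.edge_num = None
                else:
                    node.edge.edge_num = num
                    num += 1
        return cls(dtree)

    def _index_edges(self) -> None:
        self._edges: Dict[int, dendropy.Edge] = {}
        self._leaf_nodes: Dict[str, dendropy.Node] = {}
        for node in self._tree:
            num = getattr(node.edge, "edge_num", None)
            if num is None:
                if node.parent_node is not None:
                    raise TreeError("non-root edge without an edge number")
            else:
                if num in self._edges:
                    raise TreeError(f"duplicate edge number {num}")
                self._edges[num] = node.edge
            if node.is_leaf():
                label = _leaf_label(node)
                if label is None:
                    raise TreeError("leaf without a label")
                if label in self._leaf_nodes:
                    raise TreeError(f"duplicate leaf label {label!r}")
                self._leaf_nodes[label] = node
        # clade leaf sets, computed postorder once
        self._clades: Dict[int, FrozenSet[str]] = {}
        below: Dict[int, FrozenSet[str]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                leaves = frozenset([_leaf_label(node)])
            else:
                leaves = frozenset().union(
                    *(below[id(c)] for c in node.child_nodes())
                )
            below[id(node)] = leaves
            num = getattr(node.edge, "edge_num", None)
            if num is not None:
                self._clades[num] = leaves

    # -- queries ------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def leaf_labels(self) -> List[str]:
        return sorted(self._leaf_nodes)

    def __contains__(self, edge_num: int) -> bool:
        return edge_num in self._edges

    def edge_numbers(self) -> List[int]:
        return sorted(self._edges)

    def branch_length(self, edge_num: int) -> float:
        length = self._edges[edge_num].length
        return 0.0 if length is None else float(length)

    def pendant_edge_num(self, leaf_label: str) -> int:
        node = self._leaf_nodes[leaf_label]
        num = getattr(node.edge, "edge_num", None)
        if num is None:
            raise TreeError(f"pendant edge of {leaf_label!r} is unnumbered")
        return num

    def clade_leaves(self, edge_num: int) -> FrozenSet[str]:
        """Leaf labels on the far-from-root side of the edge."""
        return self._clades[edge_num]

    def path_length(self, leaf_a: str, leaf_b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        anc_a = {}
        node = self._leaf_nodes[leaf_a]
        dist = 0.0
        while node is not None:
            anc_a[id(node)] = dist
            dist += node.edge.length or 0.0
            node = node.parent_node
        node = self._leaf_nodes[leaf_b]
        dist = 0.0
        while node is not None:
            if id(node) in anc_a:
                return dist + anc_a[id(node)]
            dist += node.edge.length or 0.0
            node = node.parent_node
        raise TreeError("leaves do not share a root")  # pragma: no cover

    # -- transformation -----------------------------------------------

    def prune_to(self, keep_leaves: Iterable[str]) -> "EdgeNumberedTree":
        """Restrict the tree to the given leaves.

        Suppressed degree-2 nodes have their branch lengths summed, so the
        path length between any two retained leaves is preserved.  Edge
        numbers are reassigned in preorder.
        """
        keep = set(keep_leaves)
        missing = keep - set(self._leaf_nodes)
        if missing:
            raise TreeError(f"cannot retain unknown leaves: {sorted(missing)}")
        if not keep:
            raise TreeError("cannot prune to an empty leaf set")
        clone = self._tree.extract_tree()  # deep structural copy
        remove = [
            node
            for node in clone.leaf_node_iter()
            if _leaf_label(node) not in keep
        ]
        for node in remove:
            parent = node.parent_node
            parent.remove_child(node)
            # walk up removing now-childless internals
            while parent is not None and parent.num_child_nodes() == 0:
                grand = parent.parent_node
                if grand is None:
                    break
                grand.remove_child(parent)
                parent = grand
        clone.suppress_unifurcations()
        seed = clone.seed_node
        while seed.num_child_nodes() == 1:
            child = seed.child_nodes()[0]
            child.parent_node = None
            clone.seed_node = seed = child
            seed.edge.length = None
        return EdgeNumberedTree.from_dendropy(clone, number_edges=True)

    # -- serialization ------------------------------------------------

    def to_newick(self) -> str:
        return _write_node(self._tree.seed_node) + ";"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EdgeNumberedTree):
            return NotImplemented
        return self.to_newick() == other.to_newick()


def _leaf_label(node: dendropy.Node) -> Optional[str]:
    if node.taxon is not None and node.taxon.label is not None:
        return node.taxon.label
    return node.label


def _fmt_length(length: float) -> str:
    return repr(float(length))


def _write_node(node: dendropy.Node) -> str:
    if node.is_leaf():
        out = _quote_label(_leaf_label(node))
    else:
        inner = ",".join(_write_node(c) for c in node.child_nodes())
        out = "(" + inner + ")" + (_quote_label(node.label) if node.label else "")
    num = getattr(node.edge, "edge_num", None)
    if node.edge.length is not None:
        out += ":" + _fmt_length(node.edge.length)
    elif num is not None and node.parent_node is not None:
        out += ":0.0"
    if num is not None:
        out += "{%d}" % num
    return out


_SAFE_LABEL = re.compile(r"^[\w.\-|]+$")


def _quote_label(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"
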