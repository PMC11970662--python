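"""Taxonomy data model: ranked nodes with parent links and lineage queries.

The taxonomy is a rooted tree of nodes, each carrying one of the seven
canonical ranks (superkingdom through species) or ``"no rank"``.  "no rank"
nodes are permitted anywhere and are transparent to lineage queries, which
matches the structure of the NCBI taxonomy without implementing its dump
format.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional

#: Canonical ranks in root-to-tip order.
CANONICAL_RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

NO_RANK = "no rank"

_RANK_DEPTH = {rank: i for i, rank in enumerate(CANONICAL_RANKS)}


class TaxonomyError(ValueError):
    """Raised when a taxonomy violates its structural invariants."""


@dataclass(frozen=True)
class TaxonomyNode:
    """One taxon: identifier, parent link, rank and display name."""

    tax_id: str
    parent_id: Optional[str]  # None only for the root
    rank: str
    name: str


class Taxonomy:
    """A validated set of :class:`TaxonomyNode` indexed by ``tax_id``.

    Validation enforces: exactly one root, acyclic parent links, parent ids
    that resolve, and canonical ranks strictly descending along every
    root-to-leaf path (``"no rank"`` nodes may interleave freely).
    """

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self.nodes: Dict[str, TaxonomyNode] = {}
        for node in nodes:
            if node.tax_id in self.nodes:
                raise TaxonomyError(f"duplicate tax_id {node.tax_id!r}")
            self.nodes[node.tax_id] = node
        self._lineage_cache: Dict[str, Dict[str, Optional[str]]] = {}
        self._validate()

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise TaxonomyError(
                f"expected exactly one root node, found {len(roots)}"
            )
        self.root = roots[0]
        for node in self.nodes.values():
            if node.rank != NO_RANK and node.rank not in _RANK_DEPTH:
                raise TaxonomyError(
                    f"node {node.tax_id!r} has unknown rank {node.rank!r}"
                )
            if node.parent_id is not None and node.parent_id not in self.nodes:
                raise TaxonomyError(
                    f"node {node.tax_id!r} references missing parent "
                    f"{node.parent_id!r}"
                )
        # Acyclicity + rank ordering in one upward walk per node.
        state: Dict[str, int] = {}  # 0 = visiting, 1 = done
        for start in self.nodes:
            if state.get(start) == 1:
                continue
            path = []
            cur: Optional[str] = start
            while cur is not None:
                if state.get(cur) == 1:
                    break
                if state.get(cur) == 0:
                    raise TaxonomyError(
                        f"cyclic parent links involving tax_id {cur!r}"
                    )
                state[cur] = 0
                path.append(cur)
                cur = self.nodes[cur].parent_id
            for tax_id in path:
                state[tax_id] = 1
        for node in self.nodes.values():
            if node.rank == NO_RANK:
                continue
            anc = self._nearest_ranked_ancestor(node)
            if anc is not None and _RANK_DEPTH[anc.rank] >= _RANK_DEPTH[node.rank]:
                raise TaxonomyError(
                    f"rank order violated: {node.tax_id!r} ({node.rank}) "
                    f"below {anc.tax_id!r} ({anc.rank})"
                )

    def _nearest_ranked_ancestor(self, node: TaxonomyNode) -> Optional[TaxonomyNode]:
        cur = node.parent_id
        while cur is not None:
            parent = self.nodes[cur]
            if parent.rank != NO_RANK:
                return parent
            cur = parent.parent_id
        return None

    # -- queries ------------------------------------------------------

    def __contains__(self, tax_id: str) -> bool:
        return tax_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def lineage(self, tax_id: str) -> Dict[str, Optional[str]]:
        """Map each canonical rank to the ancestor (or self) at that rank.

        Ranks with no ancestor are ``None`` ("undefined").
        """
        cached = self._lineage_cache.get(tax_id)
        if cached is not None:
            return cached
        if tax_id not in self.nodes:
            raise KeyError(f"unknown tax_id {tax_id!r}")
        out: Dict[str, Optional[str]] = {rank: None for rank in CANONICAL_RANKS}
        cur: Optional[str] = tax_id
        while cur is not None:
            node = self.nodes[cur]
            if node.rank in _RANK_DEPTH:
                out[node.rank] = node.tax_id
            cur = node.parent_id
        self._lineage_cache[tax_id] = out
        return out

    def ancestor_at(self, tax_id: str, rank: str) -> Optional[str]:
        return self.lineage(tax_id)[rank]

    def rank_of(self, tax_id: str) -> str:
        return self.nodes[tax_id].rank

    def name_of(self, tax_id: str) -> str:
        return self.nodes[tax_id].name

    def at_rank(self, rank: str) -> list[str]:
        """All tax_ids carrying the given canonical rank, sorted."""
        return sorted(t for t, n in self.nodes.items() if n.rank == rank)

    def lineage_string(self, tax_id: str, sep: str = "|") -> str:
        """Pipe-joined tax_ids of the defined canonical ranks, root to tip."""
        lin = self.lineage(tax_id)
        depth = _RANK_DEPTH.get(self.nodes[tax_id].rank, len(CANONICAL_RANKS) - 1)
        parts = [lin[r] or "" for r in CANONICAL_RANKS[: depth + 1]]
        return sep.join(parts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Taxonomy):
            return NotImplemented
        return self.nodes == other.nodes
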