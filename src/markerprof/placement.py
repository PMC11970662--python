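"""Phylogenetic placements: jplace I/O and a deterministic naive placer.

Placement assigns a query read probability mass (likelihood weight ratios,
LWR) over edges of a reference tree; the interchange format is jplace
(versions 2 and 3 accepted).  Production placements come from external
maximum-likelihood placers; the :func:`naive_place` similarity placer here
is a deterministic desk-scale stand-in so the downstream classification and
profiling stages run end-to-end without external tools.  It is not a
substitute for likelihood-based placement accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .refpkg import MarkerGene
from .tree import EdgeNumberedTree

LWR_SUM_TOL = 1e-6

DEFAULT_FIELDS = (
    "edge_num",
    "like_weight_ratio",
    "pendant_length",
    "distal_length",
)


class JplaceError(ValueError):
    """Raised for malformed or inconsistent jplace documents."""


@dataclass(frozen=True)
class PlacementEntry:
    edge_num: int
    lwr: float
    pendant_length: Optional[float] = None
    distal_length: Optional[float] = None


@dataclass
class PlacementRecord:
    """One read's probability mass over tree edges, sorted by falling LWR."""

    read_id: str
    entries: List[PlacementEntry]

    @property
    def total_mass(self) -> float:
        return sum(e.lwr for e in self.entries)

    def validate(self, tree: Optional[EdgeNumberedTree] = None) -> None:
        for e in self.entries:
            if e.lwr < 0:
                raise JplaceError(
                    f"read {self.read_id!r}: negative like_weight_ratio {e.lwr}"
                )
            if tree is not None and e.edge_num not in tree:
                raise JplaceError(
                    f"read {self.read_id!r}: edge {e.edge_num} absent from tree"
                )
        if self.total_mass > 1 + LWR_SUM_TOL:
            raise JplaceError(
                f"read {self.read_id!r}: like_weight_ratio sum "
                f"{self.total_mass} exceeds 1"
            )


@dataclass
class PlacementSet:
    """A reference tree plus one placement record per read."""

    tree: EdgeNumberedTree
    records: List[PlacementRecord]
    fields_order: Sequence[str] = DEFAULT_FIELDS

    def validate(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.read_id in seen:
                raise JplaceError(f"duplicate read id {rec.read_id!r}")
            seen.add(rec.read_id)
            rec.validate(self.tree)


# -- jplace I/O --------------------------------------------------------

_EDGE_FIELD_NAMES = ("edge_num", "edge_number")


def read_jplace(path: str | Path) -> PlacementSet:
    """Read a jplace (v2/v3) document.

    Field order in the document is honored by name.  Entries are ordered by
    decreasing LWR per record.  Records whose LWR sum exceeds 1 (beyond
    tolerance), cite unknown edges, or carry negative LWR are rejected.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise JplaceError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("tree", "placements", "fields", "version"):
        if key not in doc:
            raise JplaceError(f"{path}: missing mandatory key {key!r}")
    fields = list(doc["fields"])
    edge_field = next((f for f in fields if f in _EDGE_FIELD_NAMES), None)
    if edge_field is None or "like_weight_ratio" not in fields:
        raise JplaceError(
            f"{path}: 'fields' must include an edge identifier and like_weight_ratio"
        )
    idx = {name: i for i, name in enumerate(fields)}
    tree = EdgeNumberedTree.from_newick(doc["tree"].strip())
    records: List[PlacementRecord] = []
    for pl in doc["placements"]:
        names = _placement_names(pl)
        entries = []
        for row in pl["p"]:
            entries.append(
                PlacementEntry(
                    edge_num=int(row[idx[edge_field]]),
                    lwr=float(row[idx["like_weight_ratio"]]),
                    pendant_length=(
                        float(row[idx["pendant_length"]])
                        if "pendant_length" in idx
                        else None
                    ),
                    distal_length=(
                        float(row[idx["distal_length"]])
                        if "distal_length" in idx
                        else None
                    ),
                )
            )
        entries.sort(key=lambda e: (-e.lwr, e.edge_num))
        for name in names:
            records.append(PlacementRecord(read_id=name, entries=list(entries)))
    pset = PlacementSet(tree=tree, records=records, fields_order=tuple(fields))
    pset.validate()
    return pset


def _placement_names(pl: dict) -> List[str]:
    if "n" in pl:
        return [str(n) for n in pl["n"]]
    if "nm" in pl:
        return [str(pair[0]) for pair in pl["nm"]]
    raise JplaceError("placement without 'n' or 'nm' name key")


def write_jplace(pset: PlacementSet, path: str | Path) -> None:
    """Write a version-3 jplace document; round-trips through read_jplace."""
    pset.validate()
    fields = list(pset.fields_order)
    idx_known = {"edge_num", "edge_number", "like_weight_ratio",
                 "pendant_length", "distal_length"}
    placements = []
    for rec in pset.records:
        rows = []
        for e in rec.entries:
            row = []
            for f in fields:
                if f in _EDGE_FIELD_NAMES:
                    row.append(e.edge_num)
                elif f == "like_weight_ratio":
                    row.append(e.lwr)
                elif f == "pendant_length":
                    row.append(e.pendant_length if e.pendant_length is not None else 0.0)
                elif f == "distal_length":
                    row.append(e.distal_length if e.distal_length is not None else 0.0)
                elif f not in idx_known:
                    row.append(0.0)  # fields we do not model (e.g. likelihood)
            rows.append(row)
        placements.append({"p": rows, "n": [rec.read_id]})
    doc = {
        "version": 3,
        "tree": pset.tree.to_newick(),
        "fields": fields,
        "placements": placements,
        "metadata": {"invocation": "markerprof"},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# -- naive similarity placer ------------------------------------------

_BASE_CODE = {"A": 1, "C": 2, "G": 3, "T": 4, "U": 4}


def _encode(seq: str, unknown: int) -> np.ndarray:
    """Encode a sequence as small ints; unknown/ambiguous bases get `unknown`."""
    out = np.full(len(seq), unknown, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        mask = np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(base)
        out[mask] = code
    return out


def _best_offset_score(query: np.ndarray, subject: np.ndarray) -> int:
    """Max matching-position count over all ungapped offsets.

    The shorter sequence slides fully inside the longer one; ambiguous
    bases never match (query N encoded 0, subject N encoded -1).
    """
    short, long_ = (query, subject) if len(query) <= len(subject) else (subject, query)
    if len(short) == 0:
        return 0
    windows = np.lib.stride_tricks.sliding_window_view(long_, len(short))
    return int((windows == short).sum(axis=1).max())


def _encoded_leaves(gene: MarkerGene) -> Dict[str, np.ndarray]:
    return {
        leaf: _encode(gene.degapped(leaf), unknown=-1)
        for leaf in gene.tree.leaf_labels()
    }


def naive_place(
    query_sequence: str,
    gene: MarkerGene,
    read_id: str = "query",
    tie_margin: int = 0,
    _leaves: Optional[Dict[str, np.ndarray]] = None,
) -> PlacementRecord:
    """Place a query on the pendant edges of its most similar leaves.

    For each leaf, similarity is the maximum count of matching positions
    over all ungapped offsets of the query against that leaf's degapped
    sequence; ambiguous bases (N) never match.  The set of leaves within
    ``tie_margin`` of the best score shares the mass equally (LWR 1/|set|
    on each pendant edge); entries are sorted by edge number for
    determinism.
    """
    if len(query_sequence) < 1:
        raise ValueError("query sequence must be non-empty")
    if not gene.msa or not gene.tree.leaf_labels():
        raise ValueError(f"gene {gene.name!r} has an empty MSA")
    encoded = _leaves if _leaves is not None else _encoded_leaves(gene)
    q = _encode(query_sequence, unknown=0)
    scores = {leaf: _best_offset_score(q, s) for leaf, s in encoded.items()}
    best = max(scores.values())
    tied = sorted(l for l, s in scores.items() if s >= best - tie_margin)
    lwr = 1.0 / len(tied)
    entries = sorted(
        (
            PlacementEntry(
                edge_num=gene.tree.pendant_edge_num(leaf),
                lwr=lwr,
                pendant_length=0.0,
                distal_length=0.0,
            )
            for leaf in tied
        ),
        key=lambda e: e.edge_num,
    )
    return PlacementRecord(read_id=read_id, entries=entries)


def naive_place_all(
    queries: Dict[str, str],
    gene: MarkerGene,
    tie_margin: int = 0,
) -> PlacementSet:
    """Place many queries on one gene's tree; record order follows input order."""
    encoded = _encoded_leaves(gene)
    records = [
        naive_place(seq, gene, read_id=read_id, tie_margin=tie_margin, _leaves=encoded)
        for read_id, seq in queries.items()
    ]
    pset = PlacementSet(tree=gene.tree, records=records)
    pset.validate()
    return pset
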