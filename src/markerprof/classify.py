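"""Stage 2 classification: placement mass → per-rank taxon supports → labels.

Each tree edge implies, at every canonical rank, either a single taxon (the
one shared by all leaves on the far-from-root side of the edge) or
"undefined".  A read's support for taxon *t* at rank *r* is the sum of its
likelihood weight ratios over edges labeled *t* at *r*; mass on edges that
are undefined at *r* counts toward no taxon there (it dilutes support, it is
not redistributed).  The read is then labeled top-down along a single
lineage, keeping every rank whose support meets the threshold and stopping
at the first failure — e.g. with supports 0.80 at species and 0.98 at genus
under a 95% threshold, the read is classified at genus and all higher ranks
but not at species.

Default thresholds: 0.90 for externally produced maximum-likelihood
placements, 0.95 for the fast preset.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .placement import PlacementRecord, PlacementSet
from .refpkg import MarkerGene
from .taxonomy import CANONICAL_RANKS, Taxonomy
from .tree import EdgeNumberedTree

#: Support threshold for maximum-likelihood placements (default mode).
DEFAULT_THRESHOLD = 0.90
#: Support threshold for the fast-placement preset.
FAST_THRESHOLD = 0.95

UNCLASSIFIED = "unclassified"

_TOL = 1e-9


@dataclass(frozen=True)
class EdgeLineage:
    """Per-rank taxon labels implied by one edge (None = undefined)."""

    edge_num: int
    labels: Dict[str, Optional[str]]


@dataclass
class RankSupport:
    """Summed placement mass per taxon at one rank, with the chosen top taxon."""

    rank: str
    masses: Dict[str, float]
    top_taxon: Optional[str]
    support: float


@dataclass
class ReadClassification:
    """Per-rank labels for one read; classified ranks form a root-anchored prefix."""

    read_id: str
    gene: str
    per_rank: Dict[str, Tuple[str, float]]  # rank -> (tax_id, support)
    lowest_rank: str  # deepest classified rank, or "unclassified"


def edge_lineage_map(
    tree: EdgeNumberedTree,
    leaf_taxa: Dict[str, str],
    taxonomy: Taxonomy,
) -> Dict[int, EdgeLineage]:
    """Label every numbered edge at every canonical rank.

    The label at rank *r* is taxon *t* iff every leaf in the edge's clade
    has lineage taxon *t* at *r*; otherwise undefined (None).
    """
    leaf_lineages: Dict[str, Dict[str, Optional[str]]] = {}
    for leaf in tree.leaf_labels():
        if leaf not in leaf_taxa:
            raise ValueError(f"leaf {leaf!r} has no tax_id")
        leaf_lineages[leaf] = taxonomy.lineage(leaf_taxa[leaf])
    out: Dict[int, EdgeLineage] = {}
    for edge_num in tree.edge_numbers():
        clade = tree.clade_leaves(edge_num)
        labels: Dict[str, Optional[str]] = {}
        for rank in CANONICAL_RANKS:
            values = {leaf_lineages[leaf][rank] for leaf in clade}
            labels[rank] = values.pop() if len(values) == 1 else None
        out[edge_num] = EdgeLineage(edge_num=edge_num, labels=labels)
    return out


def support_by_rank(
    record: PlacementRecord,
    lineages: Dict[int, EdgeLineage],
    taxonomy: Optional[Taxonomy] = None,
) -> Dict[str, RankSupport]:
    """Sum placement mass into taxa at each rank and pick top taxa.

    Top taxa are chosen by lineage-consistent descent: walking root-to-tip,
    at each rank the taxon with maximum mass among those consistent with
    the taxa already chosen at shallower ranks (ties broken by smaller
    tax_id).  Consistency is read off the edge labels themselves (nested by
    construction), so no taxonomy lookup is required; ``taxonomy`` is
    accepted for interface symmetry.
    """
    masses: Dict[str, Dict[str, float]] = {r: {} for r in CANONICAL_RANKS}
    # ancestor labels observed for each (rank, taxon), for consistency checks
    anc: Dict[Tuple[str, str], Dict[str, Optional[str]]] = {}
    for entry in record.entries:
        if entry.edge_num not in lineages:
            raise ValueError(f"edge {entry.edge_num} missing from lineage map")
        labels = lineages[entry.edge_num].labels
        for i, rank in enumerate(CANONICAL_RANKS):
            taxon = labels[rank]
            if taxon is None:
                continue
            masses[rank][taxon] = masses[rank].get(taxon, 0.0) + entry.lwr
            key = (rank, taxon)
            if key not in anc:
                anc[key] = {r: labels[r] for r in CANONICAL_RANKS[:i]}
    out: Dict[str, RankSupport] = {}
    chosen: Dict[str, Optional[str]] = {}
    for rank in CANONICAL_RANKS:
        candidates = {
            t: m
            for t, m in masses[rank].items()
            if _consistent(anc[(rank, t)], chosen)
        }
        if candidates:
            top = min(candidates, key=lambda t: (-candidates[t], t))
            support = candidates[top]
        else:
            top, support = None, 0.0
        chosen[rank] = top
        out[rank] = RankSupport(
            rank=rank, masses=masses[rank], top_taxon=top, support=support
        )
    return out


def _consistent(
    ancestors: Dict[str, Optional[str]], chosen: Dict[str, Optional[str]]
) -> bool:
    for rank, taxon in chosen.items():
        if taxon is not None and ancestors.get(rank) not in (None, taxon):
            return False
    return True


def classify_read(
    record: PlacementRecord,
    lineages: Dict[int, EdgeLineage],
    threshold: float = DEFAULT_THRESHOLD,
    gene: str = "",
) -> ReadClassification:
    """Label a read at every rank whose support meets the threshold.

    Ranks are walked root-to-tip along the lineage-consistent top taxa;
    classification stops at the first rank whose support falls below the
    threshold, so the classified ranks always form a contiguous prefix.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    supports = support_by_rank(record, lineages)
    per_rank: Dict[str, Tuple[str, float]] = {}
    lowest = UNCLASSIFIED
    for rank in CANONICAL_RANKS:
        rs = supports[rank]
        if rs.top_taxon is None or rs.support < threshold - _TOL:
            break
        per_rank[rank] = (rs.top_taxon, rs.support)
        lowest = rank
    return ReadClassification(
        read_id=record.read_id, gene=gene, per_rank=per_rank, lowest_rank=lowest
    )


def classify_all(
    pset: PlacementSet,
    gene: MarkerGene,
    taxonomy: Taxonomy,
    threshold: float = DEFAULT_THRESHOLD,
) -> List[ReadClassification]:
    """Classify every record of a placement set against one marker gene."""
    pset_leaves = set(pset.tree.leaf_labels())
    gene_leaves = set(gene.tree.leaf_labels())
    if not pset_leaves <= gene_leaves:
        raise ValueError(
            f"placement tree has leaves absent from gene {gene.name!r}: "
            f"{sorted(pset_leaves - gene_leaves)[:5]}"
        )
    lineages = edge_lineage_map(pset.tree, gene.leaf_taxa, taxonomy)
    return [
        classify_read(rec, lineages, threshold=threshold, gene=gene.name)
        for rec in pset.records
    ]


# -- TSV I/O -----------------------------------------------------------


def write_classifications_tsv(
    classifications: Sequence[ReadClassification], path: str | Path
) -> None:
    cols = ["read_id", "gene", "lowest_rank"]
    for rank in CANONICAL_RANKS:
        cols += [rank, f"{rank}_support"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for c in classifications:
            row = [c.read_id, c.gene, c.lowest_rank]
            for rank in CANONICAL_RANKS:
                if rank in c.per_rank:
                    taxon, support = c.per_rank[rank]
                    row += [taxon, f"{support:.6f}"]
                else:
                    row += ["-", "-"]
            writer.writerow(row)


def read_classifications_tsv(path: str | Path) -> List[ReadClassification]:
    out: List[ReadClassification] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader, None)
        for row in reader:
            if not row:
                continue
            per_rank: Dict[str, Tuple[str, float]] = {}
            for i, rank in enumerate(CANONICAL_RANKS):
                taxon = row[3 + 2 * i]
                if taxon != "-":
                    per_rank[rank] = (taxon, float(row[4 + 2 * i]))
            out.append(
                ReadClassification(
                    read_id=row[0], gene=row[1], per_rank=per_rank, lowest_rank=row[2]
                )
            )
    return out
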