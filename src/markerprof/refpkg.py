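"""Reference package: taxonomy + per-marker-gene alignments and trees.

A reference package is the precomputed context every pipeline stage reads:
a taxonomy, and for each marker gene an aligned FASTA, an edge-numbered
newick tree, and a leaf-to-taxon map.  On disk::

    <root>/
        taxonomy.tsv          tax_id  parent_id  rank  name   (header row)
        genes/<name>/alignment.fasta
        genes/<name>/tree.nwk
        genes/<name>/leaf_taxa.tsv    leaf_id  tax_id         (header row)

The root node's parent_id is written as the empty string.  Also provided is
the per-genus subsampling procedure used to build reduced ("small")
reference packages by keeping 1-3 genomes per genus.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .taxonomy import CANONICAL_RANKS, Taxonomy, TaxonomyError, TaxonomyNode
from .tree import EdgeNumberedTree

TAXONOMY_FILE = "taxonomy.tsv"
GENES_DIR = "genes"
ALIGNMENT_FILE = "alignment.fasta"
TREE_FILE = "tree.nwk"
LEAF_TAXA_FILE = "leaf_taxa.tsv"


class RefPkgError(ValueError):
    """Raised for missing files or invariant violations in a package."""


@dataclass
class MarkerGene:
    """One marker gene: aligned sequences, taxon-labeled tree, leaf map."""

    name: str
    msa: Dict[str, str]           # leaf id -> aligned sequence (gap "-")
    tree: EdgeNumberedTree
    leaf_taxa: Dict[str, str]     # leaf id -> tax_id

    def validate(self, taxonomy: Taxonomy) -> None:
        lengths = {len(s) for s in self.msa.values()}
        if len(lengths) > 1:
            raise RefPkgError(
                f"gene {self.name!r}: MSA rows have unequal lengths {sorted(lengths)}"
            )
        for leaf in self.tree.leaf_labels():
            if leaf not in self.msa:
                raise RefPkgError(
                    f"gene {self.name!r}: tree leaf {leaf!r} has no MSA row"
                )
            if leaf not in self.leaf_taxa:
                raise RefPkgError(
                    f"gene {self.name!r}: tree leaf {leaf!r} has no tax_id"
                )
            if self.leaf_taxa[leaf] not in taxonomy:
                raise RefPkgError(
                    f"gene {self.name!r}: leaf {leaf!r} maps to unknown "
                    f"tax_id {self.leaf_taxa[leaf]!r}"
                )

    def degapped(self, leaf: str) -> str:
        return self.msa[leaf].replace("-", "")


@dataclass
class ReferencePackage:
    """Taxonomy plus marker genes; ranks are the seven canonical ranks."""

    taxonomy: Taxonomy
    genes: Dict[str, MarkerGene]
    ranks: tuple = CANONICAL_RANKS

    def validate(self) -> None:
        if tuple(self.ranks) != CANONICAL_RANKS:
            raise RefPkgError("ranks must be the seven canonical ranks")
        for name, gene in self.genes.items():
            if name != gene.name:
                raise RefPkgError(f"gene key {name!r} != gene name {gene.name!r}")
            gene.validate(self.taxonomy)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferencePackage):
            return NotImplemented
        if self.taxonomy != other.taxonomy or set(self.genes) != set(other.genes):
            return False
        for name, gene in self.genes.items():
            o = other.genes[name]
            if (
                gene.msa != o.msa
                or gene.leaf_taxa != o.leaf_taxa
                or gene.tree.to_newick() != o.tree.to_newick()
            ):
                return False
        return True


# -- I/O ---------------------------------------------------------------


def load_refpkg(root_path: str | Path) -> ReferencePackage:
    """Load and validate a reference package directory."""
    root = Path(root_path)
    tax_path = root / TAXONOMY_FILE
    if not tax_path.is_file():
        raise RefPkgError(f"missing taxonomy file: {tax_path}")
    try:
        taxonomy = _read_taxonomy_tsv(tax_path)
    except TaxonomyError as exc:
        raise RefPkgError(f"invalid taxonomy in {tax_path}: {exc}") from exc
    genes_dir = root / GENES_DIR
    if not genes_dir.is_dir():
        raise RefPkgError(f"missing genes directory: {genes_dir}")
    genes: Dict[str, MarkerGene] = {}
    for gene_dir in sorted(p for p in genes_dir.iterdir() if p.is_dir()):
        name = gene_dir.name
        for fname in (ALIGNMENT_FILE, TREE_FILE, LEAF_TAXA_FILE):
            if not (gene_dir / fname).is_file():
                raise RefPkgError(f"gene {name!r}: missing file {gene_dir / fname}")
        msa = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(gene_dir / ALIGNMENT_FILE), "fasta")
        }
        tree = EdgeNumberedTree.from_newick(
            (gene_dir / TREE_FILE).read_text().strip()
        )
        leaf_taxa = _read_two_column_tsv(gene_dir / LEAF_TAXA_FILE)
        genes[name] = MarkerGene(name=name, msa=msa, tree=tree, leaf_taxa=leaf_taxa)
    pkg = ReferencePackage(taxonomy=taxonomy, genes=genes)
    pkg.validate()
    return pkg


def save_refpkg(pkg: ReferencePackage, root_path: str | Path) -> None:
    """Write a package so that :func:`load_refpkg` reproduces it exactly."""
    pkg.validate()
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    _write_taxonomy_tsv(pkg.taxonomy, root / TAXONOMY_FILE)
    for name, gene in pkg.genes.items():
        gene_dir = root / GENES_DIR / name
        gene_dir.mkdir(parents=True, exist_ok=True)
        records = [
            SeqRecord(Seq(seq), id=leaf, description="")
            for leaf, seq in sorted(gene.msa.items())
        ]
        SeqIO.write(records, str(gene_dir / ALIGNMENT_FILE), "fasta")
        (gene_dir / TREE_FILE).write_text(gene.tree.to_newick() + "\n")
        with open(gene_dir / LEAF_TAXA_FILE, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["leaf_id", "tax_id"])
            for leaf, tax_id in sorted(gene.leaf_taxa.items()):
                writer.writerow([leaf, tax_id])


def _read_taxonomy_tsv(path: Path) -> Taxonomy:
    nodes: List[TaxonomyNode] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:4]] != [
            "tax_id",
            "parent_id",
            "rank",
            "name",
        ]:
            raise RefPkgError(
                f"{path}: expected header 'tax_id\\tparent_id\\trank\\tname'"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                raise RefPkgError(f"{path}:{lineno}: expected 4 columns, got {len(row)}")
            tax_id, parent_id, rank, name = (c.strip() for c in row)
            nodes.append(
                TaxonomyNode(
                    tax_id=tax_id,
                    parent_id=parent_id or None,
                    rank=rank,
                    name=name,
                )
            )
    return Taxonomy(nodes)


def _write_taxonomy_tsv(taxonomy: Taxonomy, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["tax_id", "parent_id", "rank", "name"])
        for tax_id in sorted(taxonomy.nodes):
            node = taxonomy.nodes[tax_id]
            writer.writerow([node.tax_id, node.parent_id or "", node.rank, node.name])


def _read_two_column_tsv(path: Path) -> Dict[str, str]:
    out: Dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader, None)  # header
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 2:
                raise RefPkgError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
            out[row[0].strip()] = row[1].strip()
    return out


# -- subsampling -------------------------------------------------------


def subsample_per_genus(
    pkg: ReferencePackage,
    min_per_genus: int,
    max_per_genus: int,
    seed: int,
) -> ReferencePackage:
    """Build a reduced package keeping ``min..max`` leaves per genus.

    For every genus present in a gene's tree a uniform-random subset of its
    leaves (size drawn uniformly in ``[min_per_genus, max_per_genus]``,
    capped at the number available) is retained; trees are pruned with
    branch lengths of suppressed degree-2 nodes summed, and MSAs and leaf
    maps restricted accordingly.  Leaves whose taxon has no genus ancestor
    are always retained.  Deterministic given ``seed``.
    """
    if min_per_genus < 1:
        raise ValueError("min_per_genus must be >= 1")
    if max_per_genus < min_per_genus:
        raise ValueError("max_per_genus must be >= min_per_genus")
    rng = np.random.default_rng(seed)
    new_genes: Dict[str, MarkerGene] = {}
    for name in sorted(pkg.genes):
        gene = pkg.genes[name]
        by_genus: Dict[Optional[str], List[str]] = {}
        for leaf in sorted(gene.tree.leaf_labels()):
            genus = pkg.taxonomy.ancestor_at(gene.leaf_taxa[leaf], "genus")
            by_genus.setdefault(genus, []).append(leaf)
        keep: List[str] = []
        for genus in sorted(by_genus, key=lambda g: (g is None, g)):
            leaves = by_genus[genus]
            if genus is None:
                keep.extend(leaves)
                continue
            k = int(rng.integers(min_per_genus, max_per_genus + 1))
            k = min(k, len(leaves))
            chosen = rng.choice(len(leaves), size=k, replace=False)
            keep.extend(leaves[i] for i in sorted(chosen))
        new_tree = gene.tree.prune_to(keep)
        new_genes[name] = MarkerGene(
            name=name,
            msa={leaf: gene.msa[leaf] for leaf in keep},
            tree=new_tree,
            leaf_taxa={leaf: gene.leaf_taxa[leaf] for leaf in keep},
        )
    out = ReferencePackage(taxonomy=pkg.taxonomy, genes=new_genes)
    out.validate()
    return out
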