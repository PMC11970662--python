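"""Shared fixtures: hand-built micro taxonomy/tree and synthetic packages."""

import pytest

from markerprof import (
    EdgeNumberedTree,
    Taxonomy,
    TaxonomyNode,
    gen_refpkg,
    gen_taxonomy,
)


@pytest.fixture(scope="session")
def micro_taxonomy() -> Taxonomy:
    """Three species in two genera, full 7-rank lineages, hand-written."""
    nodes = [
        TaxonomyNode("root", None, "no rank", "root"),
        TaxonomyNode("sk1", "root", "superkingdom", "Bacteria-like"),
        TaxonomyNode("p1", "sk1", "phylum", "Phylum 1"),
        TaxonomyNode("c1", "p1", "class", "Class 1"),
        TaxonomyNode("o1", "c1", "order", "Order 1"),
        TaxonomyNode("f1", "o1", "family", "Family 1"),
        TaxonomyNode("g1", "f1", "genus", "Genus 1"),
        TaxonomyNode("g2", "f1", "genus", "Genus 2"),
        TaxonomyNode("sA", "g1", "species", "Species A"),
        TaxonomyNode("sB", "g1", "species", "Species B"),
        TaxonomyNode("sC", "g2", "species", "Species C"),
    ]
    return Taxonomy(nodes)


@pytest.fixture(scope="session")
def micro_tree() -> EdgeNumberedTree:
    """((A,B),C) with numbered edges; A/B congeneric, C in a second genus."""
    return EdgeNumberedTree.from_newick(
        "((A:0.1{1},B:0.1{2}):0.1{0},C:0.3{3});"
    )


@pytest.fixture(scope="session")
def micro_leaf_taxa() -> dict:
    return {"A": "sA", "B": "sB", "C": "sC"}


@pytest.fixture(scope="session")
def small_taxonomy() -> Taxonomy:
    return gen_taxonomy(8)


@pytest.fixture(scope="session")
def small_refpkg(small_taxonomy):
    return gen_refpkg(small_taxonomy, n_genes=2, gene_length=200, seed=1)
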