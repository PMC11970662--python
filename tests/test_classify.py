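"""Support-threshold classification: edge lineages, mass sums, descent."""

import math

import pytest

from markerprof import (
    PlacementEntry,
    PlacementRecord,
    PlacementSet,
    classify_all,
    classify_read,
    edge_lineage_map,
    support_by_rank,
)
from markerprof.taxonomy import CANONICAL_RANKS


@pytest.fixture(scope="module")
def micro_lineages(micro_tree, micro_leaf_taxa, micro_taxonomy):
    return edge_lineage_map(micro_tree, micro_leaf_taxa, micro_taxonomy)


def _record(*pairs):
    return PlacementRecord(
        "r", [PlacementEntry(edge_num=e, lwr=w) for e, w in pairs]
    )


class TestEdgeLineage:
    def test_pendant_edge_carries_full_lineage(self, micro_lineages, micro_taxonomy):
        labels = micro_lineages[1].labels  # pendant edge of leaf A
        assert labels == micro_taxonomy.lineage("sA")

    def test_two_congeneric_species_undefine_species_only(self, micro_lineages):
        labels = micro_lineages[0].labels  # clade {A, B}
        assert labels["species"] is None
        assert labels["genus"] == "g1"
        for rank in CANONICAL_RANKS[:5]:
            assert labels[rank] is not None

    def test_labels_match_bruteforce_over_leaf_lineages(
        self, micro_tree, micro_leaf_taxa, micro_taxonomy, micro_lineages
    ):
        for edge_num in micro_tree.edge_numbers():
            clade = micro_tree.clade_leaves(edge_num)
            for rank in CANONICAL_RANKS:
                values = {
                    micro_taxonomy.lineage(micro_leaf_taxa[l])[rank] for l in clade
                }
                expect = values.pop() if len(values) == 1 else None
                assert micro_lineages[edge_num].labels[rank] == expect

    def test_leaf_without_taxon_rejected(self, micro_tree, micro_taxonomy):
        with pytest.raises(ValueError, match="no tax_id"):
            edge_lineage_map(micro_tree, {"A": "sA"}, micro_taxonomy)


class TestSupportByRank:
    def test_worked_support_pattern(self, micro_lineages):
        # 0.80 on species A's pendant, 0.18 on sibling B (same genus),
        # 0.02 on the other genus
        rec = _record((1, 0.80), (2, 0.18), (3, 0.02))
        supports = support_by_rank(rec, micro_lineages)
        assert supports["species"].masses == pytest.approx(
            {"sA": 0.80, "sB": 0.18, "sC": 0.02}
        )
        assert supports["genus"].masses == pytest.approx({"g1": 0.98, "g2": 0.02})
        assert supports["species"].top_taxon == "sA"
        assert supports["genus"].top_taxon == "g1"
        assert supports["genus"].support == pytest.approx(0.98)

    def test_all_mass_on_one_leaf_gives_full_support_everywhere(
        self, micro_lineages, micro_taxonomy
    ):
        supports = support_by_rank(_record((3, 1.0)), micro_lineages)
        lineage = micro_taxonomy.lineage("sC")
        for rank in CANONICAL_RANKS:
            assert supports[rank].top_taxon == lineage[rank]
            assert supports[rank].support == pytest.approx(1.0)

    def test_undefined_mass_counts_toward_no_taxon(self, micro_lineages):
        # all mass on the {A,B} edge: species masses empty, genus mass 1.0
        supports = support_by_rank(_record((0, 1.0)), micro_lineages)
        assert supports["species"].masses == {}
        assert supports["species"].top_taxon is None
        assert supports["genus"].masses == pytest.approx({"g1": 1.0})

    def test_mass_conservation_per_rank(self, micro_lineages):
        rec = _record((0, 0.3), (1, 0.4), (3, 0.3))
        supports = support_by_rank(rec, micro_lineages)
        for rank in CANONICAL_RANKS:
            defined = sum(supports[rank].masses.values())
            assert defined <= rec.total_mass + 1e-9

    def test_support_monotone_along_chosen_lineage(self, micro_lineages):
        rec = _record((1, 0.5), (2, 0.3), (3, 0.2))
        supports = support_by_rank(rec, micro_lineages)
        prev = 1.0 + 1e-9
        for rank in CANONICAL_RANKS:
            if supports[rank].top_taxon is None:
                break
            assert supports[rank].support <= prev + 1e-9
            prev = supports[rank].support


class TestClassifyRead:
    def test_high_genus_low_species_classifies_to_genus(self, micro_lineages):
        # supports: species 0.80, genus 0.98 — threshold 0.95 keeps genus
        # and everything above it, but not species
        rec = _record((1, 0.80), (2, 0.18), (3, 0.02))
        cls = classify_read(rec, micro_lineages, threshold=0.95)
        assert cls.lowest_rank == "genus"
        assert "species" not in cls.per_rank
        assert cls.per_rank["genus"][0] == "g1"
        for rank in CANONICAL_RANKS[:6]:
            assert rank in cls.per_rank

    def test_same_read_at_090_reaches_species(self, micro_lineages):
        rec = _record((1, 0.80), (2, 0.18), (3, 0.02))
        cls90 = classify_read(rec, micro_lineages, threshold=0.90)
        assert cls90.lowest_rank == "genus"  # species support 0.80 < 0.90
        rec2 = _record((1, 0.92), (2, 0.06), (3, 0.02))
        cls = classify_read(rec2, micro_lineages, threshold=0.90)
        assert cls.lowest_rank == "species"
        assert cls.per_rank["species"][0] == "sA"

    def test_full_support_classifies_all_ranks(self, micro_lineages):
        cls = classify_read(_record((1, 1.0)), micro_lineages, threshold=0.90)
        assert cls.lowest_rank == "species"
        assert set(cls.per_rank) == set(CANONICAL_RANKS)

    def test_low_superkingdom_support_is_unclassified(self, micro_lineages):
        # half the mass off the tree entirely (sum < 1 is allowed)
        cls = classify_read(_record((1, 0.5)), micro_lineages, threshold=0.90)
        assert cls.lowest_rank == "unclassified"
        assert cls.per_rank == {}

    def test_threshold_exactly_met_classifies(self, micro_lineages):
        rec = _record((1, 0.95), (3, 0.05))
        cls = classify_read(rec, micro_lineages, threshold=0.95)
        assert cls.per_rank["species"] == (("sA"), pytest.approx(0.95))

    def test_classified_ranks_are_contiguous_prefix(self, micro_lineages):
        for rec in [
            _record((0, 0.96), (3, 0.04)),
            _record((1, 0.6), (2, 0.35), (3, 0.05)),
            _record((1, 0.99), (3, 0.01)),
        ]:
            cls = classify_read(rec, micro_lineages, threshold=0.9)
            seen_gap = False
            for rank in CANONICAL_RANKS:
                if rank in cls.per_rank:
                    assert not seen_gap
                else:
                    seen_gap = True

    def test_labels_form_single_lineage(self, micro_lineages, micro_taxonomy):
        rec = _record((1, 0.97), (2, 0.02), (3, 0.01))
        cls = classify_read(rec, micro_lineages, threshold=0.9)
        deepest = cls.per_rank[cls.lowest_rank][0]
        lineage = micro_taxonomy.lineage(deepest)
        for rank, (taxon, _s) in cls.per_rank.items():
            assert lineage[rank] == taxon

    def test_invalid_threshold_rejected(self, micro_lineages):
        with pytest.raises(ValueError):
            classify_read(_record((1, 1.0)), micro_lineages, threshold=0.0)


class TestClassifyAll:
    def test_empty_placement_set(self, micro_tree, small_refpkg, micro_taxonomy,
                                 micro_leaf_taxa):
        from markerprof import MarkerGene

        gene = MarkerGene(
            name="g",
            msa={l: "ACGT" for l in micro_tree.leaf_labels()},
            tree=micro_tree,
            leaf_taxa=dict(micro_leaf_taxa),
        )
        pset = PlacementSet(tree=micro_tree, records=[])
        assert classify_all(pset, gene, micro_taxonomy) == []

    def test_batch_equals_per_read(self, micro_tree, micro_leaf_taxa, micro_taxonomy):
        from markerprof import MarkerGene

        gene = MarkerGene(
            name="g",
            msa={l: "ACGT" for l in micro_tree.leaf_labels()},
            tree=micro_tree,
            leaf_taxa=dict(micro_leaf_taxa),
        )
        records = [
            PlacementRecord("x", [PlacementEntry(1, 0.9), PlacementEntry(2, 0.1)]),
            PlacementRecord("y", [PlacementEntry(0, 1.0)]),
        ]
        pset = PlacementSet(tree=micro_tree, records=records)
        batch = classify_all(pset, gene, micro_taxonomy, threshold=0.9)
        lineages = edge_lineage_map(micro_tree, gene.leaf_taxa, micro_taxonomy)
        for got, rec in zip(batch, records):
            solo = classify_read(rec, lineages, threshold=0.9, gene="g")
            assert got == solo
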