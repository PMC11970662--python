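"""jplace I/O and the naive similarity placer."""

import json
import math
import random

import pytest

from markerprof import (
    MarkerGene,
    PlacementEntry,
    PlacementRecord,
    PlacementSet,
    naive_place,
    naive_place_all,
    read_jplace,
    write_jplace,
)
from markerprof.placement import JplaceError
from markerprof.tree import EdgeNumberedTree

MICRO_TREE = "((A:0.1{1},B:0.1{2}):0.1{0},C:0.3{3});"


def _doc(fields, rows, tree=MICRO_TREE, name="read1"):
    return {
        "version": 3,
        "tree": tree,
        "fields": fields,
        "placements": [{"p": rows, "n": [name]}],
    }


class TestJplaceRead:
    def test_minimal_document(self, tmp_path):
        p = tmp_path / "m.jplace"
        p.write_text(json.dumps(_doc(["edge_num", "like_weight_ratio"], [[1, 1.0]])))
        pset = read_jplace(p)
        assert len(pset.records) == 1
        (rec,) = pset.records
        assert rec.read_id == "read1"
        assert rec.entries == [PlacementEntry(edge_num=1, lwr=1.0)]

    def test_field_order_honored_by_name(self, tmp_path):
        rows_a = [[1, 0.7, 0.01, 0.02], [3, 0.3, 0.03, 0.04]]
        a = tmp_path / "a.jplace"
        a.write_text(
            json.dumps(
                _doc(
                    ["edge_num", "like_weight_ratio", "pendant_length", "distal_length"],
                    rows_a,
                )
            )
        )
        # same content, fields permuted
        rows_b = [[0.01, 1, 0.02, 0.7], [0.03, 3, 0.04, 0.3]]
        b = tmp_path / "b.jplace"
        b.write_text(
            json.dumps(
                _doc(
                    ["pendant_length", "edge_num", "distal_length", "like_weight_ratio"],
                    rows_b,
                )
            )
        )
        pa, pb = read_jplace(a), read_jplace(b)
        assert pa.records == pb.records

    def test_entries_sorted_by_decreasing_lwr(self, tmp_path):
        p = tmp_path / "m.jplace"
        p.write_text(
            json.dumps(
                _doc(["edge_num", "like_weight_ratio"], [[1, 0.2], [3, 0.5], [2, 0.3]])
            )
        )
        (rec,) = read_jplace(p).records
        assert [e.lwr for e in rec.entries] == [0.5, 0.3, 0.2]

    def test_unknown_edge_rejected(self, tmp_path):
        p = tmp_path / "m.jplace"
        p.write_text(
            json.dumps(_doc(["edge_num", "like_weight_ratio"], [[999, 1.0]]))
        )
        with pytest.raises(JplaceError, match="999"):
            read_jplace(p)

    def test_negative_lwr_rejected(self, tmp_path):
        p = tmp_path / "m.jplace"
        p.write_text(
            json.dumps(_doc(["edge_num", "like_weight_ratio"], [[1, -0.1]]))
        )
        with pytest.raises(JplaceError, match="negative"):
            read_jplace(p)

    def test_mass_above_one_rejected_not_renormalized(self, tmp_path):
        p = tmp_path / "m.jplace"
        p.write_text(
            json.dumps(
                _doc(["edge_num", "like_weight_ratio"], [[1, 0.8], [2, 0.4]])
            )
        )
        with pytest.raises(JplaceError, match="exceeds 1"):
            read_jplace(p)

    @pytest.mark.parametrize("missing", ["tree", "placements", "fields", "version"])
    def test_missing_mandatory_key(self, tmp_path, missing):
        doc = _doc(["edge_num", "like_weight_ratio"], [[1, 1.0]])
        del doc[missing]
        p = tmp_path / "m.jplace"
        p.write_text(json.dumps(doc))
        with pytest.raises(JplaceError, match=missing):
            read_jplace(p)

    def test_edge_number_field_name_accepted(self, tmp_path):
        p = tmp_path / "m.jplace"
        p.write_text(
            json.dumps(_doc(["edge_number", "like_weight_ratio"], [[1, 1.0]]))
        )
        assert read_jplace(p).records[0].entries[0].edge_num == 1

    def test_bare_edge_tag_without_length(self, tmp_path):
        tree = "((A{1},B{2}){0},C{3});"
        p = tmp_path / "m.jplace"
        p.write_text(json.dumps(_doc(["edge_num", "like_weight_ratio"], [[1, 1.0]], tree=tree)))
        pset = read_jplace(p)
        assert pset.tree.branch_length(1) == 0.0


class TestJplaceRoundTrip:
    def _pset(self):
        tree = EdgeNumberedTree.from_newick(MICRO_TREE)
        records = [
            PlacementRecord(
                "readA",
                [
                    PlacementEntry(1, 0.723456789123, 0.01, 0.002),
                    PlacementEntry(3, 0.276543210877, 0.05, 0.001),
                ],
            ),
            PlacementRecord("readB", [PlacementEntry(2, 1.0, 0.0, 0.0)]),
        ]
        return PlacementSet(tree=tree, records=records)

    def test_round_trip_identity(self, tmp_path):
        pset = self._pset()
        write_jplace(pset, tmp_path / "p.jplace")
        again = read_jplace(tmp_path / "p.jplace")
        assert again.records == pset.records
        assert again.tree.to_newick() == pset.tree.to_newick()

    def test_lwr_preserved_to_nine_digits(self, tmp_path):
        pset = self._pset()
        write_jplace(pset, tmp_path / "p.jplace")
        again = read_jplace(tmp_path / "p.jplace")
        for rec, orig in zip(again.records, pset.records):
            for e, o in zip(rec.entries, orig.entries):
                assert abs(e.lwr - o.lwr) < 1e-9

    def test_emitted_document_has_v3_keys(self, tmp_path):
        write_jplace(self._pset(), tmp_path / "p.jplace")
        doc = json.loads((tmp_path / "p.jplace").read_text())
        assert set(doc) >= {"version", "tree", "fields", "placements"}
        assert doc["version"] == 3


def _gene_from_msa(msa: dict) -> MarkerGene:
    labels = sorted(msa)
    newick = "(" + ",".join(f"{l}:0.1{{{i}}}" for i, l in enumerate(labels)) + ");"
    return MarkerGene(
        name="g",
        msa=msa,
        tree=EdgeNumberedTree.from_newick(newick),
        leaf_taxa={l: "s" for l in labels},
    )


class TestNaivePlace:
    def test_unique_substring_gets_full_mass(self):
        gene = _gene_from_msa(
            {"A": "ACGTACGTAAACCCGGGTTT", "B": "TTTTTTTTTTTTTTTTTTTT"}
        )
        rec = naive_place("ACGTAAACCC", gene)
        assert len(rec.entries) == 1
        assert rec.entries[0].edge_num == gene.tree.pendant_edge_num("A")
        assert rec.entries[0].lwr == 1.0

    def test_two_way_tie_splits_mass_and_matches_bruteforce(self):
        msa = {"A": "ACGTACGTAC", "B": "ACGTACGTAC", "C": "GGGGGGGGGG"}
        gene = _gene_from_msa(msa)
        query = "ACGTAC"
        rec = naive_place(query, gene)
        # brute-force scoring over all leaves and offsets
        def score(seq):
            best = 0
            for off in range(len(seq) - len(query) + 1):
                best = max(
                    best,
                    sum(a == b for a, b in zip(query, seq[off : off + len(query)])),
                )
            return best

        scores = {l: score(s) for l, s in msa.items()}
        top = max(scores.values())
        tied = {l for l, s in scores.items() if s == top}
        assert tied == {"A", "B"}
        assert {e.edge_num for e in rec.entries} == {
            gene.tree.pendant_edge_num(l) for l in tied
        }
        assert all(e.lwr == pytest.approx(0.5) for e in rec.entries)

    def test_all_n_query_ties_every_leaf(self):
        msa = {"A": "ACGTACGTAC", "B": "TACGTACGTA", "C": "GGTTGGTTGG"}
        gene = _gene_from_msa(msa)
        rec = naive_place("NNNNN", gene)
        assert len(rec.entries) == 3
        assert all(e.lwr == pytest.approx(1 / 3) for e in rec.entries)

    def test_mass_sums_to_one(self):
        rng = random.Random(4)
        bases = "ACGT"
        msa = {
            f"L{i}": "".join(rng.choice(bases) for _ in range(40)) for i in range(7)
        }
        gene = _gene_from_msa(msa)
        for _ in range(20):
            q = "".join(rng.choice(bases) for _ in range(15))
            rec = naive_place(q, gene)
            assert math.isclose(rec.total_mass, 1.0, abs_tol=1e-9)

    def test_leaf_order_invariance(self):
        rng = random.Random(9)
        bases = "ACGT"
        seqs = ["".join(rng.choice(bases) for _ in range(30)) for _ in range(5)]
        msa1 = {f"L{i}": s for i, s in enumerate(seqs)}
        gene1 = _gene_from_msa(msa1)
        gene2 = _gene_from_msa(dict(reversed(list(msa1.items()))))
        q = seqs[2][5:20]
        r1, r2 = naive_place(q, gene1), naive_place(q, gene2)
        lwr1 = {e.edge_num: e.lwr for e in r1.entries}
        lwr2 = {e.edge_num: e.lwr for e in r2.entries}
        # map edge numbers back to leaves for comparison
        by_leaf1 = {l: lwr1.get(gene1.tree.pendant_edge_num(l), 0.0) for l in msa1}
        by_leaf2 = {l: lwr2.get(gene2.tree.pendant_edge_num(l), 0.0) for l in msa1}
        assert by_leaf1 == by_leaf2

    def test_empty_msa_rejected(self):
        gene = _gene_from_msa({"A": "ACGT"})
        gene.msa = {}
        with pytest.raises(ValueError, match="empty"):
            naive_place("ACGT", gene)

    def test_batch_matches_single(self):
        msa = {"A": "ACGTACGTACGTACGT", "B": "TTGGCCAATTGGCCAA"}
        gene = _gene_from_msa(msa)
        queries = {"q1": "ACGTACGT", "q2": "TTGGCCAA"}
        pset = naive_place_all(queries, gene)
        for rec in pset.records:
            solo = naive_place(queries[rec.read_id], gene, read_id=rec.read_id)
            assert rec == solo
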