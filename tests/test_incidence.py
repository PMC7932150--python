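import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zooregion.incidence import (
    OGU,
    AdjacencyGraph,
    IncidenceMatrix,
    QdsCell,
    QdsOccupancy,
    SpeciesRecord,
    TaxonLedger,
    apply_taxon_ledger,
    prune_matrix,
    read_incidence,
    score_presence,
    write_incidence,
)


class TestReadIncidence:
    def test_toy_read_back(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("species,A,B\nsp1,1,0\nsp2,0,1\nsp3,1,1\n")
        m = read_incidence(p)
        assert m.species_ids == ["sp1", "sp2", "sp3"]
        assert m.ogu_ids == ["A", "B"]
        assert list(m.range_sizes()) == [1, 1, 2]

    def test_tab_delimited_sniffed(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("species\tA\tB\nsp1\t1\t0\n")
        m = read_incidence(p)
        assert m.cells.tolist() == [[1, 0]]

    def test_duplicate_ogu_header_names_duplicate(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("species,NCB,NCB\nsp1,1,0\n")
        with pytest.raises(ValueError, match="NCB"):
            read_incidence(p)

    def test_duplicate_species_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("species,A,B\nsp1,1,0\nsp1,0,1\n")
        with pytest.raises(ValueError, match="sp1"):
            read_incidence(p)

    def test_non_binary_cell_addressed(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("species,A,B\nsp1,1,2\n")
        with pytest.raises(ValueError, match="line 2.*'B'"):
            read_incidence(p)

    def test_round_trip_bit_identical(self, tmp_path, five_ogu_matrix):
        p = tmp_path / "m.csv"
        write_incidence(five_ogu_matrix, p)
        m2 = read_incidence(p)
        assert m2 == five_ogu_matrix
        p2 = tmp_path / "m2.csv"
        write_incidence(m2, p2)
        assert p.read_text() == p2.read_text()


class TestRegistryValidation:
    def test_excluded_species_rejected_in_matrix(self):
        sp = SpeciesRecord("x", status_flags=frozenset({"excluded"}))
        with pytest.raises(ValueError, match="excluded"):
            IncidenceMatrix([sp], ["A"], np.array([[1]]))

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            OGU("A", area=-1.0)

    def test_unknown_status_flag_rejected(self):
        with pytest.raises(ValueError):
            SpeciesRecord("x", status_flags=frozenset({"bogus"}))


class TestAdjacencyGraph:
    def test_edge_endpoint_validation(self):
        with pytest.raises(ValueError, match="unregistered"):
            AdjacencyGraph(["A", "B"], [("A", "Z")])

    def test_no_self_loops(self):
        with pytest.raises(ValueError, match="self-loop"):
            AdjacencyGraph(["A"], [("A", "A")])

    def test_edge_list_round_trip(self, tmp_path, path_graph):
        p = tmp_path / "adj.csv"
        path_graph.write_edge_list(p)
        g2 = AdjacencyGraph.read_edge_list(p)
        assert g2 == path_graph

    def test_cap_neighbors(self):
        g = AdjacencyGraph(["A", "B", "C", "D"],
                           [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C")])
        capped = g.cap_neighbors(1)
        # every kept edge is top-1 for at least one endpoint
        assert ("A", "B") in capped.edges
        assert len(capped.edges) <= 3


def _occ(total=50):
    occ = QdsOccupancy({"X": total, "Y": total})
    return occ


class TestScorePresence:
    def test_single_interior_qds_present(self):
        occ = _occ()
        occ.add("s", "X", QdsCell("q1", "interior", "inland"))
        assert score_presence(occ, "s", "X") is True

    def test_marginal_above_threshold_present(self):
        occ = _occ(50)
        for i in range(6):  # 12% of 50
            occ.add("s", "X", QdsCell(f"q{i}", "marginal", "inland", "Y"))
        assert score_presence(occ, "s", "X", {"Y": True}) is True

    def test_marginal_low_coverage_neighbour_present_absent(self):
        occ = _occ(50)
        for i in range(2):  # 4%
            occ.add("s", "X", QdsCell(f"q{i}", "marginal", "inland", "Y"))
        assert score_presence(occ, "s", "X", {"Y": True}) is False

    def test_marginal_low_coverage_neighbour_absent_present(self):
        occ = _occ(50)
        occ.add("s", "X", QdsCell("q0", "marginal", "inland", "Y"))
        assert score_presence(occ, "s", "X", {"Y": False}) is True

    def test_coastal_margin_rescue(self):
        occ = _occ(50)
        for i in range(2):
            occ.add("s", "X", QdsCell(f"q{i}", "marginal", "coastal", "Y"))
        assert score_presence(occ, "s", "X", {"Y": True}) is True

    def test_threshold_is_strict(self):
        occ = _occ(10)
        occ.add("s", "X", QdsCell("q0", "marginal", "inland", "Y"))
        # exactly 10% is NOT "more than 10%"
        assert score_presence(occ, "s", "X", {"Y": True}) is False

    def test_missing_neighbour_errors_when_decisive(self):
        occ = _occ(50)
        occ.add("s", "X", QdsCell("q0", "marginal", "inland", None))
        with pytest.raises(ValueError, match="adjacency"):
            score_presence(occ, "s", "X", {})

    def test_unknown_ogu_errors(self):
        with pytest.raises(KeyError):
            score_presence(_occ(), "s", "Z")

    def test_monotone_in_interior_additions(self):
        occ = _occ(50)
        occ.add("s", "X", QdsCell("q0", "marginal", "inland", "Y"))
        before = score_presence(occ, "s", "X", {"Y": False})
        occ.add("s", "X", QdsCell("q1", "interior", "inland"))
        after = score_presence(occ, "s", "X", {"Y": False})
        assert after >= before and after is True


class TestTaxonLedger:
    def test_empty_ledger_identity(self):
        reg = [SpeciesRecord("a"), SpeciesRecord("b")]
        assert apply_taxon_ledger(reg, TaxonLedger()) == reg

    def test_merge_complex_unions_ranges(self):
        reg = ["a", "b", "c"]
        m = IncidenceMatrix(reg, ["A", "B", "C"],
                            np.array([[1, 1, 0], [0, 1, 1], [1, 0, 0]]))
        ledger = TaxonLedger().merge_complex(["a", "b"], "a-b")
        out_reg, out_m = apply_taxon_ledger([SpeciesRecord(s) for s in reg], ledger, m)
        assert [s.species_id for s in out_reg] == ["a-b", "c"]
        assert out_m.range_of("a-b") == {"A", "B", "C"}
        assert "merged_complex" in out_reg[0].status_flags

    def test_synonymise_unions_into_senior(self):
        m = IncidenceMatrix(["jr", "sr"], ["A", "B"], np.array([[1, 0], [0, 1]]))
        ledger = TaxonLedger().synonymise("jr", "sr")
        out_reg, out_m = apply_taxon_ledger(m.species, ledger, m)
        assert [s.species_id for s in out_reg] == ["sr"]
        assert out_m.range_of("sr") == {"A", "B"}

    def test_presence_conserved_by_union(self):
        rng = np.random.default_rng(0)
        cells = (rng.random((4, 5)) < 0.5).astype(np.int8)
        m = IncidenceMatrix(["a", "b", "c", "d"], list("ABCDE"), cells)
        ledger = TaxonLedger().merge_complex(["a", "b"], "ab")
        _, out = apply_taxon_ledger(m.species, ledger, m)
        merged_row = out.cells[0]
        assert np.array_equal(merged_row, np.clip(cells[0] + cells[1], 0, 1))

    def test_unknown_name_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            apply_taxon_ledger([SpeciesRecord("a")], TaxonLedger().exclude("zz"))

    def test_conflicting_rules_error(self):
        ledger = TaxonLedger().exclude("a").synonymise("a", "b")
        with pytest.raises(ValueError, match="conflicting"):
            apply_taxon_ledger([SpeciesRecord("a"), SpeciesRecord("b")], ledger)


class TestPruneMatrix:
    def test_constant_species_removed(self):
        m = IncidenceMatrix(["every", "ok"], ["A", "B", "C"],
                            np.array([[1, 1, 1], [1, 1, 0]]))
        out, rep = prune_matrix(m, drop_empty_ogus=False, drop_uninformative_species=True)
        assert out.species_ids == ["ok"]
        assert ("every", "constant") in rep.dropped_species

    def test_singleton_removed_and_reported_with_ogu(self, five_ogu_matrix):
        out, rep = prune_matrix(five_ogu_matrix, True, True)
        assert "s3" not in out.species_ids
        assert rep.singleton_species == {"s3": "A"}

    def test_empty_ogu_removed(self):
        m = IncidenceMatrix(["a"], ["A", "B"], np.array([[1, 0]]))
        out, rep = prune_matrix(m, drop_empty_ogus=True, drop_uninformative_species=False)
        assert out.ogu_ids == ["A"]
        assert rep.dropped_ogus == ["B"]

    def test_idempotent(self, five_ogu_matrix):
        once, _ = prune_matrix(five_ogu_matrix, True, True)
        twice, rep = prune_matrix(once, True, True)
        assert twice == once
        assert not rep.dropped_species and not rep.dropped_ogus

    def test_prune_to_empty_warns_not_raises(self):
        m = IncidenceMatrix(["a"], ["A"], np.array([[1]]))
        out, rep = prune_matrix(m, True, True)  # constant character
        assert 0 in out.shape
        assert rep.warnings


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_prune_idempotent_property(seed):
    rng = np.random.default_rng(seed)
    cells = (rng.random((8, 6)) < 0.35).astype(np.int8)
    m = IncidenceMatrix([f"s{i}" for i in range(8)], list("ABCDEF"), cells)
    once, _ = prune_matrix(m, True, True)
    if 0 in once.shape:
        return
    twice, _ = prune_matrix(once, True, True)
    assert twice == once
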