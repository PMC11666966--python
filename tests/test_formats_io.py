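"""I/O layer: strict parsing, normalization, and deterministic exports."""

from __future__ import annotations

import random

import pytest

from netpharm import formats_io as fio
from netpharm.cdtd_network import CDTDNetwork
from netpharm.enrichment import GeneSet, GeneSetCollection
from netpharm.reference import data_path, load_compound_panel, load_hub_top10
from netpharm.synthetic_data import SynthConfig, gen_gene_sets
from netpharm.target_assembly import ScoredTargetSet, TargetSet


class TestCompoundTable:
    def test_packaged_panel_parses_to_24_records(self):
        panel = load_compound_panel()
        assert len(panel) == 24
        quercetin = next(r for r in panel if r.name == "Quercetin")
        assert (quercetin.ob, quercetin.dl, quercetin.target_count) == (46.43, 0.28, 230)

    def test_header_only_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("pubchem_id\tname\tob\tdl\n")
        assert fio.read_compound_table(p) == []

    def test_missing_mandatory_column_names_the_column(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("pubchem_id\tname\tob\n1\tx\t50\n")
        with pytest.raises(fio.FormatError, match="dl"):
            fio.read_compound_table(p)

    def test_unparseable_number_reports_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("pubchem_id\tname\tob\tdl\n1\tx\tfifty\t0.2\n")
        with pytest.raises(fio.FormatError, match=":2"):
            fio.read_compound_table(p)

    def test_duplicate_pubchem_id_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("pubchem_id\tname\tob\tdl\n1\tx\t50\t0.2\n1\ty\t40\t0.3\n")
        with pytest.raises(fio.FormatError, match="duplicate"):
            fio.read_compound_table(p)

    def test_round_trip(self, tmp_path):
        panel = load_compound_panel()
        out = tmp_path / "panel.tsv"
        fio.write_compound_table(panel, out)
        assert fio.read_compound_table(out) == panel


class TestGeneList:
    def test_normalization_and_dedup(self, tmp_path):
        p = tmp_path / "genes.txt"
        p.write_text("tp53\nTP53 \nIL6\n")
        ts = fio.read_gene_list(p)
        assert ts.genes == {"TP53", "IL6"}
        assert ts.label == "genes"

    def test_scored_duplicates_keep_maximum(self, tmp_path):
        p = tmp_path / "scored.tsv"
        p.write_text("symbol\tgifts\nA\t1.0\nA\t2.0\n")
        ts = fio.read_gene_list(p, score_column="gifts")
        assert ts.scores == {"A": 2.0}

    def test_published_mcc_hub_list_has_ten_symbols(self):
        ts = load_hub_top10("mcc")
        assert len(ts.genes) == 10
        assert {"IL6", "BCL2", "IFNG"} <= ts.genes

    def test_empty_file_warns_and_returns_empty_set(self, tmp_path):
        p = tmp_path / "nothing.txt"
        p.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            ts = fio.read_gene_list(p)
        assert len(ts.genes) == 0

    def test_non_numeric_score_is_row_error(self, tmp_path):
        p = tmp_path / "scored.tsv"
        p.write_text("symbol\tgifts\nA\thigh\n")
        with pytest.raises(fio.FormatError, match=":2"):
            fio.read_gene_list(p, score_column="gifts")

    @pytest.mark.parametrize("scored", [False, True])
    def test_round_trip(self, tmp_path, scored):
        if scored:
            ts = ScoredTargetSet("s", {"A": 1.5, "B": 0.25})
            out = tmp_path / "s.tsv"
            fio.write_gene_list(ts, out)
            back = fio.read_gene_list(out, score_column="score")
            assert back.scores == ts.scores
        else:
            ts = TargetSet("s", frozenset({"A", "B", "C"}))
            out = tmp_path / "s.txt"
            fio.write_gene_list(ts, out)
            assert fio.read_gene_list(out).genes == ts.genes


class TestEdgeTable:
    def _write(self, tmp_path, rows, header="node1\tnode2\tcombined_score"):
        p = tmp_path / "edges.tsv"
        body = "\n".join("\t".join(str(f) for f in r) for r in rows)
        p.write_text(f"{header}\n{body}\n" if rows else f"{header}\n")
        return p

    def test_integer_dialect_dedup_and_self_loop_removal(self, tmp_path):
        p = self._write(tmp_path, [("A", "B", 900), ("B", "A", 850), ("C", "C", 999)])
        edges = fio.read_edge_table(p, 0.4)
        assert [(e.node_a, e.node_b, e.score) for e in edges] == [("A", "B", 0.9)]

    def test_threshold_is_strict_below_removal(self, tmp_path):
        p = self._write(tmp_path, [("A", "B", 0.39)])
        assert fio.read_edge_table(p, 0.4) == []
        p2 = self._write(tmp_path, [("A", "B", 0.4)])
        assert len(fio.read_edge_table(p2, 0.4)) == 1  # minimum required score kept

    def test_mixed_scores_filtered_exactly(self, tmp_path):
        rng = random.Random(11)
        rows, expected = [], set()
        nodes = [f"N{i}" for i in range(10)]
        for i in range(10):
            a, b = rng.sample(nodes, 2)
            score = rng.choice([0.2, 0.8])
            rows.append((a, b, score))
            if score == 0.8:
                expected.add(frozenset((a, b)))
        p = self._write(tmp_path, rows)
        kept = {frozenset((e.node_a, e.node_b)) for e in fio.read_edge_table(p, 0.4)}
        assert kept == expected

    def test_row_order_never_matters(self, tmp_path):
        rng = random.Random(3)
        rows = [(f"A{i}", f"B{i}", rng.choice([250, 500, 0.75])) for i in range(20)]
        p1 = self._write(tmp_path, rows)
        shuffled = rows[:]
        rng.shuffle(shuffled)
        p2 = self._write(tmp_path, shuffled)
        assert fio.read_edge_table(p1, 0.4) == fio.read_edge_table(p2, 0.4)

    def test_score_outside_both_dialects_rejected(self, tmp_path):
        p = self._write(tmp_path, [("A", "B", 1500)])
        with pytest.raises(fio.FormatError, match="dialect"):
            fio.read_edge_table(p, 0.4)

    def test_fewer_than_three_columns_rejected(self, tmp_path):
        p = tmp_path / "narrow.tsv"
        p.write_text("node1\tnode2\nA\tB\n")
        with pytest.raises(fio.FormatError, match="3 columns"):
            fio.read_edge_table(p, 0.4)

    def test_round_trip(self, tmp_path):
        edges = [fio.EdgeRecord("A", "B", 0.9), fio.EdgeRecord("B", "C", 0.45)]
        out = tmp_path / "e.tsv"
        fio.write_edge_table(edges, out)
        assert fio.read_edge_table(out, 0.4) == edges


class TestGMT:
    def test_basic_term(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("T1\tdesc\tA\tB\n")
        coll = fio.read_gmt(p)
        assert len(coll) == 1 and coll.terms[0].members == {"A", "B"}

    def test_duplicate_member_counted_once(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("T1\tdesc\tA\ta\tA\n")
        assert fio.read_gmt(p).terms[0].members == {"A"}

    def test_short_line_is_error_with_line_number(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("T1\tdesc\tA\nT2\tdesc\n")
        with pytest.raises(fio.FormatError, match=":2"):
            fio.read_gmt(p)

    def test_generated_collection_round_trips(self, tmp_path):
        coll, _, _ = gen_gene_sets(SynthConfig(seed=5, n_terms=50))
        out = tmp_path / "gen.gmt"
        fio.write_gmt(coll, out)
        back = fio.read_gmt(out)
        assert len(back) == len(coll)
        assert {(t.term_id, t.members) for t in back} == {
            (t.term_id, t.members) for t in coll
        }


class TestNetworkExport:
    def _tiny_net(self):
        net = CDTDNetwork()
        net.nodes = {"drug": "drug", "c1": "compound"}
        net.edges = {("drug", "c1", "drug-compound")}
        return net

    def test_single_edge_single_sif_line(self, tmp_path):
        sif, nodes = fio.write_network_export(self._tiny_net(), tmp_path / "net")
        assert sif.read_text().splitlines() == ["drug\tdrug-compound\tc1"]

    def test_export_is_byte_identical_across_runs(self, tmp_path):
        net = self._tiny_net()
        sif1, nodes1 = fio.write_network_export(net, tmp_path / "a")
        sif2, nodes2 = fio.write_network_export(net, tmp_path / "b")
        assert sif1.read_bytes() == sif2.read_bytes()
        assert nodes1.read_bytes() == nodes2.read_bytes()

    def test_dangling_endpoint_names_the_node(self, tmp_path):
        net = self._tiny_net()
        net.edges.add(("c1", "GHOST", "compound-target"))
        with pytest.raises(fio.FormatError, match="GHOST"):
            fio.write_network_export(net, tmp_path / "net")


class TestDockingTable:
    def test_published_energies_with_unicode_minus(self):
        matrix = fio.read_docking_table(data_path("docking_best_energies.tsv"))
        assert matrix.entries[("Quercetin", "AKT1")] == [-8.7]

    def test_empty_body_gives_empty_matrix(self, tmp_path):
        p = tmp_path / "dock.tsv"
        p.write_text("compound\ttarget\tenergy\n")
        assert len(fio.read_docking_table(p)) == 0

    def test_all_poses_retained(self, tmp_path):
        p = tmp_path / "dock.tsv"
        p.write_text("compound\ttarget\tenergy\nc\tT\t-6.0\nc\tT\t-7.0\n")
        matrix = fio.read_docking_table(p)
        assert sorted(matrix.entries[("c", "T")]) == [-7.0, -6.0]

    def test_non_finite_energy_is_row_error(self, tmp_path):
        p = tmp_path / "dock.tsv"
        p.write_text("compound\ttarget\tenergy\nc\tT\tnan\n")
        with pytest.raises(fio.FormatError, match=":2"):
            fio.read_docking_table(p)
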