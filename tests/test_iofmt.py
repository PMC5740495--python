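import numpy as np
import pytest

import ntrprox as nx
from ntrprox.iofmt import DesignError, FormatError

from conftest import write_protein_groups_tsv


class TestReadProteinGroups:
    def test_reverse_rows_removed(self, tmp_path):
        path = write_protein_groups_tsv(tmp_path / "pg.tsv", [
            {"id": "P1", "intensities": [1e6, 2e6, 3e6, 4e6]},
            {"id": "REV__P2", "rev": "+", "intensities": [1e6] * 4},
            {"id": "P3", "intensities": [5e6, 6e6, 7e6, 8e6]},
        ], runs=["r1", "r2", "r3", "r4"])
        m = nx.read_protein_groups(path)
        assert m.values.shape == (2, 4)
        assert m.group_ids == ["P1", "P3"]

    def test_zero_intensity_is_missing(self, tmp_path):
        path = write_protein_groups_tsv(tmp_path / "pg.tsv", [
            {"id": "P1", "intensities": [0, 2e6, 3e6, 4e6]},
        ], runs=["r1", "r2", "r3", "r4"])
        m = nx.read_protein_groups(path)
        assert not m.observed[0, 0]
        assert np.isnan(m.values[0, 0])
        assert m.observed[0, 1:].all()

    def test_missing_designed_run_column_is_error(self, tmp_path, paper_design):
        path = write_protein_groups_tsv(tmp_path / "pg.tsv", [
            {"id": "P1", "intensities": [1e6, 2e6]},
        ], runs=["NTR01_b1_t1", "NTR01_b1_t2"])
        with pytest.raises(FormatError, match="NTR01_b2_t1"):
            nx.read_protein_groups(path, design=paper_design)

    def test_duplicate_group_ids_is_error(self, tmp_path):
        path = write_protein_groups_tsv(tmp_path / "pg.tsv", [
            {"id": "P1", "intensities": [1e6]},
            {"id": "P1", "intensities": [2e6]},
        ], runs=["r1"])
        with pytest.raises(FormatError, match="duplicate"):
            nx.read_protein_groups(path)

    def test_round_trip(self, tmp_path):
        path = write_protein_groups_tsv(tmp_path / "pg.tsv", [
            {"id": "P1", "genes": "GENA;GENB", "uniq": 3,
             "intensities": [0, 2e6, 3e6, 4e6]},
            {"id": "P2", "genes": "GENC", "uniq": 7,
             "intensities": [9e5, 0, 1e6, 2e6]},
        ], runs=["r1", "r2", "r3", "r4"])
        m = nx.read_protein_groups(path)
        nx.write_protein_groups(m, tmp_path / "out.tsv")
        m2 = nx.read_protein_groups(tmp_path / "out.tsv")
        assert m2.group_ids == m.group_ids
        assert [p.gene_names for p in m2.proteins] == \
               [p.gene_names for p in m.proteins]
        assert [p.unique_peptides for p in m2.proteins] == [3, 7]
        np.testing.assert_array_equal(m2.observed, m.observed)
        np.testing.assert_allclose(
            m2.values[m2.observed], m.values[m.observed])


class TestReadDesign:
    def test_paper_layout_counts(self, tmp_path, paper_design):
        nx.write_design(paper_design, tmp_path / "design.tsv")
        design = nx.read_design(tmp_path / "design.tsv")
        assert len(design.runs) == 256
        assert design.n_control_experiments() == 16
        assert len(design.ntr_lines) == 28
        assert len(design.control_lines) == 4

    def test_duplicate_replicate_key_is_error(self, tmp_path):
        content = (
            "run_id\tcell_line\tbait\tterminus\tbio_rep\ttech_rep\tis_control\n"
            "r1\tL1\tB1\tN\t1\t1\tFalse\n"
            "r2\tL1\tB1\tN\t1\t1\tFalse\n"
        )
        p = tmp_path / "design.tsv"
        p.write_text(content)
        with pytest.raises(DesignError, match="duplicate"):
            nx.read_design(p)

    def test_unknown_terminus_is_error(self, tmp_path):
        content = (
            "run_id\tcell_line\tbait\tterminus\tbio_rep\ttech_rep\tis_control\n"
            "r1\tL1\tB1\tQ\t1\t1\tFalse\n"
        )
        p = tmp_path / "design.tsv"
        p.write_text(content)
        with pytest.raises(DesignError, match="terminus"):
            nx.read_design(p)

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "design.tsv"
        p.write_text("")
        with pytest.raises(DesignError):
            nx.read_design(p)


class TestReadNetwork:
    def _write(self, path, rows):
        path.write_text("\n".join("\t".join(map(str, r)) for r in rows) + "\n")
        return path

    def test_threshold_filter(self, tmp_path):
        p = self._write(tmp_path / "net.tsv",
                        [("a", "b", 0.65), ("b", "c", 0.71), ("c", "d", 0.90)])
        net = nx.read_network(p, threshold=0.7)
        assert len(net.edges) == 2
        assert set(net.nodes) == {"b", "c", "d"}

    def test_string_scale_autodetect(self, tmp_path):
        p1 = self._write(tmp_path / "n1.tsv",
                         [("a", "b", 0.65), ("b", "c", 0.71), ("c", "d", 0.90)])
        p2 = self._write(tmp_path / "n2.tsv",
                         [("a", "b", 650), ("b", "c", 710), ("c", "d", 900)])
        n1 = nx.read_network(p1, threshold=0.7)
        n2 = nx.read_network(p2, threshold=0.7)
        assert [(a, b) for a, b, _ in n1.edges] == \
               [(a, b) for a, b, _ in n2.edges]
        np.testing.assert_allclose([w for *_, w in n1.edges],
                                   [w for *_, w in n2.edges])

    def test_self_loop_dropped(self, tmp_path, caplog):
        p = self._write(tmp_path / "net.tsv",
                        [("a", "a", 0.9), ("a", "b", 0.9)])
        net = nx.read_network(p, threshold=0.7)
        assert len(net.edges) == 1

    def test_negative_weight_is_error(self, tmp_path):
        p = self._write(tmp_path / "net.tsv", [("a", "b", -0.5)])
        with pytest.raises(FormatError, match="negative"):
            nx.read_network(p)

    def test_rethreshold_idempotent(self, tmp_path):
        p = self._write(tmp_path / "net.tsv",
                        [("a", "b", 0.75), ("b", "c", 0.71), ("c", "d", 0.95)])
        net1 = nx.read_network(p, threshold=0.7)
        nx.write_network(net1, tmp_path / "out.tsv")
        net2 = nx.read_network(tmp_path / "out.tsv", threshold=0.7)
        assert net1.edges == net2.edges

    def test_isolated_nodes_from_node_file(self, tmp_path):
        p = self._write(tmp_path / "net.tsv", [("a", "b", 0.9)])
        (tmp_path / "nodes.tsv").write_text("a\nb\nzzz\n")
        net = nx.read_network(p, threshold=0.7,
                              node_file=tmp_path / "nodes.tsv")
        assert "zzz" in net.nodes


class TestReadSiteTable:
    def _write(self, path, rows, runs):
        header = "protein\tposition\t" + "\t".join(runs)
        lines = [header] + ["\t".join(map(str, r)) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_basic_shape(self, tmp_path):
        p = self._write(tmp_path / "s.tsv",
                        [("P1", 10, 1e5, 2e5, 0, 4e5),
                         ("P1", 59, 1e5, 1e5, 1e5, 1e5)],
                        runs=["r1", "r2", "r3", "r4"])
        sm = nx.read_site_table(p)
        assert sm.values.shape == (2, 4)
        assert not sm.observed[0, 2]

    def test_duplicate_sites_summed(self, tmp_path):
        p = self._write(tmp_path / "s.tsv",
                        [("P1", 10, 100.0, 200.0),
                         ("P1", 10, 50.0, 0.0)],
                        runs=["r1", "r2"])
        sm = nx.read_site_table(p)
        assert len(sm.sites) == 1
        np.testing.assert_allclose(sm.values[0], [150.0, 200.0])

    def test_position_below_one_is_error(self, tmp_path):
        p = self._write(tmp_path / "s.tsv", [("P1", 0, 100.0)], runs=["r1"])
        with pytest.raises(FormatError, match="1-based"):
            nx.read_site_table(p)

    def test_site_round_trip(self, tmp_path):
        p = self._write(tmp_path / "s.tsv",
                        [("P1", 10, 1e5, 0.0), ("P2", 4, 2e5, 3e5)],
                        runs=["r1", "r2"])
        sm = nx.read_site_table(p)
        nx.write_site_table(sm, tmp_path / "out.tsv")
        sm2 = nx.read_site_table(tmp_path / "out.tsv")
        assert sm2.sites == sm.sites
        np.testing.assert_array_equal(sm2.observed, sm.observed)
        np.testing.assert_allclose(sm2.values[sm2.observed],
                                   sm.values[sm.observed])
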