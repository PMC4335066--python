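import numpy as np
import pandas as pd
import pytest

from conetdiff import (
    DesignError,
    FormatError,
    GeneAnnotation,
    collapse_by_annotation,
    exclude_probes,
    read_expression_matrix,
    write_expression_matrix,
)

from conftest import make_matrix


def write_inputs(tmp_path, matrix_text, map_text):
    mpath = tmp_path / "m.tsv"
    spath = tmp_path / "s.tsv"
    mpath.write_text(matrix_text)
    spath.write_text(map_text)
    return mpath, spath


SAMPLE_MAP_2X2 = (
    "sample_id\tcondition\tis_reference\n"
    "s1\tWT\t1\ns2\tWT\t1\ns3\tnull\t0\ns4\tnull\t0\n"
)


class TestReadWrite:
    def test_reads_dims_and_preserves_order(self, tmp_path):
        text = "gene\ts1\ts2\ts3\ts4\ngB\t1\t2\t3\t4\ngA\t5\t6\t7\t8\ngC\t9\t1\t2\t3\n"
        m, s = write_inputs(tmp_path, text, SAMPLE_MAP_2X2)
        em = read_expression_matrix(m, s)
        assert em.gene_ids == ["gB", "gA", "gC"]
        assert em.sample_ids == ["s1", "s2", "s3", "s4"]
        assert em.values.shape == (3, 4)
        assert em.conditions == ("WT", "null")

    def test_round_trip_is_identity(self, tmp_path):
        rng = np.random.default_rng(3)
        em = make_matrix(rng.normal(8, 2, (5, 6)))
        write_expression_matrix(em, tmp_path / "m.tsv", tmp_path / "s.tsv")
        back = read_expression_matrix(tmp_path / "m.tsv", tmp_path / "s.tsv")
        assert back.gene_ids == em.gene_ids
        assert back.reference == em.reference
        # 10 significant digits survive the text round trip
        np.testing.assert_allclose(back.values, em.values, rtol=1e-9)
        # writing what was read back reproduces the values exactly
        write_expression_matrix(back, tmp_path / "m2.tsv", tmp_path / "s2.tsv")
        again = read_expression_matrix(tmp_path / "m2.tsv", tmp_path / "s2.tsv")
        np.testing.assert_array_equal(again.values, back.values)

    def test_blank_cell_is_a_format_error(self, tmp_path):
        text = "gene\ts1\ts2\ts3\ts4\ng1\t1\t\t3\t4\ng2\t5\t6\t7\t8\n"
        m, s = write_inputs(tmp_path, text, SAMPLE_MAP_2X2)
        with pytest.raises(FormatError):
            read_expression_matrix(m, s)

    def test_duplicate_gene_id_is_a_format_error(self, tmp_path):
        text = "gene\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\ng1\t5\t6\t7\t8\n"
        m, s = write_inputs(tmp_path, text, SAMPLE_MAP_2X2)
        with pytest.raises(FormatError):
            read_expression_matrix(m, s)

    def test_three_conditions_is_a_design_error(self, tmp_path):
        text = "gene\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\ng2\t5\t6\t7\t8\n"
        smap = (
            "sample_id\tcondition\n"
            "s1\tWT\ns2\tWT\ns3\tnull\ns4\thet\n"
        )
        m, s = write_inputs(tmp_path, text, smap)
        with pytest.raises(DesignError):
            read_expression_matrix(m, s)


class TestExcludeProbes:
    def test_empty_exclusion_is_identity(self, small_matrix):
        out = exclude_probes(small_matrix, GeneAnnotation())
        assert out.gene_ids == small_matrix.gene_ids
        np.testing.assert_array_equal(out.values, small_matrix.values)

    def test_drops_controls_preserving_order(self):
        em = make_matrix(np.arange(40, dtype=float).reshape(10, 4),
                         gene_ids=[f"g{i}" for i in range(10)])
        ann = GeneAnnotation(exclusion_set={"g1", "g5", "g9"})
        out = exclude_probes(em, ann)
        assert out.gene_ids == ["g0", "g2", "g3", "g4", "g6", "g7", "g8"]

    def test_excluding_everything_yields_zero_rows(self, small_matrix, caplog):
        ann = GeneAnnotation(exclusion_set=set(small_matrix.gene_ids))
        with caplog.at_level("WARNING"):
            out = exclude_probes(small_matrix, ann)
        assert out.data.shape[0] == 0
        assert any("every gene" in r.message for r in caplog.records)


class TestCollapseByAnnotation:
    @staticmethod
    def table(probes, qs):
        return pd.DataFrame({"q_value": qs}, index=pd.Index(probes, name="probe"))

    def test_keeps_smallest_q_per_symbol(self):
        tab = self.table(["p1", "p2", "p3"], [0.04, 0.01, 0.5])
        ann = GeneAnnotation(probe_to_symbol={"p1": "Klf7", "p2": "Klf7", "p3": "Mb"})
        out = collapse_by_annotation(tab, ann)
        assert list(out.index) == ["p2", "p3"]
        assert out.loc["p2", "q_value"] == 0.01

    def test_distinct_symbols_leave_table_unchanged(self):
        tab = self.table(["p1", "p2"], [0.2, 0.1])
        ann = GeneAnnotation(probe_to_symbol={"p1": "A", "p2": "B"})
        out = collapse_by_annotation(tab, ann)
        assert list(out.index) == ["p1", "p2"]

    def test_q_ties_keep_first_probe_in_input_order(self):
        tab = self.table(["pA", "pB"], [0.03, 0.03])
        ann = GeneAnnotation(probe_to_symbol={"pA": "X", "pB": "X"})
        out = collapse_by_annotation(tab, ann)
        assert list(out.index) == ["pA"]

    def test_unannotated_probes_are_kept_as_rows(self):
        tab = self.table(["p1", "p2", "p3"], [0.9, 0.8, 0.7])
        ann = GeneAnnotation(probe_to_symbol={"p1": "A"})
        out = collapse_by_annotation(tab, ann)
        assert set(out.index) == {"p1", "p2", "p3"}

    def test_properties_unique_symbols_and_q_subset(self):
        rng = np.random.default_rng(7)
        probes = [f"p{i}" for i in range(40)]
        qs = rng.uniform(size=40)
        symbols = {p: f"S{rng.integers(0, 12)}" for p in probes}
        out = collapse_by_annotation(self.table(probes, qs),
                                     GeneAnnotation(probe_to_symbol=symbols))
        syms = out["gene_symbol"][out["gene_symbol"] != ""]
        assert syms.is_unique
        assert set(out["q_value"]) <= set(qs)
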