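import pytest
from hypothesis import given, strategies as st

from betweennet import data_io
from betweennet.data_io import ValidationError
from betweennet.ranking import RankedList, RankEntry


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadPPI:
    def test_dedup_self_loops_and_reversed_duplicates(self, tmp_path):
        path = write(tmp_path, "ppi.tsv", "A\tB\nB\tA\nC\tC\nA\tB\n")
        g = data_io.read_ppi(path)
        assert set(g.nodes) == {"A", "B"}
        assert g.number_of_edges() == 1

    def test_two_edges(self, tmp_path):
        g = data_io.read_ppi(write(tmp_path, "ppi.tsv", "A\tB\nB\tC\n"))
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2

    def test_empty_network_is_an_error(self, tmp_path):
        with pytest.raises(ValidationError, match="empty network"):
            data_io.read_ppi(write(tmp_path, "ppi.tsv", ""))
        with pytest.raises(ValidationError, match="empty network"):
            data_io.read_ppi(write(tmp_path, "loops.tsv", "A\tA\n"))

    def test_short_line_is_an_error(self, tmp_path):
        with pytest.raises(ValidationError, match="2 columns"):
            data_io.read_ppi(write(tmp_path, "ppi.tsv", "A\tB\nC\n"))

    def test_header_flag_skips_first_line(self, tmp_path):
        path = write(tmp_path, "ppi.tsv", "gene1\tgene2\nA\tB\n")
        assert data_io.read_ppi(path, header=True).number_of_edges() == 1

    @given(
        edges=st.lists(
            st.tuples(st.sampled_from("ABCDE"), st.sampled_from("ABCDE")),
            min_size=1, max_size=15,
        ).filter(lambda es: any(u != v for u, v in es)),
        dup=st.booleans(),
    )
    def test_idempotent_under_reversal_and_duplication(self, tmp_path_factory, edges, dup):
        tmp = tmp_path_factory.mktemp("ppi")
        plain = "".join(f"{u}\t{v}\n" for u, v in edges)
        noisy = plain + "".join(
            f"{v}\t{u}\n" for u, v in (edges if dup else [])
        )
        g1 = data_io.read_ppi(write(tmp, "a.tsv", plain))
        g2 = data_io.read_ppi(write(tmp, "b.tsv", noisy))
        assert set(g1.edges) == set(g2.edges)


class TestReadExpression:
    def test_basic_matrix(self, tmp_path):
        path = write(tmp_path, "e.tsv", "gene\tP1\tP2\nG1\t1.5\t2\nG2\t0\t7\n")
        expr = data_io.read_expression(path, "normal")
        assert list(expr.genes) == ["G1", "G2"]
        assert list(expr.patients) == ["P1", "P2"]
        assert expr.value("G2", "P2") == 7.0

    def test_non_numeric_cell_names_location(self, tmp_path):
        path = write(tmp_path, "e.tsv", "gene\tP1\nG1\tNA\n")
        with pytest.raises(ValidationError, match="G1.*P1"):
            data_io.read_expression(path, "normal")

    def test_negative_value_rejected(self, tmp_path):
        path = write(tmp_path, "e.tsv", "gene\tP1\nG1\t-3\n")
        with pytest.raises(ValidationError, match="negative"):
            data_io.read_expression(path, "tumor")

    def test_duplicate_gene_row_rejected(self, tmp_path):
        path = write(tmp_path, "e.tsv", "gene\tP1\nG1\t1\nG1\t2\n")
        with pytest.raises(ValidationError, match="duplicate gene"):
            data_io.read_expression(path, "normal")


class TestReadMAF:
    HEADER = "Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\n"

    def test_mutation_frequencies_exclude_silent(self, tmp_path):
        path = write(
            tmp_path, "m.maf",
            self.HEADER + "g1\tp1\tMissense_Mutation\n"
            "g1\tp2\tSilent\ng2\tp1\tNonsense_Mutation\n",
        )
        table = data_io.read_maf(path)
        assert table.patients == ("p1", "p2")
        assert table.mutation_frequency("g1") == 0.5
        assert table.mutation_frequency("g2") == 0.5
        assert table.mutated_genes("p2") == frozenset()

    def test_all_silent_gives_empty_sets_and_zero_mf(self, tmp_path, caplog):
        path = write(tmp_path, "m.maf", self.HEADER + "g1\tp1\tSilent\n")
        with caplog.at_level("WARNING", logger="betweennet"):
            table = data_io.read_maf(path)
        assert table.all_mutated_genes == frozenset()
        assert table.mutation_frequency("g1") == 0.0
        assert any("no non-silent" in r.message for r in caplog.records)

    def test_repeat_mutation_in_one_patient_counted_once(self, tmp_path):
        path = write(
            tmp_path, "m.maf",
            self.HEADER + "g1\tp1\tMissense_Mutation\ng1\tp1\tNonsense_Mutation\n"
            "g2\tp2\tMissense_Mutation\n",
        )
        assert data_io.read_maf(path).mutation_frequency("g1") == 0.5

    def test_missing_column_is_an_error(self, tmp_path):
        path = write(tmp_path, "m.maf", "gene\tpatient\ng1\tp1\n")
        with pytest.raises(ValidationError, match="missing required column"):
            data_io.read_maf(path)

    def test_restrict_recomputes_frequencies(self, tmp_path):
        path = write(
            tmp_path, "m.maf",
            self.HEADER + "g1\tp1\tMissense_Mutation\ng2\tp2\tMissense_Mutation\n",
        )
        table = data_io.read_maf(path).restrict(["p1"])
        assert table.patients == ("p1",)
        assert table.mutation_frequency("g1") == 1.0
        assert table.mutation_frequency("g2") == 0.0


class TestGeneSetsAndRanking:
    def test_gene_set_deduplicated(self, tmp_path):
        path = write(tmp_path, "ref.txt", "TP53\nTP53\nKRAS\n")
        assert data_io.read_gene_set(path).genes == frozenset({"TP53", "KRAS"})

    def test_empty_gene_set_is_an_error(self, tmp_path):
        with pytest.raises(ValidationError, match="empty"):
            data_io.read_gene_set(write(tmp_path, "ref.txt", "\n\n"))

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(OSError):
            data_io.read_gene_set(tmp_path / "absent.txt")

    def test_ranking_round_trip_preserves_order_and_scores(self, tmp_path):
        ranking = RankedList(entries=[
            RankEntry(1, "TP53", 0.987654321, 1.0, 0.5),
            RankEntry(2, "KRAS", 0.5, 0.25, 0.75),
            RankEntry(3, "ZZZ3", 0.01, 0.0, 0.0, note="no-network"),
        ], alpha=0.5)
        path = tmp_path / "ranking.tsv"
        data_io.write_ranking(ranking, path)
        back = data_io.read_ranking(path)
        assert back.genes == ["TP53", "KRAS", "ZZZ3"]
        assert [e.rank for e in back.entries] == [1, 2, 3]
        for orig, re_read in zip(ranking.entries, back.entries):
            assert re_read.score == pytest.approx(orig.score, rel=1e-9)
            assert re_read.note == orig.note

    def test_annotation_reader_groups_terms(self, tmp_path):
        path = write(tmp_path, "ann.tsv", "g1\tT1\ng2\tT1\ng2\tT2\n")
        ann = data_io.read_annotation(path)
        assert ann == {"T1": frozenset({"g1", "g2"}), "T2": frozenset({"g2"})}
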