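import random

import pytest
from hypothesis import given, strategies as st

from ppinet import netio
from ppinet.netio import (
    AnnotationSet,
    NetworkFormatError,
    SignedEdge,
    normalize_identifier,
    read_gene_sets,
    read_network,
    read_signed_edges,
    write_network,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadNetwork:
    def test_tsv_triangle(self, tmp_path):
        p = _write(tmp_path, "n.tsv", "A\tB\nB\tC\nC\tA\n")
        g = read_network(p)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3

    def test_duplicates_and_self_loops_dropped(self, tmp_path):
        p = _write(tmp_path, "n.tsv", "A\tB\nB\tA\nA\tA\n")
        g = read_network(p)
        assert set(g.nodes()) == {"A", "B"}
        assert g.number_of_edges() == 1
        prov = g.graph["provenance"]
        assert prov["self_loops_dropped"] == 1 and prov["duplicates_dropped"] == 1

    def test_sif_multi_target_row_expands_to_star(self, tmp_path):
        p = _write(tmp_path, "n.sif", "A pp B C\n")
        g = read_network(p)
        assert set(map(frozenset, g.edges())) == {frozenset("AB"), frozenset("AC")}

    def test_sif_single_token_is_isolated_node(self, tmp_path):
        p = _write(tmp_path, "n.sif", "A pp B\nZ\n")
        g = read_network(p)
        assert "Z" in g and g.degree("Z") == 0

    @pytest.mark.parametrize(
        "name,text",
        [
            ("bad.tsv", "A\tB\nA\tB\tC\n"),  # 3 fields in a 2-column TSV
            ("bad.sif", "A pp B\nX Y\n"),  # 2-token SIF row
        ],
    )
    def test_malformed_row_names_line_number(self, tmp_path, name, text):
        with pytest.raises(NetworkFormatError, match=":2:"):
            read_network(_write(tmp_path, name, text))

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(NetworkFormatError, match="empty"):
            read_network(_write(tmp_path, "e.tsv", "\n"))

    def test_identifier_whitespace_trimmed(self, tmp_path):
        g = read_network(_write(tmp_path, "n.tsv", " A \tB\n"))
        assert set(g.nodes()) == {"A", "B"}

    def test_round_trip(self, tmp_path):
        g = read_network(_write(tmp_path, "n.tsv", "A\tB\nB\tC\nD\tA\n"))
        out = tmp_path / "out.tsv"
        write_network(g, out)
        g2 = read_network(out)
        assert set(g.nodes()) == set(g2.nodes())
        assert set(map(frozenset, g.edges())) == set(map(frozenset, g2.edges()))
        assert (tmp_path / "out.tsv.prov.json").exists()

    @given(
        edges=st.lists(
            st.tuples(st.sampled_from("ABCDEF"), st.sampled_from("ABCDEF")),
            min_size=1,
            max_size=20,
        ),
        shuffle_seed=st.integers(0, 1000),
    )
    def test_row_order_irrelevant(self, tmp_path, edges, shuffle_seed):
        rows = [f"{a}\t{b}" for a, b in edges]
        shuffled = rows[:]
        random.Random(shuffle_seed).shuffle(shuffled)
        d = tmp_path / str(abs(hash((tuple(rows), shuffle_seed))))
        d.mkdir(exist_ok=True)
        g1 = read_network(_write(d, "a.tsv", "\n".join(rows) + "\n"))
        g2 = read_network(_write(d, "b.tsv", "\n".join(shuffled) + "\n"))
        assert set(g1.nodes()) == set(g2.nodes())
        assert set(map(frozenset, g1.edges())) == set(map(frozenset, g2.edges()))


class TestNormalizeIdentifier:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("tp53", "TP53"),
            (" AKT1 ", "AKT1"),
            ("MIR-622", "miR-622"),
            ("hsa-MIR-429", "hsa-miR-429"),
            ("miR-6893-5P", "miR-6893-5p"),
            ("let-7a", "let-7a"),
        ],
    )
    def test_case_rules(self, raw, expected):
        assert normalize_identifier(raw) == expected


class TestSignedEdges:
    def test_repression_and_activation_tokens(self, tmp_path):
        p = _write(tmp_path, "s.tsv", "EZH2\tTP53\trepress\nKLF4\tmiR-429\tactivate\n")
        tf_gene = read_signed_edges(p, "tf_gene")
        assert tf_gene[0] == SignedEdge("EZH2", "TP53", -1, "tf_gene")
        assert tf_gene[1].sign == 1

    @pytest.mark.parametrize("token,sign", [("+", 1), ("+1", 1), ("-", -1), ("-1", -1)])
    def test_numeric_sign_tokens(self, tmp_path, token, sign):
        p = _write(tmp_path, "s.tsv", f"A\tB\t{token}\n")
        assert read_signed_edges(p, "tf_gene")[0].sign == sign

    def test_unknown_sign_token_names_row(self, tmp_path):
        p = _write(tmp_path, "s.tsv", "A\tB\t+\nX\tY\tmaybe\n")
        with pytest.raises(NetworkFormatError, match=":2:.*maybe"):
            read_signed_edges(p, "tf_gene")

    def test_two_column_rows_need_default_sign(self, tmp_path):
        p = _write(tmp_path, "s.tsv", "miR-1\tG1\n")
        with pytest.raises(NetworkFormatError):
            read_signed_edges(p, "mirna_gene")
        edges = read_signed_edges(p, "mirna_gene", default_sign=-1)
        assert edges[0].sign == -1

    def test_invalid_layer_rejected(self, tmp_path):
        p = _write(tmp_path, "s.tsv", "A\tB\t+\n")
        with pytest.raises(ValueError, match="layer"):
            read_signed_edges(p, "gene_tf")

    def test_signed_edge_validation(self):
        with pytest.raises(ValueError):
            SignedEdge("A", "B", 0, "tf_gene")
        with pytest.raises(ValueError):
            SignedEdge("A", "B", 1, "bogus")


class TestGeneSets:
    def test_members_parsed_and_deduplicated(self, tmp_path):
        p = _write(tmp_path, "g.gmt", "T1\td\tA\tB\tC\nT2\td\tA\tA\tB\n")
        sets = read_gene_sets(p)
        assert sets[0].members == frozenset("ABC")
        assert sets[1].members == frozenset("AB")

    def test_short_line_rejected(self, tmp_path):
        with pytest.raises(NetworkFormatError, match=":1:"):
            read_gene_sets(_write(tmp_path, "g.gmt", "T1\tdesc\n"))

    def test_duplicate_term_id_rejected(self, tmp_path):
        p = _write(tmp_path, "g.gmt", "T1\td\tA\nT1\td\tB\n")
        with pytest.raises(NetworkFormatError, match="duplicate"):
            read_gene_sets(p)

    def test_empty_member_set_rejected(self):
        with pytest.raises(ValueError):
            AnnotationSet("T", "d", frozenset())
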