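import itertools
import random

import pytest
from hypothesis import given, strategies as st

import oracles
from ppinet.netio import SignedEdge
from ppinet.regnet import (
    FFL_TYPE_TABLE,
    assemble,
    classify_ffl,
    consensus_targets,
    enumerate_feedback_loops,
    enumerate_ffls,
)
from ppinet.synthetic import gen_signed_regnet


def _edges(*triples_by_layer):
    """Helper: [(source, target, sign, layer), ...] -> list of SignedEdge."""
    return [SignedEdge(s, t, sign, layer) for s, t, sign, layer in triples_by_layer]


class TestConsensusTargets:
    def test_strict_intersection_by_default(self):
        sources = {
            "S1": {("a", "G")},
            "S2": {("a", "G")},
            "S3": {("a", "G"), ("b", "G")},
        }
        assert consensus_targets(sources) == {("a", "G")}

    def test_min_support_one_is_union(self):
        sources = {"S1": {("a", "G")}, "S2": {("b", "H")}}
        assert consensus_targets(sources, 1) == {("a", "G"), ("b", "H")}

    def test_matches_brute_force_set_algebra(self):
        rng = random.Random(0)
        universe = [(f"miR-{i}", f"G{j}") for i in range(20) for j in range(10)]
        sources = {f"S{k}": set(rng.sample(universe, 50)) for k in range(3)}
        expected = sources["S0"] & sources["S1"] & sources["S2"]
        assert consensus_targets(sources, 3) == expected

    @given(support=st.integers(1, 3))
    def test_monotone_in_min_support(self, support):
        rng = random.Random(7)
        universe = [(f"m{i}", f"g{j}") for i in range(8) for j in range(8)]
        sources = {f"S{k}": set(rng.sample(universe, 20)) for k in range(3)}
        if support < 3:
            assert consensus_targets(sources, support + 1) <= consensus_targets(
                sources, support
            )

    def test_out_of_range_support_rejected(self):
        with pytest.raises(ValueError):
            consensus_targets({"S1": set()}, 2)
        with pytest.raises(ValueError):
            consensus_targets({"S1": {("a", "G")}}, 0)


class TestAssemble:
    def test_counts_nodes_and_edges(self):
        net = assemble(
            _edges(
                ("TF1", "G1", 1, "tf_gene"),
                ("TF2", "G1", -1, "tf_gene"),
                ("TF1", "miR-1", 1, "tf_mirna"),
                ("miR-1", "G1", -1, "mirna_gene"),
            )
        )
        assert net.n_nodes == 4 and net.n_edges == 4

    def test_duplicate_edge_counted_once(self):
        e = SignedEdge("TF1", "G1", 1, "tf_gene")
        net = assemble([e, e])
        assert net.n_edges == 1

    def test_conflicting_duplicate_sign_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            assemble(
                _edges(("TF1", "G1", 1, "tf_gene"), ("TF1", "G1", -1, "tf_gene"))
            )

    def test_dual_tf_gene_role_is_one_node(self):
        # a hub gene that itself transactivates a miRNA
        net = assemble(
            _edges(
                ("EZH2", "TP53", -1, "tf_gene"),
                ("TP53", "miR-429", 1, "tf_mirna"),
            )
        )
        assert net.n_nodes == 3
        assert net.roles["TP53"] == {"TF", "gene"}

    def test_mirna_role_is_exclusive(self):
        with pytest.raises(ValueError, match="roles"):
            assemble(
                _edges(
                    ("TF1", "miR-1", 1, "tf_mirna"),
                    ("miR-1", "G1", 1, "tf_gene"),  # would make miR-1 a TF
                )
            )


class TestClassifyFFL:
    def test_all_eight_patterns_split_evenly(self):
        labels = {}
        for signs in itertools.product((1, -1), repeat=3):
            coherence, label = classify_ffl(*signs)
            labels[signs] = (coherence, label)
            assert (coherence == "coherent") == (signs[2] == signs[0] * signs[1])
        assert sum(c == "coherent" for c, _ in labels.values()) == 4
        assert {l for _, l in labels.values()} == set(FFL_TYPE_TABLE.values())

    def test_known_patterns(self):
        assert classify_ffl(1, -1, -1) == ("coherent", "C3")
        # TF activates the miRNA, the miRNA represses the hub gene, and the
        # TF also activates the gene directly: the classic incoherent type 1
        assert classify_ffl(1, -1, 1) == ("incoherent", "I1")
        assert classify_ffl(1, 1, 1) == ("coherent", "C1")

    def test_double_sign_flip_of_indirect_path_preserves_class(self):
        for signs in itertools.product((1, -1), repeat=3):
            s1, s2, s3 = signs
            assert classify_ffl(-(-s1), -(-s2), s3) == classify_ffl(s1, s2, s3)

    def test_invalid_sign_rejected(self):
        with pytest.raises(ValueError):
            classify_ffl(0, 1, 1)


class TestEnumerateFFLs:
    def test_repressive_cascade_with_direct_repression_is_coherent(self):
        # TF represses the gene directly and, via an activated miRNA that
        # represses the gene, indirectly: signs (+1, -1, -1)
        net = assemble(
            _edges(
                ("EZH2", "TP53", -1, "tf_gene"),
                ("EZH2", "miR-622", 1, "tf_mirna"),
                ("miR-622", "TP53", -1, "mirna_gene"),
            )
        )
        (motif,) = enumerate_ffls(net)
        assert (motif.tf, motif.mirna, motif.gene) == ("EZH2", "miR-622", "TP53")
        assert motif.coherence == "coherent" and motif.type_label == "C3"

    def test_no_direct_edges_no_motifs(self):
        net = assemble(
            _edges(
                ("TF1", "miR-1", 1, "tf_mirna"),
                ("miR-1", "G1", -1, "mirna_gene"),
            )
        )
        assert enumerate_ffls(net) == []

    def test_matches_brute_force_on_random_networks(self):
        probs = {"tf_mirna": 0.1, "mirna_gene": 0.1, "tf_gene": 0.1}
        for seed in range(10):
            net, _ = gen_signed_regnet(20, 20, 20, probs, seed=seed)
            got = {
                (m.tf, m.mirna, m.gene, m.sign_tf_mirna, m.sign_mirna_gene, m.sign_tf_gene)
                for m in enumerate_ffls(net)
            }
            assert got == oracles.brute_ffls(net)

    def test_planted_motifs_recovered_exactly_without_background(self):
        net, truth = gen_signed_regnet(
            0, 0, 0, {}, planted_ffls=["I1", "I1", "I1"], seed=1
        )
        motifs = enumerate_ffls(net)
        assert len(motifs) == len(truth) == 3
        assert all(m.coherence == "incoherent" for m in motifs)


class TestFeedbackLoops:
    def test_mutual_repression_is_net_positive(self):
        net = assemble(
            _edges(
                ("JUN", "miR-429", -1, "gene_mirna"),
                ("miR-429", "JUN", -1, "mirna_gene"),
            )
        )
        (loop,) = enumerate_feedback_loops(net)
        assert loop.loop_sign == 1  # double negative

    def test_activation_with_repression_is_negative_feedback(self):
        net = assemble(
            _edges(
                ("TP53", "miR-429", 1, "gene_mirna"),
                ("miR-429", "TP53", -1, "mirna_gene"),
            )
        )
        (loop,) = enumerate_feedback_loops(net)
        assert loop.loop_sign == -1

    def test_acyclic_network_has_none(self):
        net = assemble(
            _edges(
                ("TP53", "miR-429", 1, "gene_mirna"),
                ("miR-429", "EGFR", -1, "mirna_gene"),
            )
        )
        assert enumerate_feedback_loops(net) == []
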