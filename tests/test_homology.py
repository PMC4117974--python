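import numpy as np
import pytest
from Bio.Align import substitution_matrices

from oracles import global_align_score_brute, local_align_score_brute
from paleofam.homology import (
    LocalAlignment,
    ScoringScheme,
    all_vs_all_within,
    call_orthologs,
    call_paralogs,
    global_align_protein,
    local_align_nt,
)

SCHEME = ScoringScheme()


class TestLocalAlign:
    def test_self_alignment_is_perfect(self):
        seq = "ACGT" * 100
        aln = local_align_nt(seq, seq)
        assert aln.identity == 1.0
        assert aln.aligned_length == 400
        assert aln.score == 400 * SCHEME.match

    def test_derived_eight_by_eight_instance_matches_dp_oracle(self):
        a, b = "ACACACAC", "ACACTCAC"
        expected = local_align_score_brute(a, b, 1, -2, -5, -2)
        aln = local_align_nt(a, b)
        assert aln.score == expected == 5.0
        assert aln.aligned_length == 8 and aln.identity == 7 / 8

    def test_disjoint_alphabets_give_zero_score(self):
        aln = local_align_nt("AAAA", "CCCC")
        assert aln.score == 0.0 and aln.aligned_length == 0

    def test_invalid_characters_raise(self):
        with pytest.raises(ValueError):
            local_align_nt("ACGU", "ACGT")
        with pytest.raises(ValueError):
            local_align_nt("", "ACGT")

    def test_score_symmetric_in_arguments(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), rng.integers(5, 30)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(5, 30)))
            assert local_align_nt(a, b).score == local_align_nt(b, a).score

    def test_matches_brute_force_enumeration_on_tiny_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            a = "".join(rng.choice(list("ACGT"), rng.integers(1, 7)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(1, 7)))
            expected = local_align_score_brute(a, b, 1, -2, -5, -2)
            assert local_align_nt(a, b).score == expected

    def test_evalue_follows_karlin_altschul_form(self):
        aln = local_align_nt("ACGTACGTACGT", "ACGTACGTACGT")
        m = n = 12
        expected = SCHEME.karlin_k * m * n * np.exp(-SCHEME.karlin_lambda * aln.score)
        assert aln.evalue == pytest.approx(expected)


class TestGlobalProtein:
    def test_identical_proteins_align_without_gaps(self):
        aln = global_align_protein("MKVLA", "MKVLA")
        assert aln.aligned_a == aln.aligned_b == "MKVLA"

    def test_one_gap_case_matches_exhaustive_enumeration(self):
        blosum = substitution_matrices.load("BLOSUM62")
        expected = global_align_score_brute(
            "MKV", "MV", lambda x, y: blosum[x, y], 2.0, 0.2
        )
        aln = global_align_protein("MKV", "MV")
        assert aln.score == expected
        assert (aln.aligned_a, aln.aligned_b) == ("MKV", "M-V")

    def test_empty_versus_nonempty_is_all_gaps(self):
        aln = global_align_protein("", "MKV")
        assert aln.aligned_a == "---" and aln.aligned_b == "MKV"

    def test_random_tiny_pairs_match_enumeration(self):
        blosum = substitution_matrices.load("BLOSUM62")
        rng = np.random.default_rng(3)
        aas = list("ARNDCQEGHILKMFPSTWYV")
        for _ in range(15):
            a = "".join(rng.choice(aas, rng.integers(1, 6)))
            b = "".join(rng.choice(aas, rng.integers(1, 6)))
            expected = global_align_score_brute(
                a, b, lambda x, y: blosum[x, y], 2.0, 0.2
            )
            assert global_align_protein(a, b).score == pytest.approx(expected)


def _aln(a, b, length, identity, score=100.0, evalue=1e-30):
    return LocalAlignment(a, b, score, length, identity, evalue, (0, length), (0, length))


class TestParalogs:
    def test_thresholds_are_strict_on_length_and_inclusive_on_identity(self):
        pairs, _ = call_paralogs([_aln("a", "b", 350, 0.45)])
        assert len(pairs) == 1
        pairs, _ = call_paralogs([_aln("a", "b", 300, 0.90)])
        assert pairs == []  # "over 300 bp" is strict
        pairs, _ = call_paralogs([_aln("a", "b", 301, 0.40)])
        assert len(pairs) == 1

    def test_groups_are_connected_components(self):
        pairs, groups = call_paralogs(
            [_aln("a", "b", 400, 0.5), _aln("b", "c", 400, 0.5), _aln("d", "e", 400, 0.5)]
        )
        assert groups == [["a", "b", "c"], ["d", "e"]]

    def test_groups_match_networkx_components_on_random_graphs(self):
        import networkx as nx

        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(4, 12))
            names = [f"g{i}" for i in range(n)]
            alignments = []
            graph = nx.Graph()
            graph.add_nodes_from([])
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.25:
                        alignments.append(_aln(names[i], names[j], 400, 0.5))
                        graph.add_edge(names[i], names[j])
            _, groups = call_paralogs(alignments)
            expected = sorted(
                (sorted(c) for c in nx.connected_components(graph)), key=lambda g: g[0]
            )
            assert groups == expected


class TestOrthologs:
    def test_reciprocal_best_hit_is_kept(self):
        hits_ab = [_aln("a1", "b1", 350, 0.8, score=90), _aln("a1", "b2", 350, 0.8, score=50)]
        hits_ba = [_aln("b1", "a1", 350, 0.8, score=90), _aln("b2", "a1", 350, 0.8, score=50)]
        pairs = call_orthologs(hits_ab, hits_ba)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a1", "b1")]

    def test_non_reciprocal_best_is_rejected(self):
        hits_ab = [_aln("a1", "b1", 350, 0.8, score=90)]
        hits_ba = [_aln("b1", "a2", 350, 0.8, score=95), _aln("b1", "a1", 350, 0.8, score=90)]
        assert call_orthologs(hits_ab, hits_ba) == []

    def test_short_reciprocal_best_is_rejected(self):
        hits_ab = [_aln("a1", "b1", 250, 0.9, score=90)]
        hits_ba = [_aln("b1", "a1", 250, 0.9, score=90)]
        assert call_orthologs(hits_ab, hits_ba) == []

    def test_output_is_a_matching(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            na, nb = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            hits_ab, hits_ba = [], []
            for i in range(na):
                for j in range(nb):
                    s = float(rng.integers(10, 100))
                    hits_ab.append(_aln(f"a{i}", f"b{j}", 400, 0.5, score=s))
                    hits_ba.append(_aln(f"b{j}", f"a{i}", 400, 0.5, score=s))
            pairs = call_orthologs(hits_ab, hits_ba)
            seen = [g for p in pairs for g in (p.gene_a, p.gene_b)]
            assert len(seen) == len(set(seen))


def test_all_vs_all_excludes_self_and_visits_each_pair_once():
    cds = {"a": "ACGTACGT", "b": "ACGTACGA", "c": "TTTTCCCC"}
    alignments = all_vs_all_within(cds)
    keys = {frozenset((x.query_id, x.subject_id)) for x in alignments}
    assert len(alignments) == 3 == len(keys)
    assert all(len(k) == 2 for k in keys)
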