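import numpy as np
import pytest

from oracles import chain_is_valid, longest_chain_brute
from paleofam.io import GeneRecord
from paleofam.motifs import FamilyCall
from paleofam.synteny import (
    AnchorPair,
    DuplicationCall,
    SyntenicBlock,
    WgdCalibration,
    assign_wgd_event,
    block_median_ks,
    build_retention_matrix,
    call_tandem,
    classify_duplication,
    expected_multiplicity,
    find_collinear_blocks,
    index_block_anchors,
    POPULUS_CALIBRATION,
)


def _gene(gid, rank, species="sp", chrom="c1", start=None):
    start = rank * 20_000 if start is None else start
    return GeneRecord(gid, species, chrom, start, start + 450, "+", rank)


def _diag_anchors(n, chrom_b="c2"):
    return [
        AnchorPair(_gene(f"a{i}", i), _gene(f"b{i}", i, chrom=chrom_b), 0.3)
        for i in range(n)
    ]


class TestBlocks:
    def test_six_collinear_anchors_form_one_block(self):
        blocks = find_collinear_blocks(_diag_anchors(6))
        assert len(blocks) == 1
        assert len(blocks[0].anchors) == 6
        assert blocks[0].orientation == "same"

    def test_four_anchors_below_threshold_yield_nothing(self):
        assert find_collinear_blocks(_diag_anchors(4)) == []

    def test_inverted_blocks_are_found(self):
        anchors = [
            AnchorPair(_gene(f"a{i}", i), _gene(f"b{i}", 9 - i, chrom="c2"), None)
            for i in range(6)
        ]
        blocks = find_collinear_blocks(anchors)
        assert len(blocks) == 1 and blocks[0].orientation == "inverted"

    def test_rank_gap_limit_splits_chains(self):
        anchors = _diag_anchors(5) + [
            AnchorPair(_gene(f"a{i}", i), _gene(f"b{i}", i, chrom="c2"), None)
            for i in range(30, 35)
        ]
        blocks = find_collinear_blocks(anchors, min_anchors=5, max_rank_gap=10)
        assert len(blocks) == 2

    def test_every_anchor_in_at_most_one_block_and_chains_valid(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(8, 20))
            ra = rng.permutation(60)[:n]
            rb = rng.permutation(60)[:n]
            anchors = [
                AnchorPair(_gene(f"a{i}", int(ra[i])), _gene(f"b{i}", int(rb[i]), chrom="c2"), None)
                for i in range(n)
            ]
            blocks = find_collinear_blocks(anchors, min_anchors=3)
            seen = set()
            for block in blocks:
                ranks = [(p.gene_a.rank, p.gene_b.rank) for p in block.anchors]
                assert chain_is_valid(ranks, 10)
                for pair in block.anchors:
                    key = (pair.gene_a.gene_id, pair.gene_b.gene_id)
                    assert key not in seen
                    seen.add(key)

    def test_greedy_extraction_matches_exhaustive_chain_search(self):
        rng = np.random.default_rng(4)
        for _ in range(6):
            n = int(rng.integers(8, 15))
            ra = rng.permutation(40)[:n]
            rb = rng.permutation(40)[:n]
            pairs = [(int(ra[i]), int(rb[i])) for i in range(n)]
            anchors = [
                AnchorPair(_gene(f"a{i}", p[0]), _gene(f"b{i}", p[1], chrom="c2"), None)
                for i, p in enumerate(pairs)
            ]
            blocks = find_collinear_blocks(anchors, min_anchors=2, max_rank_gap=10)
            best = longest_chain_brute(pairs, 10)
            if best >= 2:
                assert max(len(b.anchors) for b in blocks) == best
            else:
                assert blocks == []


class TestBlockKs:
    def test_median_over_anchor_ks(self):
        block = SyntenicBlock(0, "sp", "sp", "c1", "c2", _diag_anchors(3), "same")
        block.anchors[0].ks, block.anchors[1].ks, block.anchors[2].ks = 0.25, 0.27, 0.30
        assert block_median_ks(block) == 0.27

    def test_single_and_even_counts(self):
        block = SyntenicBlock(0, "sp", "sp", "c1", "c2", _diag_anchors(1), "same")
        block.anchors[0].ks = 1.5
        assert block_median_ks(block) == 1.5
        block = SyntenicBlock(0, "sp", "sp", "c1", "c2", _diag_anchors(2), "same")
        block.anchors[0].ks, block.anchors[1].ks = 0.2, 0.4
        assert block_median_ks(block) == pytest.approx(0.3)

    def test_no_defined_ks_raises(self):
        block = SyntenicBlock(0, "sp", "sp", "c1", "c2", _diag_anchors(2), "same")
        block.anchors[0].ks = block.anchors[1].ks = None
        with pytest.raises(ValueError):
            block_median_ks(block)


class TestEventAssignment:
    @pytest.mark.parametrize(
        "ks,label",
        [(0.27, "P-WGD"), (1.54, "gamma"), (0.60, "unassigned"),
         (0.2437, "P-WGD"), (1.7896, "gamma")],
    )
    def test_populus_published_ranges(self, ks, label):
        assert assign_wgd_event(ks, POPULUS_CALIBRATION) == label

    def test_overlapping_intervals_rejected_at_load(self):
        with pytest.raises(ValueError, match="overlap"):
            WgdCalibration([("x", 0.1, 0.5), ("y", 0.4, 0.9)])

    def test_saturated_blocks_get_the_indistinguishable_label(self):
        calibration = WgdCalibration([("alpha", 0.783, 0.881)], saturation=1.9)
        assert assign_wgd_event(2.1, calibration) == "beta/gamma-indistinguishable"
        assert assign_wgd_event(1.2, calibration) == "unassigned"

    def test_piecewise_constant_within_intervals(self):
        for ks in np.linspace(0.2437, 0.3345, 7):
            assert assign_wgd_event(float(ks), POPULUS_CALIBRATION) == "P-WGD"


class TestTandem:
    def test_same_chromosome_within_window_and_significant(self):
        a, b = _gene("a", 0, start=0), _gene("b", 3, start=50_000)
        assert call_tandem(a, b, 1e-30) is True

    def test_distance_beyond_window_fails(self):
        a, b = _gene("a", 0, start=0), _gene("b", 9, start=150_000)
        assert call_tandem(a, b, 1e-30) is False

    def test_different_chromosomes_fail_even_when_close(self):
        a = _gene("a", 0, start=0)
        b = GeneRecord("b", "sp", "c9", 10_000, 10_450, "+", 0)
        assert call_tandem(a, b, 1e-30) is False

    def test_weak_evalue_fails(self):
        a, b = _gene("a", 0, start=0), _gene("b", 1, start=20_000)
        assert call_tandem(a, b, 1e-10) is False


class TestClassify:
    def test_precedence_swgd_over_td_over_other(self):
        anchors = _diag_anchors(6)
        for p in anchors:
            p.ks = 0.27
        blocks = find_collinear_blocks(anchors)
        blocks[0].assigned_event = "P-WGD"
        index = index_block_anchors(blocks)
        a0, b0 = anchors[0].gene_a, anchors[0].gene_b
        call = classify_duplication(a0, b0, blocks, 1e-40, block_index=index)
        assert call.mechanism == "SWGD" and call.event == "P-WGD"
        # same pair positions but not anchored: close + significant -> TD
        x, y = _gene("x", 0, start=0), _gene("y", 1, start=30_000)
        assert classify_duplication(x, y, blocks, 1e-40, block_index=index).mechanism == "TD"
        far = _gene("z", 50, chrom="c9", start=5_000_000)
        assert classify_duplication(x, far, blocks, 1e-40, block_index=index).mechanism == "OTHER"

    def test_classification_is_exhaustive_and_exclusive(self):
        blocks = []
        x, y = _gene("x", 0, start=0), _gene("y", 1, start=30_000)
        call = classify_duplication(x, y, blocks, 1e-10)
        assert call.mechanism in {"SWGD", "TD", "OTHER"}


class TestMultiplicity:
    @pytest.mark.parametrize(
        "events,expected",
        [(["duplication", "duplication"], 4), (["duplication"], 2),
         (["triplication"], 3), ([], 1),
         (["triplication", "duplication", "duplication"], 12)],
    )
    def test_products(self, events, expected):
        assert expected_multiplicity(events) == expected

    def test_unknown_event_raises(self):
        with pytest.raises(ValueError):
            expected_multiplicity(["fission"])


class TestRetentionMatrix:
    def _family(self, gid, member=True):
        return FamilyCall(gid, gid.split("_")[0], 2 if member else 0, member)

    def test_single_species_no_blocks_gives_isolated_loci(self):
        genes = {
            "sp_g1": _gene("sp_g1", 0, species="sp"),
            "sp_g2": _gene("sp_g2", 50, species="sp", start=5_000_000),
        }
        calls = {g: self._family(g) for g in genes}
        matrix = build_retention_matrix([], calls, genes, {"sp": 2}, anchors=[])
        # each observed member occupies its own slot; the rest is block-less
        assert len(matrix.loci) == 2
        for locus in matrix.loci:
            assert matrix.states[locus]["sp"] == ["E", "B"]

    def test_member_and_nonmember_states(self):
        # two species, one locus; the sp2 copy lost its motif
        anchors = [
            AnchorPair(_gene(f"sp1_a{i}", i, species="sp1"),
                       _gene(f"sp2_a{i}", i, species="sp2", chrom="c5"), 0.3)
            for i in range(5)
        ]
        blocks = find_collinear_blocks(anchors)
        genes = {}
        calls = {}
        for pair in anchors:
            for rec, member in ((pair.gene_a, True), (pair.gene_b, False)):
                genes[rec.gene_id] = rec
                calls[rec.gene_id] = self._family(rec.gene_id, member)
        matrix = build_retention_matrix(
            blocks, calls, genes, {"sp1": 1, "sp2": 1}, anchors=anchors
        )
        assert len(matrix.loci) == 5
        for locus in matrix.loci:
            assert matrix.states[locus]["sp1"] == ["E"]
            assert matrix.states[locus]["sp2"] == ["N"]

    def test_lost_gene_inside_retained_block_scores_l(self):
        # locus 2 lost its sp2 copy; flanking anchors keep the block alive
        anchors = []
        genes, calls = {}, {}
        for i in range(5):
            ga = _gene(f"sp1_a{i}", i, species="sp1")
            genes[ga.gene_id] = ga
            calls[ga.gene_id] = self._family(ga.gene_id)
            if i != 2:
                gb = _gene(f"sp2_a{i}", i, species="sp2", chrom="c5")
                genes[gb.gene_id] = gb
                calls[gb.gene_id] = self._family(gb.gene_id)
                anchors.append(AnchorPair(ga, gb, 0.3))
        blocks = find_collinear_blocks(anchors, min_anchors=4)
        assert blocks
        matrix = build_retention_matrix(
            blocks, calls, genes, {"sp1": 1, "sp2": 1}, anchors=anchors
        )
        locus = [l for l in matrix.loci if "a2" in l][0]
        assert matrix.states[locus]["sp1"] == ["E"]
        assert matrix.states[locus]["sp2"] == ["L"]

    def test_fraction_non_retained(self):
        anchors = [
            AnchorPair(_gene(f"sp1_a{i}", i, species="sp1"),
                       _gene(f"sp2_a{i}", i, species="sp2", chrom="c5"), 0.3)
            for i in range(5)
        ]
        blocks = find_collinear_blocks(anchors)
        genes, calls = {}, {}
        for pair in anchors:
            for rec, member in ((pair.gene_a, True), (pair.gene_b, False)):
                genes[rec.gene_id] = rec
                calls[rec.gene_id] = self._family(rec.gene_id, member)
        matrix = build_retention_matrix(
            blocks, calls, genes, {"sp1": 1, "sp2": 1}, anchors=anchors
        )
        assert matrix.fraction_non_retained() == pytest.approx(0.5)
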