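import numpy as np
import pytest
from scipy import stats

from paleofam import dnds
from paleofam.motifs import scan_sp_repeats
from paleofam.simulate import (
    LineageNode,
    SimConfig,
    diverge_cds,
    expected_pairwise_ks,
    generate_ancestral_family,
    simulate_dataset,
)

LAMBDA = 1.5e-8


class TestAncestralFamily:
    def test_every_protein_carries_the_template_repeats(self):
        cds, proteins, records = generate_ancestral_family(5, motif_repeats=3, seed=0)
        assert len(cds) == len(proteins) == len(records) == 5
        for gid, protein in proteins.items():
            assert scan_sp_repeats(protein, gid).repeat_count == 3
            assert dnds.translate_cds(cds[gid], gid) == protein

    def test_deterministic_under_seed(self):
        a = generate_ancestral_family(4, seed=7)
        b = generate_ancestral_family(4, seed=7)
        assert a[0].sequences == b[0].sequences
        assert a[2] == b[2]

    def test_single_gene_family(self):
        cds, proteins, records = generate_ancestral_family(1, seed=1)
        assert len(records) == 1 and records[0].rank == 0

    def test_subthreshold_template_warns(self):
        with pytest.warns(UserWarning, match="not classify"):
            generate_ancestral_family(2, motif_repeats=1, seed=0)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            generate_ancestral_family(0)


class TestExpectedKs:
    def test_neutral_clock_inversion(self):
        assert expected_pairwise_ks(4e6, LAMBDA) == pytest.approx(0.12)
        assert expected_pairwise_ks(0.0) == 0.0

    def test_linearity(self):
        assert expected_pairwise_ks(2e7) == pytest.approx(2 * expected_pairwise_ks(1e7))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            expected_pairwise_ks(-1.0)


def _tiny_config(**kwargs):
    defaults = dict(seed=3, n_family=4, n_background=12, gene_codons=60)
    defaults.update(kwargs)
    return SimConfig(**defaults)


class TestSimulateDataset:
    def test_deterministic_under_seed(self):
        a = simulate_dataset(_tiny_config())
        b = simulate_dataset(_tiny_config())
        assert a.anchors == b.anchors
        for sp in a.species:
            assert a.cds[sp].sequences == b.cds[sp].sequences

    def test_gene_count_bookkeeping(self):
        ds = simulate_dataset(_tiny_config())
        book = ds.truth["bookkeeping"]
        assert book["births"] - book["losses"] == book["final"]
        assert book["final"] == sum(len(ds.genes[sp]) for sp in ds.species)

    def test_full_retention_reproduces_the_multiplicity_ratio(self):
        config = _tiny_config(
            p_family_retained=1.0,
            p_family_subfun=0.0,
            p_background_retained=1.0,
            p_segment_loss=0.0,
            td_rate=0.0,
            other_rate=0.0,
        )
        ds = simulate_dataset(config)
        per_locus = {}
        for info in ds.truth["genes"].values():
            if info["kind"] != "family":
                continue
            per_locus.setdefault(info["locus"], {}).setdefault(info["species"], 0)
            per_locus[info["locus"]][info["species"]] += 1
        for locus, counts in per_locus.items():
            assert counts == {"sp1": 4, "sp2": 2, "sp3": 1}

    def test_full_subfunctionalization_leaves_no_member_duplicates(self):
        config = _tiny_config(
            p_family_retained=0.0, p_family_subfun=1.0, td_rate=0.0, other_rate=0.0
        )
        ds = simulate_dataset(config)
        for sp in ds.species:
            for gid, protein in ds.proteins[sp].items():
                info = ds.truth["genes"][gid]
                if info["kind"] == "family" and info["birth"].startswith("wgd"):
                    assert scan_sp_repeats(protein, gid).repeat_count < 2

    def test_truth_slots_match_expected_multiplicity(self):
        ds = simulate_dataset(_tiny_config())
        for locus, per_sp in ds.truth["slots"].items():
            assert len(per_sp["sp1"]) == 4
            assert len(per_sp["sp2"]) == 2
            assert len(per_sp["sp3"]) == 1

    def test_event_beyond_root_age_rejected(self):
        tree = LineageNode(
            "leaf", 0.0, events=[("too_old", "duplication", 80e6)]
        )
        with pytest.raises(ValueError):
            SimConfig(tree=LineageNode("root", 1e6, [tree]), root_age=62e6)

    def test_written_files_round_trip(self, tmp_path):
        from paleofam.io import read_anchor_table, read_fasta, read_gff3

        ds = simulate_dataset(_tiny_config())
        ds.write(tmp_path)
        for sp in ds.species:
            cds = read_fasta(tmp_path / f"{sp}.cds.fasta", "cds")
            assert cds.sequences == ds.cds[sp].sequences
            assert read_gff3(tmp_path / f"{sp}.gff3", sp) == ds.genes[sp]
        anchors = read_anchor_table(tmp_path / "anchors.tsv")
        assert [(a, b) for a, b, _ in anchors] == [(a, b) for a, b, _ in ds.anchors]


class TestDivergence:
    def test_wgd_pair_ks_centers_on_the_neutral_expectation(self):
        # pairs split 10 My ago: expected Ks = 2 * lambda * t = 0.30
        rng = np.random.default_rng(10)
        cds0, _, _ = generate_ancestral_family(1, gene_codons=150, seed=5)
        cds = next(iter(cds0.sequences.values()))
        values = []
        for _ in range(100):
            a, _, _ = diverge_cds(cds, 10e6, rng=rng)
            b, _, _ = diverge_cds(cds, 10e6, rng=rng)
            est = dnds.estimate_pair(
                dnds.translate_cds(a), dnds.translate_cds(b), a, b
            )
            values.append(est.ds)
        mean = float(np.mean(values))
        assert abs(mean - 0.30) / 0.30 < 0.10

    def test_synonymous_only_divergence_keeps_dn_near_zero(self):
        rng = np.random.default_rng(11)
        cds0, _, _ = generate_ancestral_family(1, gene_codons=120, seed=6)
        cds = next(iter(cds0.sequences.values()))
        values = []
        for _ in range(200):
            a, _, na = diverge_cds(cds, 8e6, omega=0.0, rng=rng)
            b, _, nb = diverge_cds(cds, 8e6, omega=0.0, rng=rng)
            assert na == nb == 0
            est = dnds.estimate_pair(
                dnds.translate_cds(a), dnds.translate_cds(b), a, b
            )
            values.append(est.dn)
        assert abs(float(np.mean(values))) < 0.005

    def test_synonymous_counts_are_poisson_distributed(self):
        # realized synonymous substitutions per branch ~ Poisson(lambda*S*t)
        rng = np.random.default_rng(12)
        cds0, _, _ = generate_ancestral_family(1, gene_codons=100, seed=7)
        cds = next(iter(cds0.sequences.values()))
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        s_sites = sum(dnds.ng86_sites(c)[0] for c in codons)
        t = 2e6  # short branch: site composition barely drifts
        mu = LAMBDA * s_sites * t
        counts = [diverge_cds(cds, t, omega=0.0, rng=rng)[1] for _ in range(1000)]
        kmax = int(stats.poisson.ppf(0.995, mu)) + 1
        observed = np.bincount(counts, minlength=kmax + 1)[: kmax + 1].astype(float)
        observed[kmax] += sum(1 for c in counts if c > kmax)
        expected = stats.poisson.pmf(np.arange(kmax), mu) * len(counts)
        expected = np.append(expected, len(counts) - expected.sum())
        keep = expected > 1.0
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        pvalue = stats.chi2.sf(chi2, keep.sum() - 1)
        assert pvalue > 0.01
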