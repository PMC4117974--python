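"""End-to-end orchestration: identify -> homology -> dN/dS -> clustering ->
synteny -> duplication classification -> retention matrix.

Every stage is a pure function of its inputs and the configuration, so a
re-run on identical inputs produces byte-identical reports.  The run
manifest records every threshold, the seed and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import dnds, homology, ksclust, motifs, synteny
from .io import (
    GeneRecord,
    SequenceSet,
    read_anchor_table,
    read_domain_table,
    read_fasta,
    read_gff3,
    write_tsv_report,
)


@dataclass
class SpeciesInput:
    protein_fasta: str = ""
    cds_fasta: str = ""
    gff3: str = ""
    domain_tsv: str = ""


@dataclass
class PipelineConfig:
    species: dict[str, SpeciesInput] = field(default_factory=dict)
    anchor_tsv: str = ""
    outdir: str = "paleofam_out"
    min_repeats: int = 2
    require_domain: bool = False
    min_aligned: int = 300
    min_identity: float = 0.40
    td_window: int = 100_000
    td_max_evalue: float = 1e-25
    min_anchors: int = 5
    max_rank_gap: int = 10
    rate: float = ksclust.DEFAULT_RATE
    seed: int = 0
    # calibration: species -> [(label, lo, hi)], plus optional saturation
    calibration: dict[str, list] = field(default_factory=dict)
    saturation: dict[str, float] = field(default_factory=dict)
    # events per species ("duplication"/"triplication") for slot counts
    species_events: dict[str, list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        for name, value in (
            ("min_repeats", self.min_repeats),
            ("min_aligned", self.min_aligned),
            ("td_window", self.td_window),
            ("min_anchors", self.min_anchors),
            ("max_rank_gap", self.max_rank_gap),
        ):
            if value <= 0:
                raise ValueError(f"threshold {name} must be positive, got {value}")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass
class PipelineData:
    """In-memory per-species inputs (an alternative to file paths)."""

    proteins: dict[str, SequenceSet]
    cds: dict[str, SequenceSet]
    genes: dict[str, list[GeneRecord]]
    domains: dict[str, list] = field(default_factory=dict)
    anchors: list[tuple[str, str, float | None]] = field(default_factory=list)


def load_inputs(config: PipelineConfig) -> PipelineData:
    proteins, cds, genes, domains = {}, {}, {}, {}
    for sp, paths in config.species.items():
        proteins[sp] = read_fasta(paths.protein_fasta, "protein")
        cds[sp] = read_fasta(paths.cds_fasta, "cds")
        genes[sp] = read_gff3(paths.gff3, sp)
        if paths.domain_tsv:
            domains[sp] = read_domain_table(paths.domain_tsv)
    anchors = read_anchor_table(config.anchor_tsv) if config.anchor_tsv else []
    return PipelineData(proteins, cds, genes, domains, anchors)


@dataclass
class PipelineResult:
    family_calls: dict[str, dict[str, motifs.FamilyCall]]
    domain_tally: pd.DataFrame
    paralog_pairs: dict[str, list[homology.HomologPair]]
    paralog_groups: dict[str, list[list[str]]]
    ortholog_pairs: list[homology.HomologPair]
    estimates: dict[frozenset, dnds.SubstitutionEstimate]
    omega_summary: pd.DataFrame
    trees: dict[str, ksclust.ClusterTree]
    blocks: list[synteny.SyntenicBlock]
    anchor_ks: dict[frozenset, float]
    duplication_calls: list[synteny.DuplicationCall]
    retention: synteny.RetentionMatrix | None


def _check_cds_coverage(data: PipelineData) -> None:
    for sp, proteins in data.proteins.items():
        for gid in proteins.ids():
            if gid not in data.cds[sp]:
                raise ValueError(f"stage load [{sp}]: missing CDS for gene {gid}")


def run_pipeline(
    config: PipelineConfig, data: PipelineData | None = None
) -> PipelineResult:
    """Execute every stage and write the report bundle to ``config.outdir``."""
    config.validate()
    if data is None:
        data = load_inputs(config)
    _check_cds_coverage(data)
    os.makedirs(config.outdir, exist_ok=True)
    species_list = sorted(data.proteins)

    # stage 1: family identification
    family_calls: dict[str, dict[str, motifs.FamilyCall]] = {}
    for sp in species_list:
        calls = motifs.call_family(
            data.proteins[sp].sequences,
            sp,
            config.min_repeats,
            data.domains.get(sp, ()),
            config.require_domain,
        )
        family_calls[sp] = {c.protein_id: c for c in calls}
    tally = motifs.tally_by_domain(
        [c for sp in species_list for c in family_calls[sp].values()]
    )

    members: dict[str, list[str]] = {
        sp: sorted(g for g, c in family_calls[sp].items() if c.is_member)
        for sp in species_list
    }

    # stage 2: homology among family members
    local_cache: dict[str, dict[frozenset, homology.LocalAlignment]] = {}
    paralog_pairs: dict[str, list[homology.HomologPair]] = {}
    paralog_groups: dict[str, list[list[str]]] = {}
    for sp in species_list:
        cds = {g: data.cds[sp][g] for g in members[sp]}
        alignments = homology.all_vs_all_within(cds)
        local_cache[sp] = {
            frozenset((a.query_id, a.subject_id)): a for a in alignments
        }
        pairs, groups = homology.call_paralogs(
            alignments, config.min_aligned, config.min_identity
        )
        paralog_pairs[sp] = pairs
        paralog_groups[sp] = groups

    ortholog_pairs: list[homology.HomologPair] = []
    for i, sp_a in enumerate(species_list):
        for sp_b in species_list[i + 1 :]:
            cds_a = {g: data.cds[sp_a][g] for g in members[sp_a]}
            cds_b = {g: data.cds[sp_b][g] for g in members[sp_b]}
            hits_ab = homology.all_vs_all_between(cds_a, cds_b)
            hits_ba = [
                homology.LocalAlignment(
                    h.subject_id, h.query_id, h.score, h.aligned_length,
                    h.identity, h.evalue, h.subject_span, h.query_span,
                )
                for h in hits_ab
            ]
            ortholog_pairs.extend(
                homology.call_orthologs(hits_ab, hits_ba, config.min_aligned)
            )

    # stage 3: dN/dS for called pairs and all within-group pairs
    estimates: dict[frozenset, dnds.SubstitutionEstimate] = {}

    def estimate(sp_a: str, a: str, sp_b: str, b: str) -> dnds.SubstitutionEstimate:
        key = frozenset((a, b))
        if key not in estimates:
            estimates[key] = dnds.estimate_pair(
                data.proteins[sp_a][a], data.proteins[sp_b][b],
                data.cds[sp_a][a], data.cds[sp_b][b], a, b,
            )
        return estimates[key]

    omega_rows = []
    for sp in species_list:
        for pair in paralog_pairs[sp]:
            est = estimate(sp, pair.gene_a, sp, pair.gene_b)
            omega_rows.append(("paralog", sp, est))
    species_of = {
        g: sp for sp in species_list for g in data.proteins[sp].ids()
    }
    for pair in ortholog_pairs:
        sp_a, sp_b = species_of[pair.gene_a], species_of[pair.gene_b]
        est = estimate(sp_a, pair.gene_a, sp_b, pair.gene_b)
        omega_rows.append(("ortholog", f"{sp_a}|{sp_b}", est))
    omega_summary = dnds.summarize_omega(omega_rows)

    # stage 4: median-Ks clustering of each paralog group (>= 3 genes)
    trees: dict[str, ksclust.ClusterTree] = {}
    for sp in species_list:
        for group in paralog_groups[sp]:
            if len(group) < 3:
                continue
            pairs_ks = {}
            for i, a in enumerate(group):
                for b in group[i + 1 :]:
                    est = estimate(sp, a, sp, b)
                    ks = est.ds if not est.ds_saturated else None
                    pairs_ks[frozenset((a, b))] = ks
            matrix = ksclust.KsMatrix.from_pairs(group, pairs_ks)
            trees[f"{sp}:{group[0]}"] = ksclust.median_ks_linkage(matrix)

    # stage 5: synteny blocks from anchors, with NG86 Ks per anchor
    gene_index: dict[str, GeneRecord] = {
        r.gene_id: r for sp in species_list for r in data.genes[sp]
    }
    anchor_objs: list[synteny.AnchorPair] = []
    anchor_ks: dict[frozenset, float] = {}
    for a, b, ks in data.anchors:
        if a not in gene_index or b not in gene_index:
            raise ValueError(f"stage synteny: anchor gene not in annotation: {a}/{b}")
        if ks is None:
            sp_a, sp_b = species_of[a], species_of[b]
            est = estimate(sp_a, a, sp_b, b)
            ks = None if est.ds_saturated else est.ds
        if ks is not None:
            anchor_ks[frozenset((a, b))] = ks
        anchor_objs.append(synteny.AnchorPair(gene_index[a], gene_index[b], ks))
    blocks = synteny.find_collinear_blocks(
        anchor_objs, config.min_anchors, config.max_rank_gap
    )
    calibrations = {
        sp: synteny.WgdCalibration(
            [tuple(iv) for iv in intervals], config.saturation.get(sp)
        )
        for sp, intervals in config.calibration.items()
    }
    synteny.annotate_blocks(blocks, calibrations, anchor_ks)

    # stage 6: duplication mechanism per paralog pair
    block_index = synteny.index_block_anchors(blocks)
    duplication_calls = []
    for sp in species_list:
        for pair in paralog_pairs[sp]:
            aln = local_cache[sp][frozenset((pair.gene_a, pair.gene_b))]
            duplication_calls.append(
                synteny.classify_duplication(
                    gene_index[pair.gene_a],
                    gene_index[pair.gene_b],
                    blocks,
                    aln.evalue,
                    config.td_window,
                    config.td_max_evalue,
                    block_index,
                )
            )

    # stage 7: retention matrix
    retention = None
    if config.species_events:
        slots = {
            sp: synteny.expected_multiplicity(events)
            for sp, events in config.species_events.items()
        }
        all_calls = {
            g: c for sp in species_list for g, c in family_calls[sp].items()
        }
        retention = synteny.build_retention_matrix(
            blocks, all_calls, gene_index, slots, config.td_window, anchor_objs
        )

    result = PipelineResult(
        family_calls, tally, paralog_pairs, paralog_groups, ortholog_pairs,
        estimates, omega_summary, trees, blocks, anchor_ks, duplication_calls,
        retention,
    )
    _write_reports(config, result)
    return result


def _write_reports(config: PipelineConfig, result: PipelineResult) -> None:
    out = config.outdir

    membership = [
        {
            "protein_id": c.protein_id,
            "species": c.species,
            "repeat_count": c.repeat_count,
            "is_member": c.is_member,
            "domain_ids": ",".join(sorted(c.domain_ids)),
        }
        for sp in sorted(result.family_calls)
        for c in result.family_calls[sp].values()
    ]
    write_tsv_report(
        membership, os.path.join(out, "membership.tsv"),
        ["protein_id", "species", "repeat_count", "is_member", "domain_ids"],
    )
    result.domain_tally.to_csv(os.path.join(out, "domain_tally.tsv"), sep="\t", index=False)

    group_id: dict[str, str] = {}
    for sp in sorted(result.paralog_groups):
        for group in result.paralog_groups[sp]:
            for g in group:
                group_id[g] = f"{sp}:{group[0]}"
    paralog_rows = [
        {
            "gene_a": p.gene_a,
            "gene_b": p.gene_b,
            "group_id": group_id.get(p.gene_a, ""),
            "aligned_length": p.aligned_length,
            "identity": round(p.identity, 4),
        }
        for sp in sorted(result.paralog_pairs)
        for p in result.paralog_pairs[sp]
    ]
    write_tsv_report(
        paralog_rows, os.path.join(out, "paralogs.tsv"),
        ["gene_a", "gene_b", "group_id", "aligned_length", "identity"],
    )
    ortholog_rows = [
        {
            "gene_a": p.gene_a,
            "gene_b": p.gene_b,
            "aligned_length": p.aligned_length,
            "identity": round(p.identity, 4),
        }
        for p in result.ortholog_pairs
    ]
    write_tsv_report(
        ortholog_rows, os.path.join(out, "orthologs.tsv"),
        ["gene_a", "gene_b", "aligned_length", "identity"],
    )

    dnds_rows = []
    for key in sorted(result.estimates, key=sorted):
        est = result.estimates[key]
        dnds_rows.append(
            {
                "gene_a": est.gene_a,
                "gene_b": est.gene_b,
                "syn_sites": round(est.syn_sites, 3),
                "nonsyn_sites": round(est.nonsyn_sites, 3),
                "syn_diffs": round(est.syn_diffs, 3),
                "nonsyn_diffs": round(est.nonsyn_diffs, 3),
                "dn": round(est.dn, 5) if not est.dn_saturated else "inf",
                "ds": round(est.ds, 5) if not est.ds_saturated else "inf",
                "omega": round(est.omega, 5) if est.omega is not None else "NA",
            }
        )
    write_tsv_report(
        dnds_rows, os.path.join(out, "dnds.tsv"),
        ["gene_a", "gene_b", "syn_sites", "nonsyn_sites", "syn_diffs",
         "nonsyn_diffs", "dn", "ds", "omega"],
    )
    result.omega_summary.to_csv(os.path.join(out, "omega_summary.tsv"), sep="\t", index=False)

    with open(os.path.join(out, "trees.nwk"), "w") as handle:
        for name in sorted(result.trees):
            handle.write(f"{ksclust.to_newick(result.trees[name])}\n")
    node_rows = []
    for name in sorted(result.trees):
        table = ksclust.node_table(result.trees[name], config.rate)
        table.insert(0, "group", name)
        node_rows.append(table)
    if node_rows:
        pd.concat(node_rows).to_csv(os.path.join(out, "tree_nodes.tsv"), sep="\t", index=False)
    else:
        pd.DataFrame(columns=["group", "node_id", "members", "median_ks", "date_years"]).to_csv(
            os.path.join(out, "tree_nodes.tsv"), sep="\t", index=False
        )

    block_rows = [
        {
            "block_id": b.block_id,
            "species_a": b.species_a,
            "chromosome_a": b.chromosome_a,
            "species_b": b.species_b,
            "chromosome_b": b.chromosome_b,
            "n_anchors": len(b.anchors),
            "orientation": b.orientation,
            "median_ks": round(b.median_ks, 5) if b.median_ks is not None else "NA",
            "assigned_event": b.assigned_event,
        }
        for b in result.blocks
    ]
    write_tsv_report(
        block_rows, os.path.join(out, "blocks.tsv"),
        ["block_id", "species_a", "chromosome_a", "species_b", "chromosome_b",
         "n_anchors", "orientation", "median_ks", "assigned_event"],
    )
    write_tsv_report(
        result.duplication_calls, os.path.join(out, "duplication_calls.tsv"),
        ["gene_a", "gene_b", "mechanism", "event", "block_id"],
    )
    if result.retention is not None:
        result.retention.to_frame().to_csv(
            os.path.join(out, "retention_matrix.tsv"), sep="\t", index=False
        )

    manifest = {
        "config": _config_dict(config),
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "notes": (
            "dN/dS estimated with the in-package NG86 counting estimator "
            "(Jukes-Cantor corrected); collinear blocks from the in-package "
            "rank-chaining finder"
        ),
    }
    with open(os.path.join(out, "manifest.json"), "w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)


def _config_dict(config: PipelineConfig) -> dict:
    raw = dataclasses.asdict(config)
    return json.loads(json.dumps(raw, default=str, sort_keys=True))


def summarize_counts(
    member_counts: Mapping[str, int], baseline_species: str
) -> pd.DataFrame:
    """Per-species member counts and ratios relative to a baseline species.

    Ratios are count / baseline count rounded to one decimal.
    """
    if baseline_species not in member_counts:
        raise ValueError(f"unknown baseline species {baseline_species!r}")
    baseline = member_counts[baseline_species]
    if baseline == 0:
        raise ValueError(f"baseline species {baseline_species!r} has zero members")
    rows = [
        {
            "species": sp,
            "members": count,
            "ratio": round(count / baseline, 1),
        }
        for sp, count in sorted(
            member_counts.items(), key=lambda kv: (-kv[1], kv[0])
        )
    ]
    return pd.DataFrame(rows, columns=["species", "members", "ratio"])
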