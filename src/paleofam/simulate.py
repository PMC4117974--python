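"""Forward simulator of a motif-defined gene family across paleopolyploid lineages.

The simulator evolves an ancestral chromosome of family and background
genes down a lineage tree.  At a whole-genome duplication (triplication)
every chromosome is copied once (twice), preserving gene order so that
true syntenic blocks exist; each new gene copy is independently retained,
subfunctionalized (its family-defining Ser-Pro repeats are destroyed) or
lost, and contiguous chromosome segments on new copies can be lost
wholesale (the "block lost" state).  Tandem duplications insert copies
next to their source within the genomic window; dispersed duplications
insert copies at random positions.  Sequence divergence is a Poisson
process per site: each single-base change proceeds at rate lambda/3 if
synonymous and omega * lambda/3 if nonsynonymous (changes creating stop
codons are forbidden), with synonymous/nonsynonymous status recomputed
from the current codon after every substitution.  A fully synonymous site
therefore accumulates substitutions at the neutral rate lambda, and a pair
split t years ago has expected Ks = 2 * lambda * t.

Family members keep their motif because the repeat codons are protected
from nonsynonymous change — the strong purifying selection the family
shows in practice; subfunctionalized copies lose that protection along
with the motif.

Output is byte-identical in format to real inputs: per-species CDS and
protein FASTA, GFF3, a homolog anchor TSV, plus a truth log (JSON) holding
every gene's ancestral locus, birth event and fate, the per-locus slot
states per species, and the truth mechanism of every duplicate pair.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .dnds import GENETIC_CODE, translate_cds
from .io import GeneRecord, SequenceSet, write_fasta, write_gff3
from .motifs import scan_sp_repeats

DEFAULT_RATE = 1.5e-8
DEFAULT_OMEGA = 0.15

_CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(GENETIC_CODE.items()):
    _CODONS_FOR_AA.setdefault(_aa, []).append(_codon)
# serine restricted to its fourfold-degenerate TC* box so that generated
# synonymous sites follow the four-state dynamics the Jukes-Cantor
# correction models (see the composition note in docs/methods.md)
_CODONS_FOR_AA["S"] = ["TCA", "TCC", "TCG", "TCT"]


@dataclass
class LineageNode:
    """A node of the lineage tree.

    ``age`` is the node's time in years ago (split time for internal
    nodes, 0 for leaves); ``events`` lists (label, type, time) WGDs on the
    branch leading into the node, with type ``duplication`` or
    ``triplication``.
    """

    name: str
    age: float
    children: list["LineageNode"] = field(default_factory=list)
    events: list[tuple[str, str, float]] = field(default_factory=list)

    def leaves(self) -> list["LineageNode"]:
        if not self.children:
            return [self]
        out: list[LineageNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out


def default_tree() -> LineageNode:
    """Three lineages: a WGD shared by sp1/sp2 at 50 My and one specific
    to sp1 at 10 My; sp3 is the undisturbed baseline."""
    sp1 = LineageNode("sp1", 0.0, events=[("wgd_recent", "duplication", 10e6)])
    sp2 = LineageNode("sp2", 0.0)
    sp3 = LineageNode("sp3", 0.0)
    anc12 = LineageNode(
        "anc12", 45e6, [sp1, sp2], events=[("wgd_shared", "duplication", 50e6)]
    )
    return LineageNode("root", 60e6, [anc12, sp3])


@dataclass
class SimConfig:
    """Study conditions for the simulation.

    Probabilities are per new duplicate; rates are per gene per year.
    Retention/subfunctionalization/loss of family duplicates must sum to
    at most 1 (the remainder is loss).
    """

    seed: int = 0
    root_age: float = 62e6
    tree: LineageNode = field(default_factory=default_tree)
    n_family: int = 25
    n_background: int = 75
    gene_codons: int = 150
    motif_repeats: int = 3
    spacing: int = 20_000
    p_family_retained: float = 0.45
    p_family_subfun: float = 0.30
    p_background_retained: float = 0.60
    p_segment_loss: float = 0.12
    mean_segment_genes: int = 20
    td_rate: float = 2e-9
    other_rate: float = 1e-9
    rate: float = DEFAULT_RATE
    omega: float = DEFAULT_OMEGA

    def __post_init__(self) -> None:
        for p in (
            self.p_family_retained,
            self.p_family_subfun,
            self.p_background_retained,
            self.p_segment_loss,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.p_family_retained + self.p_family_subfun > 1.0:
            raise ValueError("family retention + subfunctionalization > 1")
        if self.rate <= 0:
            raise ValueError("neutral rate must be positive")
        ages = [self.tree.age] + [t for _, _, t in _all_events(self.tree)]
        if max(ages) > self.root_age:
            raise ValueError(
                f"event or split time {max(ages)} exceeds root age {self.root_age}"
            )


def _all_events(node: LineageNode) -> list[tuple[str, str, float]]:
    events = list(node.events)
    for child in node.children:
        events.extend(_all_events(child))
    return events


def expected_pairwise_ks(split_time: float, rate: float = DEFAULT_RATE) -> float:
    """Expected synonymous divergence of a pair split t years ago: 2*rate*t."""
    if split_time < 0:
        raise ValueError(f"negative split time {split_time}")
    return 2.0 * rate * split_time


# ---------------------------------------------------------------------------
# sequence machinery


_CHANGE_CACHE: dict[str, list[tuple[int, str, bool]]] = {}


def _codon_changes(codon: str) -> list[tuple[int, str, bool]]:
    """Sense single-base changes of a codon: (position, new base, is_syn)."""
    cached = _CHANGE_CACHE.get(codon)
    if cached is not None:
        return cached
    aa = GENETIC_CODE[codon]
    changes = []
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            new_aa = GENETIC_CODE[mutant]
            if new_aa == "*":
                continue  # substitutions to stop codons are forbidden
            changes.append((pos, base, new_aa == aa))
    _CHANGE_CACHE[codon] = changes
    return changes


def diverge_cds(
    cds: str,
    years: float,
    rate: float = DEFAULT_RATE,
    omega: float = DEFAULT_OMEGA,
    rng: np.random.Generator | None = None,
    protected: frozenset[int] = frozenset(),
) -> tuple[str, int, int]:
    """Evolve a CDS for ``years`` and return (new_cds, syn_count, nonsyn_count).

    ``protected`` lists codon indices where nonsynonymous changes are
    disallowed (motif codons of retained family members).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    n = len(codons)

    def codon_rate(i: int) -> float:
        total = 0.0
        for _pos, _base, is_syn in _codon_changes(codons[i]):
            if is_syn:
                total += rate / 3.0
            elif i not in protected:
                total += omega * rate / 3.0
        return total

    rates = np.array([codon_rate(i) for i in range(n)])
    total = rates.sum()
    t = 0.0
    syn_count = nonsyn_count = 0
    while total > 0:
        t += rng.exponential(1.0 / total)
        if t > years:
            break
        u = rng.random() * total
        i = int(np.searchsorted(np.cumsum(rates), u, side="right"))
        i = min(i, n - 1)
        options = []
        weights = []
        for pos, base, is_syn in _codon_changes(codons[i]):
            if is_syn:
                options.append((pos, base, True))
                weights.append(rate / 3.0)
            elif i not in protected:
                options.append((pos, base, False))
                weights.append(omega * rate / 3.0)
        weights_arr = np.asarray(weights)
        k = rng.choice(len(options), p=weights_arr / weights_arr.sum())
        pos, base, is_syn = options[k]
        codons[i] = codons[i][:pos] + base + codons[i][pos + 1 :]
        if is_syn:
            syn_count += 1
        else:
            nonsyn_count += 1
        new_rate = codon_rate(i)
        total += new_rate - rates[i]
        rates[i] = new_rate
    return "".join(codons), syn_count, nonsyn_count


def _random_codon_for(aa: str, rng: np.random.Generator) -> str:
    options = _CODONS_FOR_AA[aa]
    return options[int(rng.integers(len(options)))]


def _backtranslate_random(protein: str, rng: np.random.Generator) -> str:
    return "".join(_random_codon_for(aa, rng) for aa in protein)


# spacer/tail residues: no S or P (cannot extend repeat units) and all from
# fourfold-degenerate codon boxes, so synonymous sites saturate the way the
# estimator's multiple-hit correction assumes; small residues also dominate
# real hydroxyproline-rich glycoprotein backbones
_NONMOTIF_AA = "AGTV"


def _random_family_protein(
    gene_codons: int, repeats: int, rng: np.random.Generator
) -> str:
    parts = ["M"]
    length = 1
    for r in range(repeats):
        spacer_len = int(rng.integers(4, 9))
        spacer = "".join(
            _NONMOTIF_AA[int(rng.integers(len(_NONMOTIF_AA)))] for _ in range(spacer_len)
        )
        unit = "SPPP" if rng.random() < 0.5 else "SPPPP"
        parts += [spacer, unit]
        length += spacer_len + len(unit)
    tail_len = max(0, gene_codons - length)
    tail = "".join(
        _NONMOTIF_AA[int(rng.integers(len(_NONMOTIF_AA)))] for _ in range(tail_len)
    )
    parts.append(tail)
    return "".join(parts)


def _random_background_protein(gene_codons: int, rng: np.random.Generator) -> str:
    alphabet = "AGPTVS"
    while True:
        protein = "M" + "".join(
            alphabet[int(rng.integers(len(alphabet)))] for _ in range(gene_codons - 1)
        )
        if scan_sp_repeats(protein, "background").repeat_count == 0:
            return protein


def _motif_codon_indices(cds: str) -> frozenset[int]:
    protein = translate_cds(cds)
    spans = scan_sp_repeats(protein, "motif").repeat_spans
    return frozenset(i for lo, hi in spans for i in range(lo, hi))


def _destroy_motif(cds: str) -> str:
    """Mutate the serine of all but one repeat unit so the copy no longer
    classifies as a family member (TCx -> GCx Ala, AGx -> GGx Gly)."""
    protein = translate_cds(cds)
    spans = scan_sp_repeats(protein, "subfun").repeat_spans
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for lo, _hi in spans[1:] if len(spans) > 1 else spans:
        codons[lo] = "G" + codons[lo][1:]
    return "".join(codons)


# ---------------------------------------------------------------------------
# genome model


@dataclass
class _SimGene:
    uid: int
    locus: str
    kind: str  # "family" | "background"
    cds: str
    status: str  # "member" | "subfun" | "lost" | "region_lost"
    birth: str  # "ancestral" | WGD label | "TD" | "OTHER"
    birth_time: float
    progenitor: int | None
    slot: bool  # True for ancestral/WGD copies (occupies a duplication slot)
    protected: frozenset[int] = frozenset()

    @property
    def live(self) -> bool:
        return self.status in ("member", "subfun")


@dataclass
class _SimChromosome:
    name: str
    genes: list[_SimGene]


class _Counter:
    def __init__(self) -> None:
        self.value = 0

    def next(self) -> int:
        self.value += 1
        return self.value


def generate_ancestral_family(
    n_genes: int,
    motif_repeats: int = 3,
    gene_codons: int = 150,
    spacing: int = 20_000,
    seed: int = 0,
    species: str = "ancestor",
) -> tuple[SequenceSet, SequenceSet, list[GeneRecord]]:
    """Generate an ancestral family on a linear chromosome.

    Returns (CDS set, protein set, gene records); each protein carries
    ``motif_repeats`` Ser-Pro repeat units.  Deterministic under ``seed``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if motif_repeats < 2:
        warnings.warn(
            f"motif_repeats={motif_repeats}: genes will not classify as family members",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    cds: dict[str, str] = {}
    proteins: dict[str, str] = {}
    records: list[GeneRecord] = []
    for i in range(n_genes):
        protein = _random_family_protein(gene_codons, motif_repeats, rng)
        gene_id = f"{species}_fam{i:03d}"
        proteins[gene_id] = protein
        cds[gene_id] = _backtranslate_random(protein, rng)
        start = i * spacing
        records.append(
            GeneRecord(gene_id, species, "chr1", start, start + 3 * len(protein), "+", i)
        )
    return SequenceSet(cds, "cds"), SequenceSet(proteins, "protein"), records


@dataclass
class SimulatedDataset:
    """In-memory bundle of everything the simulator emits."""

    species: list[str]
    cds: dict[str, SequenceSet]
    proteins: dict[str, SequenceSet]
    genes: dict[str, list[GeneRecord]]
    anchors: list[tuple[str, str, float | None]]
    truth: dict
    species_events: dict[str, list[str]]

    def write(self, outdir: str | os.PathLike) -> None:
        os.makedirs(outdir, exist_ok=True)
        for sp in self.species:
            write_fasta(self.cds[sp].sequences, os.path.join(outdir, f"{sp}.cds.fasta"))
            write_fasta(
                self.proteins[sp].sequences, os.path.join(outdir, f"{sp}.protein.fasta")
            )
            write_gff3(self.genes[sp], os.path.join(outdir, f"{sp}.gff3"))
        with open(os.path.join(outdir, "anchors.tsv"), "w") as handle:
            handle.write("gene_a\tgene_b\tks\n")
            for a, b, ks in self.anchors:
                handle.write(f"{a}\t{b}\t{'' if ks is None else ks}\n")
        with open(os.path.join(outdir, "truth.json"), "w") as handle:
            json.dump(self.truth, handle, indent=1, sort_keys=True)


def simulate_dataset(config: SimConfig | None = None) -> SimulatedDataset:
    """Run the forward simulation and collect per-species outputs + truth."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    counter = _Counter()

    # ancestral genome: family genes every 4th position among background genes
    genome: list[_SimChromosome] = []
    genes: list[_SimGene] = []
    n_total = config.n_family + config.n_background
    family_positions = set(
        np.linspace(0, n_total - 1, config.n_family).astype(int).tolist()
    )
    fam_i = bg_i = 0
    for pos in range(n_total):
        if pos in family_positions:
            locus = f"fam{fam_i:03d}"
            fam_i += 1
            protein = _random_family_protein(
                config.gene_codons, config.motif_repeats, rng
            )
            cds = _backtranslate_random(protein, rng)
            gene = _SimGene(
                counter.next(), locus, "family", cds, "member", "ancestral",
                config.root_age, None, True, _motif_codon_indices(cds),
            )
        else:
            locus = f"bg{bg_i:03d}"
            bg_i += 1
            protein = _random_background_protein(config.gene_codons, rng)
            cds = _backtranslate_random(protein, rng)
            gene = _SimGene(
                counter.next(), locus, "background", cds, "member", "ancestral",
                config.root_age, None, True,
            )
        genes.append(gene)
    genome.append(_SimChromosome("c0", genes))

    leaf_genomes: dict[str, list[_SimChromosome]] = {}
    _descend(genome, config.root_age, config.tree, config, rng, counter, leaf_genomes)

    return _emit(leaf_genomes, config)


def _descend(
    genome: list[_SimChromosome],
    t_start: float,
    node: LineageNode,
    config: SimConfig,
    rng: np.random.Generator,
    counter: _Counter,
    leaf_genomes: dict[str, list[_SimChromosome]],
) -> None:
    events = sorted(node.events, key=lambda e: -e[2])
    t_cur = t_start
    for label, etype, time in events:
        if not (node.age <= time <= t_start):
            raise ValueError(
                f"event {label} at {time} outside branch ({t_start}, {node.age})"
            )
        _evolve_segment(genome, t_cur - time, config, rng, counter, time)
        _apply_wgd(genome, label, etype, time, config, rng, counter)
        t_cur = time
    _evolve_segment(genome, t_cur - node.age, config, rng, counter, node.age)
    if not node.children:
        leaf_genomes[node.name] = genome
        return
    for child in node.children:
        child_genome, _ = _clone_genome(genome, counter)
        _descend(child_genome, node.age, child, config, rng, counter, leaf_genomes)


def _clone_genome(
    genome: list[_SimChromosome], counter: _Counter
) -> tuple[list[_SimChromosome], dict[int, int]]:
    """Deep copy with fresh uids; progenitor references are rewritten."""
    uid_map: dict[int, int] = {}
    cloned: list[_SimChromosome] = []
    for chrom in genome:
        new_genes = []
        for gene in chrom.genes:
            new_uid = counter.next()
            uid_map[gene.uid] = new_uid
            new_genes.append(replace(gene, uid=new_uid))
        cloned.append(_SimChromosome(chrom.name, new_genes))
    for chrom in cloned:
        for gene in chrom.genes:
            if gene.progenitor is not None:
                gene.progenitor = uid_map.get(gene.progenitor, gene.progenitor)
    return cloned, uid_map


def _evolve_segment(
    genome: list[_SimChromosome],
    duration: float,
    config: SimConfig,
    rng: np.random.Generator,
    counter: _Counter,
    t_end: float,
) -> None:
    """Diverge sequences over ``duration`` years with tandem/dispersed births."""
    if duration <= 0:
        return
    t_start = t_end + duration
    births: list[tuple[float, str, _SimChromosome, _SimGene]] = []
    for chrom in genome:
        for gene in chrom.genes:
            if gene.kind != "family" or gene.status != "member":
                continue
            for kind, gene_rate in (("TD", config.td_rate), ("OTHER", config.other_rate)):
                for _ in range(rng.poisson(gene_rate * duration)):
                    births.append(
                        (float(rng.uniform(t_end, t_start)), kind, chrom, gene)
                    )
    births.sort(key=lambda b: (-b[0], b[1], b[3].uid))
    t_cur = t_start
    for time, kind, chrom, source in births:
        _diverge_all(genome, t_cur - time, config, rng)
        t_cur = time
        copy = replace(
            source,
            uid=counter.next(),
            birth=kind,
            birth_time=time,
            progenitor=source.uid,
            slot=False,
        )
        if kind == "TD":
            idx = chrom.genes.index(source)
            chrom.genes.insert(idx + 1, copy)
        else:
            target = genome[int(rng.integers(len(genome)))]
            target.genes.insert(int(rng.integers(len(target.genes) + 1)), copy)
    _diverge_all(genome, t_cur - t_end, config, rng)


def _diverge_all(
    genome: list[_SimChromosome],
    duration: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> None:
    if duration <= 0:
        return
    for chrom in genome:
        for gene in chrom.genes:
            if not gene.live:
                continue
            protected = gene.protected if gene.status == "member" else frozenset()
            gene.cds, _, _ = diverge_cds(
                gene.cds, duration, config.rate, config.omega, rng, protected
            )


def _apply_wgd(
    genome: list[_SimChromosome],
    label: str,
    etype: str,
    time: float,
    config: SimConfig,
    rng: np.random.Generator,
    counter: _Counter,
) -> None:
    if etype not in ("duplication", "triplication"):
        raise ValueError(f"unknown event type {etype!r}")
    n_copies = 1 if etype == "duplication" else 2
    for chrom in list(genome):
        for c in range(n_copies):
            new_genes: list[_SimGene] = []
            for gene in chrom.genes:
                copy = replace(
                    gene,
                    uid=counter.next(),
                    birth=label,
                    birth_time=time,
                    progenitor=gene.uid,
                    slot=gene.slot,
                )
                if gene.status in ("lost", "region_lost"):
                    copy.status = gene.status
                elif gene.kind == "background":
                    if rng.random() >= config.p_background_retained:
                        copy.status = "lost"
                elif gene.status == "subfun":
                    pass  # subfunctionalized copies stay subfunctionalized
                else:
                    u = rng.random()
                    if u < config.p_family_retained:
                        pass
                    elif u < config.p_family_retained + config.p_family_subfun:
                        copy.status = "subfun"
                        copy.cds = _destroy_motif(copy.cds)
                        copy.protected = frozenset()
                    else:
                        copy.status = "lost"
                new_genes.append(copy)
            _drop_segments(new_genes, config, rng)
            genome.append(_SimChromosome(f"{chrom.name}.{label}{c}", new_genes))


def _drop_segments(
    genes: list[_SimGene], config: SimConfig, rng: np.random.Generator
) -> None:
    """Delete contiguous runs of genes from a fresh chromosome copy."""
    i = 0
    n = len(genes)
    while i < n:
        run = int(rng.geometric(1.0 / config.mean_segment_genes))
        if rng.random() < config.p_segment_loss:
            for gene in genes[i : i + run]:
                gene.status = "region_lost"
        i += run


def _species_events(tree: LineageNode) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}

    def walk(node: LineageNode, acc: list[str]) -> None:
        acc = acc + [etype for _, etype, _ in sorted(node.events, key=lambda e: -e[2])]
        if not node.children:
            out[node.name] = acc
            return
        for child in node.children:
            walk(child, acc)

    walk(tree, [])
    return out


def _emit(
    leaf_genomes: dict[str, list[_SimChromosome]], config: SimConfig
) -> SimulatedDataset:
    species = sorted(leaf_genomes)
    cds_sets: dict[str, SequenceSet] = {}
    protein_sets: dict[str, SequenceSet] = {}
    gene_records: dict[str, list[GeneRecord]] = {}
    public_id: dict[tuple[str, int], str] = {}
    truth_genes: dict[str, dict] = {}
    locus_of: dict[str, str] = {}
    births = losses = 0

    for sp in species:
        chromosomes = sorted(leaf_genomes[sp], key=lambda c: c.name)
        cds: dict[str, str] = {}
        proteins: dict[str, str] = {}
        records: list[GeneRecord] = []
        gene_counter = 0
        for chrom_idx, chrom in enumerate(chromosomes):
            chrom_name = f"chr{chrom_idx + 1}"
            rank = 0
            for gene in chrom.genes:
                births += 1
                if not gene.live:
                    losses += 1
                    continue
                gene_counter += 1
                gid = f"{sp}_g{gene_counter:04d}"
                public_id[(sp, gene.uid)] = gid
                locus_of[gid] = gene.locus
                start = rank * config.spacing
                records.append(
                    GeneRecord(
                        gid, sp, chrom_name, start, start + len(gene.cds), "+", rank
                    )
                )
                cds[gid] = gene.cds
                proteins[gid] = translate_cds(gene.cds, gid)
                rank += 1
        cds_sets[sp] = SequenceSet(cds, "cds")
        protein_sets[sp] = SequenceSet(proteins, "protein")
        gene_records[sp] = records

    fates = {
        "member": "retained",
        "subfun": "subfunctionalized",
        "lost": "lost",
        "region_lost": "region_lost",
    }
    truth_pairs: list[dict] = []
    slots: dict[str, dict[str, list[str]]] = {}
    for sp in species:
        for chrom in sorted(leaf_genomes[sp], key=lambda c: c.name):
            for gene in chrom.genes:
                gid = public_id.get((sp, gene.uid))
                if gid is not None:
                    prog = public_id.get((sp, gene.progenitor)) if gene.progenitor else None
                    truth_genes[gid] = {
                        "locus": gene.locus,
                        "species": sp,
                        "kind": gene.kind,
                        "birth": gene.birth,
                        "birth_time": gene.birth_time,
                        "fate": fates[gene.status],
                        "progenitor": prog,
                        "slot": gene.slot,
                    }
                    if (
                        gene.kind == "family"
                        and gene.birth != "ancestral"
                        and prog is not None
                    ):
                        mechanism = (
                            gene.birth if gene.birth in ("TD", "OTHER") else "SWGD"
                        )
                        truth_pairs.append(
                            {
                                "gene_a": min(gid, prog),
                                "gene_b": max(gid, prog),
                                "mechanism": mechanism,
                                "event": "" if mechanism != "SWGD" else gene.birth,
                            }
                        )
                if gene.kind == "family" and gene.slot:
                    state = {
                        "member": "E",
                        "subfun": "N",
                        "lost": "L",
                        "region_lost": "B",
                    }[gene.status]
                    slots.setdefault(gene.locus, {}).setdefault(sp, []).append(state)
    for locus in slots:
        for sp in slots[locus]:
            slots[locus][sp].sort()

    anchors: list[tuple[str, str, float | None]] = []
    by_locus: dict[str, list[str]] = {}
    for gid, locus in locus_of.items():
        by_locus.setdefault(locus, []).append(gid)
    for locus in sorted(by_locus):
        members = sorted(by_locus[locus])
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                anchors.append((a, b, None))

    truth = {
        "genes": truth_genes,
        "slots": slots,
        "pairs": sorted(truth_pairs, key=lambda p: (p["gene_a"], p["gene_b"])),
        "bookkeeping": {"births": births, "losses": losses, "final": births - losses},
        "config": {
            "seed": config.seed,
            "rate": config.rate,
            "omega": config.omega,
            "n_family": config.n_family,
            "n_background": config.n_background,
        },
    }
    return SimulatedDataset(
        species,
        cds_sets,
        protein_sets,
        gene_records,
        anchors,
        truth,
        _species_events(config.tree),
    )
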