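"""Collinear blocks, WGD assignment, tandem duplications and the retention matrix.

Syntenic chromosomal blocks (SCBs) are detected as maximal chains of
homolog anchor pairs whose gene ranks are strictly monotone on both
chromosomes (both orientations are tried), with consecutive anchors no more
than ``max_rank_gap`` ranks apart on either side and at least
``min_anchors`` anchors per block.  Chains are extracted greedily, longest
first, and each anchor belongs to at most one block.

Genes duplicated together on an SCB pair duplicated simultaneously, so the
median Ks over a block's anchors dates the block: a calibration table of
closed Ks intervals per species maps block median Ks to a named
paleopolyploidy event (e.g. the salicoid P-duplication at median Ks
0.2437-0.3345, the ancient gamma-triplication at 1.2633-1.7896).  Blocks
whose median Ks exceeds a saturation threshold are labelled indistinguishable
rather than assigned to a single ancient event.

Tandem duplicates are same-chromosome pairs within a 100-kb window whose
alignment E-value is at most 1e-25.  Each paralog pair is classified by
precedence SWGD > TD > OTHER: block membership is stronger positional
evidence than mere proximity.

The retention matrix is the cross-species summary: rows are ancestral loci
(connected components of block-linked genes), columns are per-species
duplication slots (one per expected post-baseline copy), and each cell is
E (retained family member), N (present but subfunctionalized out of the
family), L (gene lost but the block retained) or B (block lost entirely).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .homology import UnionFind
from .io import GeneRecord
from .motifs import FamilyCall

UNASSIGNED = "unassigned"
SATURATED_LABEL = "beta/gamma-indistinguishable"


@dataclass
class AnchorPair:
    gene_a: GeneRecord
    gene_b: GeneRecord
    ks: float | None = None

    def key(self) -> frozenset:
        return frozenset((self.gene_a.gene_id, self.gene_b.gene_id))


@dataclass
class SyntenicBlock:
    block_id: int
    species_a: str
    species_b: str
    chromosome_a: str
    chromosome_b: str
    anchors: list[AnchorPair]
    orientation: str  # "same" | "inverted"
    median_ks: float | None = None
    assigned_event: str = UNASSIGNED

    @property
    def span_a(self) -> tuple[int, int]:
        ranks = [a.gene_a.rank for a in self.anchors]
        return min(ranks), max(ranks)

    @property
    def span_b(self) -> tuple[int, int]:
        ranks = [a.gene_b.rank for a in self.anchors]
        return min(ranks), max(ranks)


@dataclass
class WgdCalibration:
    """Closed Ks intervals per event label, with an optional saturation cutoff.

    Intervals must not overlap; a block median above ``saturation`` is
    labelled ``saturation_label`` instead of remaining unassigned.
    """

    intervals: list[tuple[str, float, float]]
    saturation: float | None = None
    saturation_label: str = SATURATED_LABEL

    def __post_init__(self) -> None:
        ordered = sorted(self.intervals, key=lambda iv: iv[1])
        for (la, lo_a, hi_a), (lb, lo_b, hi_b) in zip(ordered, ordered[1:]):
            if lo_b <= hi_a:
                raise ValueError(
                    f"overlapping calibration intervals {la} [{lo_a}, {hi_a}] and "
                    f"{lb} [{lo_b}, {hi_b}]"
                )
        for label, lo, hi in self.intervals:
            if lo > hi:
                raise ValueError(f"calibration interval {label}: lo {lo} > hi {hi}")


# the printed within-species calibrations for the rosids studied here:
# Populus (P-duplication, gamma-triplication) and Arabidopsis (alpha;
# beta/gamma medians sit at the Ks saturation ceiling of ~2).
POPULUS_CALIBRATION = WgdCalibration(
    [("P-WGD", 0.2437, 0.3345), ("gamma", 1.2633, 1.7896)]
)
ARABIDOPSIS_CALIBRATION = WgdCalibration(
    [("alpha-WGD", 0.783, 0.881)], saturation=1.9
)


def _orient(a: GeneRecord, b: GeneRecord) -> tuple[GeneRecord, GeneRecord]:
    if (a.species, a.chromosome, a.rank) <= (b.species, b.chromosome, b.rank):
        return a, b
    return b, a


def find_collinear_blocks(
    anchors: Sequence[AnchorPair],
    min_anchors: int = 5,
    max_rank_gap: int = 10,
) -> list[SyntenicBlock]:
    """Chain anchors into syntenic blocks, longest chain first.

    Within each (species, chromosome) pair, chains must be strictly
    increasing in rank on the first chromosome and strictly increasing
    (same orientation) or strictly decreasing (inverted) on the second,
    with consecutive anchors within ``max_rank_gap`` ranks on both sides.
    """
    groups: dict[tuple, list[AnchorPair]] = {}
    for anchor in anchors:
        a, b = _orient(anchor.gene_a, anchor.gene_b)
        oriented = AnchorPair(a, b, anchor.ks)
        key = (a.species, a.chromosome, b.species, b.chromosome)
        groups.setdefault(key, []).append(oriented)
    blocks: list[SyntenicBlock] = []
    for key in sorted(groups):
        species_a, chrom_a, species_b, chrom_b = key
        remaining = sorted(
            groups[key],
            key=lambda p: (p.gene_a.rank, p.gene_b.rank, p.gene_a.gene_id, p.gene_b.gene_id),
        )
        while True:
            chain, orientation = _longest_chain(remaining, max_rank_gap)
            if len(chain) < min_anchors:
                break
            blocks.append(
                SyntenicBlock(
                    0,
                    species_a,
                    species_b,
                    chrom_a,
                    chrom_b,
                    chain,
                    orientation,
                )
            )
            used = {id(p) for p in chain}
            remaining = [p for p in remaining if id(p) not in used]
    blocks.sort(
        key=lambda b: (
            b.species_a,
            b.chromosome_a,
            b.species_b,
            b.chromosome_b,
            b.span_a,
            b.span_b,
        )
    )
    for i, block in enumerate(blocks):
        block.block_id = i
    return blocks


def _longest_chain(
    anchors: Sequence[AnchorPair], max_rank_gap: int
) -> tuple[list[AnchorPair], str]:
    """Best monotone chain over the anchors, across both orientations.

    Ties prefer the "same" orientation, then the chain found first in the
    deterministic anchor order.
    """
    best_chain: list[AnchorPair] = []
    best_orientation = "same"
    for orientation in ("same", "inverted"):
        chain = _longest_chain_oriented(anchors, max_rank_gap, orientation)
        if len(chain) > len(best_chain):
            best_chain, best_orientation = chain, orientation
    return best_chain, best_orientation


def _longest_chain_oriented(
    anchors: Sequence[AnchorPair], max_rank_gap: int, orientation: str
) -> list[AnchorPair]:
    n = len(anchors)
    if n == 0:
        return []
    sign = 1 if orientation == "same" else -1
    # anchors are pre-sorted by (rank_a, rank_b); DP over predecessors
    length = [1] * n
    prev = [-1] * n
    for j in range(n):
        aj = anchors[j]
        for i in range(j):
            ai = anchors[i]
            da = aj.gene_a.rank - ai.gene_a.rank
            db = sign * (aj.gene_b.rank - ai.gene_b.rank)
            if da <= 0 or db <= 0:
                continue
            if da > max_rank_gap or db > max_rank_gap:
                continue
            if ai.gene_a.gene_id == aj.gene_a.gene_id or ai.gene_b.gene_id == aj.gene_b.gene_id:
                continue
            if length[i] + 1 > length[j]:
                length[j] = length[i] + 1
                prev[j] = i
    end = max(range(n), key=lambda j: length[j])
    chain = []
    while end != -1:
        chain.append(anchors[end])
        end = prev[end]
    return chain[::-1]


def block_median_ks(block: SyntenicBlock, ks_lookup: Mapping[frozenset, float] | None = None) -> float:
    """Median Ks over the block's anchors with defined, finite Ks."""
    values = []
    for anchor in block.anchors:
        ks = anchor.ks
        if ks is None and ks_lookup is not None:
            ks = ks_lookup.get(anchor.key())
        if ks is not None and math.isfinite(ks):
            values.append(ks)
    if not values:
        raise ValueError(f"block {block.block_id}: no anchor has a defined Ks")
    values.sort()
    mid = len(values) // 2
    if len(values) % 2:
        return values[mid]
    return 0.5 * (values[mid - 1] + values[mid])


def assign_wgd_event(median_ks: float, calibration: WgdCalibration) -> str:
    """Event label of the calibration interval containing ``median_ks``.

    Outside every interval the block is unassigned, unless the median
    exceeds the saturation threshold, in which case the saturation label
    is returned.
    """
    for label, lo, hi in calibration.intervals:
        if lo <= median_ks <= hi:
            return label
    if calibration.saturation is not None and median_ks >= calibration.saturation:
        return calibration.saturation_label
    return UNASSIGNED


def annotate_blocks(
    blocks: Iterable[SyntenicBlock],
    calibrations: Mapping[str, WgdCalibration],
    ks_lookup: Mapping[frozenset, float] | None = None,
) -> list[SyntenicBlock]:
    """Fill median Ks and assigned event on within-species blocks.

    Cross-species blocks get a median Ks but stay unassigned (speciation,
    not duplication, separates their anchors) unless a calibration keyed by
    ``"species_a|species_b"`` is supplied.
    """
    blocks = list(blocks)
    for block in blocks:
        try:
            block.median_ks = block_median_ks(block, ks_lookup)
        except ValueError:
            block.median_ks = None
            continue
        if block.species_a == block.species_b:
            calibration = calibrations.get(block.species_a)
        else:
            calibration = calibrations.get(f"{block.species_a}|{block.species_b}")
        if calibration is not None:
            block.assigned_event = assign_wgd_event(block.median_ks, calibration)
    return blocks


def call_tandem(
    gene_a: GeneRecord,
    gene_b: GeneRecord,
    evalue: float,
    window: int = 100_000,
    max_evalue: float = 1e-25,
) -> bool:
    """Tandem rule: same species and chromosome, start-to-start distance
    within the window, alignment E-value at most ``max_evalue``."""
    if gene_a.species != gene_b.species:
        return False
    if gene_a.chromosome != gene_b.chromosome:
        return False
    if abs(gene_a.start - gene_b.start) > window:
        return False
    return evalue <= max_evalue


@dataclass
class DuplicationCall:
    gene_a: str
    gene_b: str
    mechanism: str  # "SWGD" | "TD" | "OTHER"
    event: str = ""  # block's assigned event, SWGD only
    block_id: int | None = None


def classify_duplication(
    gene_a: GeneRecord,
    gene_b: GeneRecord,
    blocks: Sequence[SyntenicBlock],
    evalue: float,
    window: int = 100_000,
    max_evalue: float = 1e-25,
    block_index: Mapping[frozenset, SyntenicBlock] | None = None,
) -> DuplicationCall:
    """Mechanism of a paralog pair with precedence SWGD > TD > OTHER."""
    key = frozenset((gene_a.gene_id, gene_b.gene_id))
    if block_index is None:
        block_index = index_block_anchors(blocks)
    block = block_index.get(key)
    a_id, b_id = sorted((gene_a.gene_id, gene_b.gene_id))
    if block is not None:
        return DuplicationCall(a_id, b_id, "SWGD", block.assigned_event, block.block_id)
    if call_tandem(gene_a, gene_b, evalue, window, max_evalue):
        return DuplicationCall(a_id, b_id, "TD")
    return DuplicationCall(a_id, b_id, "OTHER")


def index_block_anchors(
    blocks: Iterable[SyntenicBlock],
) -> dict[frozenset, SyntenicBlock]:
    index: dict[frozenset, SyntenicBlock] = {}
    for block in blocks:
        for anchor in block.anchors:
            index.setdefault(anchor.key(), block)
    return index


def expected_multiplicity(events: Sequence[str]) -> int:
    """Expected copy number of an ancestral gene after the listed events.

    Each ``duplication`` doubles and each ``triplication`` triples the
    count; the empty list gives 1.
    """
    multiplicity = 1
    for event in events:
        if event == "duplication":
            multiplicity *= 2
        elif event == "triplication":
            multiplicity *= 3
        else:
            raise ValueError(f"unknown event type {event!r}")
    return multiplicity


@dataclass
class RetentionMatrix:
    """Per-ancestral-locus slot states across species.

    ``states[locus][species]`` is the list of slot states, length equal to
    the species' expected multiplicity, each in {"E", "N", "L", "B"}.
    ``occupants`` records which gene fills each E/N slot.
    """

    loci: list[str]
    species: list[str]
    slots: dict[str, int]
    states: dict[str, dict[str, list[str]]]
    occupants: dict[str, dict[str, list[str]]]

    def to_frame(self) -> pd.DataFrame:
        columns = ["locus"]
        for sp in self.species:
            columns += [f"{sp}_slot{i + 1}" for i in range(self.slots[sp])]
        rows = []
        for locus in self.loci:
            row: dict[str, str] = {"locus": locus}
            for sp in self.species:
                for i, state in enumerate(self.states[locus][sp]):
                    row[f"{sp}_slot{i + 1}"] = state
            rows.append(row)
        return pd.DataFrame(rows, columns=columns)

    def fraction_non_retained(self) -> float:
        """Fraction of paleopolyploidy-derived slots not retained as members
        (states N, L or B among all slots beyond the first per locus)."""
        total = lost = 0
        for locus in self.loci:
            for sp in self.species:
                for state in self.states[locus][sp]:
                    total += 1
                    if state != "E":
                        lost += 1
        return lost / total if total else float("nan")


def build_retention_matrix(
    blocks: Sequence[SyntenicBlock],
    family_calls: Mapping[str, FamilyCall],
    genes: Mapping[str, GeneRecord],
    species_slots: Mapping[str, int],
    collapse_window: int = 100_000,
    anchors: Sequence[AnchorPair] | None = None,
) -> RetentionMatrix:
    """Score every ancestral locus across species-specific duplication slots.

    Ancestral loci are the connected components of genes linked by block
    anchors (within and between species), restricted to components that
    contain at least one family member.  Raw homolog pairs from ``anchors``
    extend that connectivity so that copies outside every block (tandem or
    dispersed duplicates) still join their relatives' locus — the analog of
    assigning a non-collinear paralog to its ancestral gene through its
    paralogs.  Per species, observed component genes fill slots as E
    (member) or N (subfunctionalized non-member); same-chromosome genes
    within ``collapse_window`` collapse to one slot occupant, since tandem
    arrays descend from a single post-WGD copy, and block-anchored
    occupants take slots before unanchored ones (tandem or dispersed
    duplicates do not occupy a WGD slot while a collinear copy exists).
    A slot with no gene is L when some block covering another copy of the
    locus pairs with a chromosome of this species at the expected position,
    and B (block lost) otherwise.
    """
    uf = UnionFind()
    anchored_genes: set[str] = set()
    block_count: dict[str, int] = {}
    for block in blocks:
        for anchor in block.anchors:
            uf.union(anchor.gene_a.gene_id, anchor.gene_b.gene_id)
            for g in (anchor.gene_a.gene_id, anchor.gene_b.gene_id):
                anchored_genes.add(g)
                block_count[g] = block_count.get(g, 0) + 1
    if anchors:
        # homolog pairs outside blocks still tie copies to the same
        # ancestral gene (a dispersed paralog belongs to its paralogs' locus)
        for pair in anchors:
            uf.union(pair.gene_a.gene_id, pair.gene_b.gene_id)
    # a family member with no surviving homolog is still an ancestral locus
    for g in sorted(genes):
        if g in family_calls and family_calls[g].is_member:
            uf.find(g)
    components = uf.components()
    species = sorted(species_slots)

    loci: list[str] = []
    locus_members: dict[str, list[str]] = {}
    gene_to_locus: dict[str, str] = {}
    for root in sorted(components):
        members = components[root]
        if not any(
            family_calls[g].is_member for g in members if g in family_calls
        ):
            continue
        locus = f"locus_{min(members)}"
        loci.append(locus)
        locus_members[locus] = members
        for g in members:
            if g in gene_to_locus:
                raise ValueError(
                    f"gene {g} assigned to two ancestral loci "
                    f"({gene_to_locus[g]} and {locus})"
                )
            gene_to_locus[g] = locus

    states: dict[str, dict[str, list[str]]] = {}
    occupants: dict[str, dict[str, list[str]]] = {}
    for locus in loci:
        members = [g for g in locus_members[locus] if g in genes]
        per_species: dict[str, list[list[str]]] = {sp: [] for sp in species}
        # group observed genes into slot occupants, collapsing tandem arrays
        for g in sorted(members):
            rec = genes[g]
            if rec.species not in per_species:
                continue
            placed = False
            for cluster in per_species[rec.species]:
                head = genes[cluster[0]]
                if (
                    head.chromosome == rec.chromosome
                    and abs(head.start - rec.start) <= collapse_window
                ):
                    cluster.append(g)
                    placed = True
                    break
            if not placed:
                per_species[rec.species].append([g])
        # L evidence: blocks covering an observed copy whose partner side
        # lies in a chromosome of the target species with no locus gene there
        l_evidence: dict[str, set[tuple[str, str]]] = {sp: set() for sp in species}
        occupied_chromosomes: dict[str, set[str]] = {sp: set() for sp in species}
        for sp in species:
            for cluster in per_species[sp]:
                occupied_chromosomes[sp].add(genes[cluster[0]].chromosome)
        for g in members:
            if g not in genes:
                continue
            rec = genes[g]
            for block in blocks:
                for side, other in (("a", "b"), ("b", "a")):
                    sp_side = getattr(block, f"species_{side}")
                    chrom_side = getattr(block, f"chromosome_{side}")
                    if sp_side != rec.species or chrom_side != rec.chromosome:
                        continue
                    lo, hi = getattr(block, f"span_{side}")
                    if not (lo <= rec.rank <= hi):
                        continue
                    sp_other = getattr(block, f"species_{other}")
                    chrom_other = getattr(block, f"chromosome_{other}")
                    if sp_other not in l_evidence:
                        continue
                    if block.species_a == block.species_b and chrom_other == rec.chromosome and chrom_side == rec.chromosome:
                        # self-side of a within-chromosome block
                        continue
                    if chrom_other in occupied_chromosomes[sp_other]:
                        continue
                    l_evidence[sp_other].add((sp_other, chrom_other))
        states[locus] = {}
        occupants[locus] = {}
        for sp in species:
            n_slots = species_slots[sp]
            anchored_clusters = [
                c for c in per_species[sp] if any(g in anchored_genes for g in c)
            ]
            # collinearity support: clusters seen in more blocks take slots
            # first (a copy in one lucky chain ranks below a true WGD copy
            # anchored across several chromosome pairs)
            anchored_clusters.sort(
                key=lambda c: (-sum(block_count.get(g, 0) for g in c), c[0])
            )
            loose_clusters = [
                c for c in per_species[sp] if not any(g in anchored_genes for g in c)
            ]
            slot_states: list[str] = []
            slot_occupants: list[str] = []

            def fill(cluster: list[str]) -> None:
                is_member = any(
                    family_calls[g].is_member for g in cluster if g in family_calls
                )
                slot_states.append("E" if is_member else "N")
                slot_occupants.append(",".join(cluster))

            for cluster in anchored_clusters[:n_slots]:
                fill(cluster)
            n_l = min(len(l_evidence[sp]), n_slots - len(slot_states))
            slot_states += ["L"] * n_l
            slot_occupants += [""] * n_l
            for cluster in loose_clusters[: n_slots - len(slot_states)]:
                fill(cluster)
            n_b = n_slots - len(slot_states)
            slot_states += ["B"] * n_b
            slot_occupants += [""] * n_b
            states[locus][sp] = slot_states
            occupants[locus][sp] = slot_occupants
    return RetentionMatrix(loci, species, dict(species_slots), states, occupants)
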