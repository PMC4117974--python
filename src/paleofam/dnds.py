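"""Codon alignments and Nei-Gojobori (1986) dN/dS estimation.

A protein alignment is back-translated onto the two coding sequences to
give a codon alignment; per-codon synonymous/nonsynonymous site fractions
and pathway-averaged difference counts then yield the NG86 proportions
pS and pN, which are corrected for multiple hits with the Jukes-Cantor
formula d = -(3/4) ln(1 - (4/3) p).  dS is the synonymous distance Ks used
throughout the pipeline for dating; omega = dN/dS summarises selection.

Conventions (stated for reproducibility):

* mutations creating stop codons count as nonsynonymous in site counting;
* evolutionary pathways passing through a stop codon are excluded when
  counting differences in multi-hit codons — unless every pathway is
  blocked, in which case all pathways are used;
* multi-hit pathways are averaged with equal weights (original NG86);
* the standard genetic code only.

pS >= 3/4 is outside the Jukes-Cantor domain; dS is then flagged infinite
(saturated) and omega is undefined.  omega is likewise undefined when
dS = 0 (identical synonymous sites).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations, product
from typing import Iterable, Mapping

import pandas as pd

BASES = "ACGT"

# standard genetic code
_CODON_TABLE = {}
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_b1, _b2, _b3) in enumerate(product("TCAG", repeat=3)):
    _CODON_TABLE[_b1 + _b2 + _b3] = _AA[_i]

GENETIC_CODE: Mapping[str, str] = dict(_CODON_TABLE)
SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


def translate_cds(cds: str, gene_id: str = "") -> str:
    """Translate an in-frame CDS; internal stops raise with their position."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS {gene_id!r} length {len(cds)} not divisible by 3")
    protein = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        aa = GENETIC_CODE.get(codon)
        if aa is None:
            raise ValueError(f"CDS {gene_id!r}: invalid codon {codon!r} at position {i}")
        if aa == "*":
            raise ValueError(f"CDS {gene_id!r}: internal stop codon at nt {i}")
        protein.append(aa)
    return "".join(protein)


def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts for one sense codon.

    Each codon position contributes the fraction of its three single-base
    changes that are synonymous; changes to stop codons are nonsynonymous.
    The two counts always sum to 3.
    """
    aa = GENETIC_CODE.get(codon)
    if aa is None:
        raise ValueError(f"invalid codon {codon!r}")
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no site counts")
    syn = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


_SITES_CACHE = {codon: ng86_sites(codon) for codon in SENSE_CODONS}


def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for a codon pair.

    All orders of the differing positions are enumerated; a pathway is
    admissible if no intermediate (or endpoint) codon is a stop.  Averages
    are over admissible pathways, or over all pathways if none is
    admissible.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diff_positions):
        current = codon_a
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if GENETIC_CODE[nxt] == "*":
                blocked = True
            steps.append((current, nxt))
            current = nxt
        syn = sum(1.0 for c1, c2 in steps if GENETIC_CODE[c1] == GENETIC_CODE[c2])
        pathways.append((blocked, syn, len(steps) - syn))
    admissible = [p for p in pathways if not p[0]]
    chosen = admissible if admissible else pathways
    sd = sum(p[1] for p in chosen) / len(chosen)
    nd = sum(p[2] for p in chosen) / len(chosen)
    return sd, nd


_DIFFS_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def codon_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    key = (codon_a, codon_b)
    if key not in _DIFFS_CACHE:
        _DIFFS_CACHE[key] = _pathway_differences(codon_a, codon_b)
    return _DIFFS_CACHE[key]


@dataclass
class CodonAlignment:
    gene_a: str
    gene_b: str
    # each column is (codon_or_None, codon_or_None); None is a codon gap
    columns: list[tuple[str | None, str | None]]


@dataclass
class SubstitutionEstimate:
    gene_a: str
    gene_b: str
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    ps: float
    pn: float
    ds: float  # math.inf when saturated
    dn: float
    omega: float | None  # None when undefined (ds == 0 or saturated)
    ds_saturated: bool
    dn_saturated: bool

    @property
    def omega_defined(self) -> bool:
        return self.omega is not None


def backtranslate(
    protein_alignment_a: str,
    protein_alignment_b: str,
    cds_a: str,
    cds_b: str,
    gene_a: str = "a",
    gene_b: str = "b",
) -> CodonAlignment:
    """Map an aligned protein pair back onto its coding sequences.

    Residue columns become codon columns and residue gaps become codon
    gaps.  The CDS must translate exactly to the ungapped protein; any
    mismatch raises naming the offending residue position.
    """
    if len(protein_alignment_a) != len(protein_alignment_b):
        raise ValueError("protein alignment rows differ in length")
    for gene, aligned, cds in ((gene_a, protein_alignment_a, cds_a), (gene_b, protein_alignment_b, cds_b)):
        ungapped = aligned.replace("-", "")
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"{gene}: CDS length {len(cds)} does not match protein length {len(ungapped)}"
            )
        translated = translate_cds(cds, gene)
        for i, (expected, got) in enumerate(zip(ungapped, translated)):
            if expected != got and expected != "X" and got != "X":
                raise ValueError(
                    f"{gene}: translation mismatch at residue {i}: protein has "
                    f"{expected!r}, CDS encodes {got!r}"
                )
    columns: list[tuple[str | None, str | None]] = []
    ia = ib = 0
    for res_a, res_b in zip(protein_alignment_a, protein_alignment_b):
        codon_a = codon_b = None
        if res_a != "-":
            codon_a = cds_a[3 * ia : 3 * ia + 3]
            ia += 1
        if res_b != "-":
            codon_b = cds_b[3 * ib : 3 * ib + 3]
            ib += 1
        columns.append((codon_a, codon_b))
    return CodonAlignment(gene_a, gene_b, columns)


def ng86_estimate(alignment: CodonAlignment) -> SubstitutionEstimate:
    """NG86 estimate of dN, dS and omega from a codon alignment.

    Site counts are averaged over the two sequences; differences use
    pathway averaging.  Jukes-Cantor correction is applied to both
    proportions; p >= 3/4 flags the corresponding distance as infinite.
    """
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    ungapped = 0
    for codon_a, codon_b in alignment.columns:
        if codon_a is None or codon_b is None:
            continue
        ungapped += 1
        sa, na = _SITES_CACHE.get(codon_a) or ng86_sites(codon_a)
        sb, nb = _SITES_CACHE.get(codon_b) or ng86_sites(codon_b)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        dsd, dnd = codon_pair_differences(codon_a, codon_b)
        sd += dsd
        nd += dnd
    if ungapped == 0:
        raise ValueError(
            f"{alignment.gene_a}/{alignment.gene_b}: no ungapped codon columns"
        )
    s_sites = (s_a + s_b) / 2.0
    n_sites = (n_a + n_b) / 2.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds, ds_sat = _jukes_cantor(ps)
    dn, dn_sat = _jukes_cantor(pn)
    omega: float | None
    if ds_sat or ds == 0.0 or dn_sat:
        omega = None
    else:
        omega = dn / ds
    return SubstitutionEstimate(
        alignment.gene_a,
        alignment.gene_b,
        s_sites,
        n_sites,
        sd,
        nd,
        ps,
        pn,
        ds,
        dn,
        omega,
        ds_sat,
        dn_sat,
    )


def _jukes_cantor(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return math.inf, True
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def estimate_pair(
    protein_a: str, protein_b: str, cds_a: str, cds_b: str, gene_a: str = "a", gene_b: str = "b"
) -> SubstitutionEstimate:
    """Convenience: protein global alignment -> codon alignment -> NG86."""
    from .homology import global_align_protein

    aln = global_align_protein(protein_a, protein_b, gene_a, gene_b)
    codon_aln = backtranslate(aln.aligned_a, aln.aligned_b, cds_a, cds_b, gene_a, gene_b)
    return ng86_estimate(codon_aln)


def classify_selection(
    omega: float, neutral_band: float = 0.1
) -> tuple[str, bool]:
    """Classify omega as purifying / neutral / positive with a neutral band.

    Returns (category, weak_evidence); weak_evidence marks purifying calls
    with omega > 0.9, where purifying selection is not clearly evident.
    """
    if omega is None:
        raise ValueError("omega undefined; cannot classify selection")
    if omega < 1.0 - neutral_band:
        return "purifying", omega > 0.9
    if omega > 1.0 + neutral_band:
        return "positive", False
    return "neutral", False


def summarize_omega(estimates: Iterable[tuple[str, str, SubstitutionEstimate]]) -> pd.DataFrame:
    """Mean omega per (relation, species-or-species-pair) over defined values.

    ``estimates`` yields (relation, group_label, estimate).  Pairs with
    undefined omega are counted but excluded from means.
    """
    buckets: dict[tuple[str, str], list[SubstitutionEstimate]] = {}
    for relation, label, est in estimates:
        buckets.setdefault((relation, label), []).append(est)
    rows = []
    for (relation, label), ests in sorted(buckets.items()):
        defined = [e.omega for e in ests if e.omega is not None]
        excluded = sorted(
            f"{e.gene_a}-{e.gene_b}" for e in ests if e.omega is None
        )
        rows.append(
            {
                "relation": relation,
                "group": label,
                "n_pairs": len(ests),
                "n_defined": len(defined),
                "mean_omega": sum(defined) / len(defined) if defined else float("nan"),
                "excluded_pairs": ",".join(excluded),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["relation", "group", "n_pairs", "n_defined", "mean_omega", "excluded_pairs"],
    )
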