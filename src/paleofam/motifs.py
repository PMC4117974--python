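"""Family membership by Ser-Pro(3+) repeat content.

Extensins are hydroxyproline-rich cell-wall glycoproteins characterised by
repeats of Ser-Pro-Pro-Pro (SP3) and/or Ser-Pro-Pro-Pro-Pro (SP4); in
genomic protein sequences hydroxyproline appears as plain proline, so the
scan runs directly on translated CDS.  A protein with at least two such
repeats is called a family member.  Each maximal run ``S P{3,}`` counts as
exactly one repeat unit — "SPPPPPP" is a single unit, not several
overlapping ones — which makes the count deterministic and conservative.

Signature-domain annotations (e.g. IPR006706, the extensin-2 domain) are
attached as subfamily labels.  By default they are metadata only: the motif
rule alone decides membership.  Pass ``require_domain=True`` to
:func:`classify_member` callers that want the stricter conjunction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .io import PROTEIN_ALPHABET, DomainAnnotation

SP_REPEAT = re.compile(r"SP{3,}")


@dataclass
class MotifScanResult:
    protein_id: str
    repeat_count: int
    repeat_spans: list[tuple[int, int]]


@dataclass
class FamilyCall:
    protein_id: str
    species: str
    repeat_count: int
    is_member: bool
    domain_ids: set[str] = field(default_factory=set)


def scan_sp_repeats(protein: str, protein_id: str = "") -> MotifScanResult:
    """Count maximal S-P(3+) repeat units in a protein sequence.

    Spans are 0-based half-open protein coordinates, non-overlapping and
    sorted left to right.
    """
    if not protein:
        raise ValueError(f"empty protein sequence for {protein_id!r}")
    bad = set(protein) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(
            f"protein {protein_id!r} contains non-amino-acid characters {sorted(bad)}"
        )
    spans = [m.span() for m in SP_REPEAT.finditer(protein)]
    return MotifScanResult(protein_id, len(spans), spans)


def classify_member(scan: MotifScanResult, min_repeats: int = 2) -> bool:
    """True iff the scan found at least ``min_repeats`` repeat units."""
    if min_repeats < 1:
        raise ValueError(f"min_repeats must be >= 1, got {min_repeats}")
    return scan.repeat_count >= min_repeats


def call_family(
    proteins: Mapping[str, str],
    species: str,
    min_repeats: int = 2,
    annotations: Iterable[DomainAnnotation] = (),
    require_domain: bool = False,
) -> list[FamilyCall]:
    """Scan every protein and produce family calls with domains attached."""
    calls = []
    for protein_id in sorted(proteins):
        scan = scan_sp_repeats(proteins[protein_id], protein_id)
        calls.append(
            FamilyCall(
                protein_id,
                species,
                scan.repeat_count,
                classify_member(scan, min_repeats),
            )
        )
    attach_domains(calls, annotations)
    if require_domain:
        for call in calls:
            call.is_member = call.is_member and bool(call.domain_ids)
    return calls


def attach_domains(
    calls: Iterable[FamilyCall], annotations: Iterable[DomainAnnotation]
) -> list[FamilyCall]:
    """Fill ``domain_ids`` from annotation rows; membership is unchanged.

    Proteins without annotation rows get an empty set.
    """
    by_protein: dict[str, set[str]] = {}
    for ann in annotations:
        by_protein.setdefault(ann.protein_id, set()).add(ann.domain_id)
    calls = list(calls)
    for call in calls:
        call.domain_ids = set(by_protein.get(call.protein_id, set()))
    return calls


def tally_by_domain(calls: Iterable[FamilyCall]) -> pd.DataFrame:
    """Per-(species, domain) member counts and percentages.

    Percentage = members carrying the domain / total members in the species,
    times 100, rounded to one decimal.  Species with zero members are
    reported with count 0 and a missing percentage (flagged undefined).
    """
    calls = list(calls)
    species_totals: dict[str, int] = {}
    for call in calls:
        species_totals.setdefault(call.species, 0)
        if call.is_member:
            species_totals[call.species] += 1
    counts: dict[tuple[str, str], int] = {}
    for call in calls:
        if not call.is_member:
            continue
        for domain_id in call.domain_ids:
            counts[(call.species, domain_id)] = counts.get((call.species, domain_id), 0) + 1
    rows = []
    for (species, domain_id), count in sorted(counts.items()):
        total = species_totals[species]
        rows.append(
            {
                "species": species,
                "domain_id": domain_id,
                "count": count,
                "total_members": total,
                "percent": round(100.0 * count / total, 1) if total else float("nan"),
            }
        )
    for species, total in sorted(species_totals.items()):
        if total == 0:
            rows.append(
                {
                    "species": species,
                    "domain_id": "",
                    "count": 0,
                    "total_members": 0,
                    "percent": float("nan"),
                }
            )
    return pd.DataFrame(
        rows, columns=["species", "domain_id", "count", "total_members", "percent"]
    )
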