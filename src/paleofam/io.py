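"""Data model and readers/writers for the standard formats the pipeline touches.

Internal coordinates are 0-based, half-open; GFF3's 1-based inclusive
intervals are converted at the I/O boundary.  Terminal stop codons are
stripped from coding sequences on load so downstream codon arithmetic never
sees them; internal stops are rejected later, at the codon-alignment stage.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = set("ACGTN")
STOP_CODONS = {"TAA", "TAG", "TGA"}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene with its genomic placement.

    ``rank`` is the 0-based ordinal of the gene along its chromosome,
    ordered by ascending start (strand ignored); collinearity chaining
    operates on these ranks, while the tandem-duplication window rule
    operates on ``start`` coordinates.
    """

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    rank: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class SequenceSet:
    """Map of gene_id -> sequence with an alphabet tag (``protein`` or ``cds``)."""

    sequences: dict[str, str]
    alphabet: str

    def __getitem__(self, key: str) -> str:
        return self.sequences[key]

    def __contains__(self, key: str) -> bool:
        return key in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    def items(self):
        return self.sequences.items()

    def ids(self) -> list[str]:
        return list(self.sequences)


@dataclass(frozen=True)
class DomainAnnotation:
    protein_id: str
    domain_id: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.domain_id:
            raise FormatError(f"empty domain_id for protein {self.protein_id}")


def trim_terminal_stop(cds: str) -> str:
    """Strip one trailing stop codon from an in-frame CDS, if present."""
    if len(cds) % 3 == 0 and len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def read_fasta(path: str | os.PathLike, alphabet: str) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Records are keyed by the first whitespace-delimited token of the header
    and uppercased.  ``alphabet`` must be ``"protein"`` or ``"cds"``; for CDS
    input a terminal stop codon is stripped.
    """
    if alphabet not in {"protein", "cds"}:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if record.id in sequences:
            raise FormatError(f"duplicate FASTA id {record.id!r} in {path}")
        if alphabet == "cds":
            seq = trim_terminal_stop(seq)
        sequences[record.id] = seq
    if not sequences:
        raise FormatError(f"no FASTA records in {path}")
    return SequenceSet(sequences, alphabet)


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for name in sequences:
            handle.write(f">{name}\n{sequences[name]}\n")


def read_gff3(path: str | os.PathLike, species: str) -> list[GeneRecord]:
    """Read gene features from a GFF3 file.

    Only rows whose type column is ``gene`` are used; each must carry an
    ``ID`` attribute.  1-based inclusive coordinates become 0-based
    half-open, and ranks are assigned per chromosome by ascending start.
    Column-level parsing is done directly: gene rows are flat 9-column
    records and need no feature-hierarchy database.
    """
    rows: list[tuple[str, int, int, str, str]] = []
    seen_ids: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype != "gene":
                continue
            attributes = dict(
                item.split("=", 1) for item in attrs.split(";") if "=" in item
            )
            gene_id = attributes.get("ID")
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: gene feature without ID attribute")
            if gene_id in seen_ids:
                raise FormatError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen_ids.add(gene_id)
            start, end = int(start_s), int(end_s)
            if start > end:
                raise FormatError(f"{path}:{lineno}: start {start} > end {end}")
            rows.append((chrom, start - 1, end, strand if strand in "+-" else "+", gene_id))
    records: list[GeneRecord] = []
    by_chrom: dict[str, list[tuple[str, int, int, str, str]]] = {}
    for row in rows:
        by_chrom.setdefault(row[0], []).append(row)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda r: (r[1], r[4]))
        for rank, (chrom_, start, end, strand, gene_id) in enumerate(ordered):
            records.append(
                GeneRecord(gene_id, species, chrom_, start, end, strand, rank)
            )
    return records


def write_gff3(records: Iterable[GeneRecord], path: str | os.PathLike) -> None:
    """Write gene records as GFF3 (inverse of :func:`read_gff3`)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        ordered = sorted(records, key=lambda r: (r.chromosome, r.start, r.gene_id))
        for rec in ordered:
            handle.write(
                "\t".join(
                    [
                        rec.chromosome,
                        "paleofam",
                        "gene",
                        str(rec.start + 1),
                        str(rec.end),
                        ".",
                        rec.strand,
                        ".",
                        f"ID={rec.gene_id}",
                    ]
                )
                + "\n"
            )


def read_domain_table(path: str | os.PathLike) -> list[DomainAnnotation]:
    """Read an InterProScan-style TSV of (protein_id, domain_id, label).

    Extra columns are ignored; an empty file yields an empty list.
    """
    annotations: list[DomainAnnotation] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns, got {len(cols)}")
            annotations.append(DomainAnnotation(cols[0], cols[1], cols[2]))
    return annotations


def read_anchor_table(path: str | os.PathLike) -> list[tuple[str, str, float | None]]:
    """Read homolog anchor pairs: gene_a, gene_b, optional ks column.

    A header line starting with ``gene_a`` is tolerated and skipped.
    """
    anchors: list[tuple[str, str, float | None]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if lineno == 1 and cols[0] == "gene_a":
                continue
            if len(cols) < 2:
                raise FormatError(f"{path}:{lineno}: expected >=2 columns")
            ks: float | None = None
            if len(cols) >= 3 and cols[2] not in {"", "NA", "nan"}:
                ks = float(cols[2])
            anchors.append((cols[0], cols[1], ks))
    return anchors


def write_tsv_report(
    records: Sequence, path: str | os.PathLike, columns: list[str] | None = None
) -> None:
    """Write homogeneous records (dataclasses or dicts) as a sorted TSV.

    Rows are sorted by their leading fields so re-runs on the same input are
    byte-identical.  ``columns`` supplies the header for an empty record list.
    """
    if records and dataclasses.is_dataclass(records[0]):
        rows = [dataclasses.asdict(r) for r in records]
        columns = [f.name for f in dataclasses.fields(records[0])]
    elif records:
        rows = [dict(r) for r in records]
        columns = list(rows[0])
    else:
        rows, columns = [], list(columns or [])
    frame = pd.DataFrame(rows, columns=columns)
    if len(frame) and len(frame.columns):
        frame = frame.sort_values(list(frame.columns[:2]), kind="mergesort")
    frame.to_csv(path, sep="\t", index=False)
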