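"""Readers and writers for the standard formats the pipeline touches.

The pipeline consumes a genome annotation (GFF3), protein and CDS sequences
(FASTA), profile-HMM domain hits (HMMER3 ``domtblout`` or a simplified
six-column TSV) and per-protein feature annotations (TSV).  Everything is
normalised into plain dataclasses / dicts here so the analysis modules never
touch file formats directly.

Coordinates are 1-based inclusive throughout (the GFF3 convention); any
distance arithmetic downstream converts explicitly.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO


class Gff3ParseError(ValueError):
    """Raised for a malformed GFF3 line; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"GFF3 parse error at line {line_number}: {message}")


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: coordinates, strand and family membership."""

    gene_id: str
    chromosome_id: str
    start: int  # bp, 1-based inclusive
    end: int  # bp, 1-based inclusive
    strand: str  # '+' or '-'
    is_family: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainHit:
    """A profile-HMM domain hit on a protein (alignment coordinates in aa)."""

    protein_id: str
    domain_name: str
    ali_start: int  # aa, 1-based
    ali_end: int  # aa, 1-based
    e_value: float
    model_coverage: float  # fraction of the HMM model covered, in [0, 1]

    def __post_init__(self):
        if self.ali_start > self.ali_end:
            raise ValueError(
                f"{self.protein_id}/{self.domain_name}: ali_start > ali_end"
            )
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")


@dataclass
class SequenceSet:
    """An id -> residue-string mapping with a declared alphabet."""

    sequences: dict[str, str]
    alphabet: str  # 'protein' or 'dna'

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, key: str) -> str:
        return self.sequences[key]

    def __contains__(self, key: str) -> bool:
        return key in self.sequences

    def items(self):
        return self.sequences.items()


def _prevalidate_gff3(path: str) -> None:
    """Cheap line-level sanity pass so parse failures carry line numbers."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise Gff3ParseError(
                    lineno, f"expected 9 tab-separated columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise Gff3ParseError(lineno, "non-integer start/end") from None
            if end < start:
                raise Gff3ParseError(lineno, f"end {end} < start {start}")
            if fields[6] not in ("+", "-", ".", "?"):
                raise Gff3ParseError(lineno, f"invalid strand {fields[6]!r}")


def read_gff3(
    path: str,
    family_id_list: Iterable[str] = (),
    feature_type: str = "gene",
) -> list[GeneRecord]:
    """Read gene features from a GFF3 file into :class:`GeneRecord` objects.

    ``is_family`` is set for records whose gene id appears in
    *family_id_list*; family ids absent from the annotation trigger a warning
    naming the unresolved ids.  Records come back sorted by
    (chromosome, start, end, gene_id).
    """
    _prevalidate_gff3(path)
    family = set(family_id_list)
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    records = []
    seen = set()
    for feat in db.features_of_type(feature_type):
        gid = feat.id
        if gid in seen:
            raise ValueError(f"duplicate gene id {gid!r} in {path}")
        seen.add(gid)
        records.append(
            GeneRecord(
                gene_id=gid,
                chromosome_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                is_family=gid in family,
            )
        )
    unresolved = sorted(family - seen)
    if unresolved:
        warnings.warn(
            f"{len(unresolved)} family id(s) not found in annotation: "
            + ", ".join(unresolved),
            stacklevel=2,
        )
    return sort_genes(records)


def read_chromosome_lengths(path: str) -> dict[str, int]:
    """Chromosome sizes from ``##sequence-region`` directives of a GFF3 file."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths[parts[1]] = int(parts[3])
            elif line and not line.startswith("#"):
                break
    return lengths


def sort_genes(records: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Deterministic chromosome order: (chromosome, start, end, gene_id)."""
    return sorted(
        records, key=lambda r: (r.chromosome_id, r.start, r.end, r.gene_id)
    )


def read_fasta(path: str, alphabet: str = "protein") -> SequenceSet:
    """Read a FASTA file; ids are the first header token, residues upper-cased.

    Protein sequences may carry one trailing stop symbol (stripped); an
    internal ``*`` is an error, as is a duplicated id.
    """
    if alphabet not in ("protein", "dna"):
        raise ValueError("alphabet must be 'protein' or 'dna'")
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if alphabet == "protein":
            if seq.endswith("*"):
                seq = seq[:-1]
            if "*" in seq:
                raise ValueError(f"internal stop symbol in protein {rec.id!r}")
        seqs[rec.id] = seq
    if not seqs:
        warnings.warn(f"FASTA file {path} contains no sequences", stacklevel=2)
    return SequenceSet(seqs, alphabet)


def write_fasta(seqs: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_SIMPLE_COLS = [
    "protein_id",
    "domain_name",
    "ali_start",
    "ali_end",
    "e_value",
    "model_coverage",
]


def read_domain_table(
    path: str,
    e_threshold: float = 0.05,
    min_model_coverage: float = 0.6,
) -> list[DomainHit]:
    """Read domain hits and apply the e-value and partial-domain filters.

    Two layouts are accepted: a simplified 6-column TSV
    (protein_id, domain_name, ali_start, ali_end, e_value, model_coverage),
    or HMMER3 ``domtblout`` as written by ``hmmscan`` (model coverage is then
    derived from the hmm from/to span over the model length).  Hits with
    e-value above *e_threshold* or model coverage below *min_model_coverage*
    (partial domains) are discarded; survivors come back sorted by
    (protein_id, ali_start).
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) >= 23:  # domtblout (hmmscan orientation)
                try:
                    tlen = int(fields[2])
                    hit = DomainHit(
                        protein_id=fields[3],
                        domain_name=fields[0],
                        ali_start=int(fields[17]),
                        ali_end=int(fields[18]),
                        e_value=float(fields[12]),
                        model_coverage=(int(fields[16]) - int(fields[15]) + 1)
                        / tlen,
                    )
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: bad domtblout record: {exc}"
                    ) from None
            elif len(fields) == 6:
                if fields == _SIMPLE_COLS:  # optional header row
                    continue
                try:
                    hit = DomainHit(
                        protein_id=fields[0],
                        domain_name=fields[1],
                        ali_start=int(fields[2]),
                        ali_end=int(fields[3]),
                        e_value=float(fields[4]),
                        model_coverage=float(fields[5]),
                    )
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: bad domain-hit record: {exc}"
                    ) from None
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 6-column TSV or domtblout, "
                    f"got {len(fields)} fields"
                )
            if hit.e_value > e_threshold:
                continue
            if hit.model_coverage < min_model_coverage:
                continue
            hits.append(hit)
    hits.sort(key=lambda h: (h.protein_id, h.ali_start, h.ali_end))
    return hits


def gene_table(records: Iterable[GeneRecord]) -> pd.DataFrame:
    """Unified gene table as a DataFrame (one row per gene, sorted)."""
    rows = [
        {
            "gene_id": r.gene_id,
            "chromosome_id": r.chromosome_id,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
            "is_family": r.is_family,
        }
        for r in sort_genes(records)
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chromosome_id", "start", "end", "strand", "is_family"],
    )


def write_gene_table(records: Iterable[GeneRecord], path: str) -> None:
    gene_table(records).to_csv(path, sep="\t", index=False)


def read_gene_table(path: str) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome_id": str})
    return [
        GeneRecord(
            gene_id=row.gene_id,
            chromosome_id=row.chromosome_id,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            is_family=bool(row.is_family),
        )
        for row in df.itertuples()
    ]
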