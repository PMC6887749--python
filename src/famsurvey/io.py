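"""Readers and writers for every on-disk artifact the pipeline touches.

Conventions
-----------
* All genomic coordinates are 1-based inclusive (GFF3 convention); any
  half-open arithmetic is internal and never serialized.
* Readers reject malformed input instead of silently repairing it; every
  writer produces files its paired reader accepts.
* Motif E-values are carried as opaque text: values such as
  ``4.9 x 10^-1822`` underflow IEEE doubles and are metadata, not numbers
  the pipeline computes on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import ConsistencyError, FormatError

Interval = tuple[int, int]

# 20 canonical amino acids; the extended motif alphabet adds B/Z/J/X.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
EXTENDED_AMINO_ALPHABET = set(AMINO_ACIDS) | {"B", "Z", "J", "X"}

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def natural_key(identifier: str) -> tuple:
    """Sort key placing ``chr2`` before ``chr10`` (natural numeric order)."""
    return tuple(
        int(part) if part.isdigit() else part
        for part in re.split(r"(\d+)", identifier)
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> uppercase-sequence map.

    Raises :class:`FormatError` on duplicate identifiers or empty records.
    """
    result: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in result:
            raise FormatError(f"duplicate FASTA id {record.id!r} in {path}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"empty FASTA record {record.id!r} in {path}")
        result[record.id] = seq
    if not result:
        raise FormatError(f"no FASTA records in {path}")
    return result


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3 / gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One annotated gene: location plus exon/CDS parts (1-based inclusive)."""

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    rank_on_chromosome: int = 0

    @property
    def cds_start(self) -> int:
        """First CDS base in genome coordinates (5' on the coding strand
        is the minimum coordinate for '+' genes, the maximum for '-')."""
        if not self.cds:
            raise ConsistencyError(f"gene {self.gene_id} has no CDS")
        if self.strand == "+":
            return min(s for s, _ in self.cds)
        return max(e for _, e in self.cds)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into :class:`GeneModel` records.

    Models are sorted by (chromosome, start) with natural chromosome
    ordering, and ``rank_on_chromosome`` is assigned 1..n per chromosome.
    """
    db = gffutils.create_db(
        str(path), ":memory:",
        merge_strategy="create_unique", keep_order=True,
    )
    # orphan exon/CDS features are a structural error, not data to repair
    for ftype in ("exon", "CDS", "mRNA", "five_prime_UTR"):
        for feat in db.features_of_type(ftype):
            if "Parent" not in feat.attributes:
                raise FormatError(
                    f"{ftype} feature at {feat.seqid}:{feat.start} lacks a Parent"
                )

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons: list[Interval] = []
        cds: list[Interval] = []
        for child in db.children(gene, featuretype="exon"):
            exons.append((child.start, child.end))
        for child in db.children(gene, featuretype="CDS"):
            cds.append((child.start, child.end))
        exons.sort()
        cds.sort()
        for cs, ce in cds:
            if not any(es <= cs and ce <= ee for es, ee in exons):
                raise ConsistencyError(
                    f"gene {gene.id}: CDS {cs}-{ce} outside every exon"
                )
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                exons=exons,
                cds=cds,
            )
        )

    models.sort(key=lambda m: (natural_key(m.chromosome), m.start))
    rank = 0
    current_chrom = None
    for model in models:
        if model.chromosome != current_chrom:
            current_chrom = model.chromosome
            rank = 0
        rank += 1
        model.rank_on_chromosome = rank
    return models


def write_gff3(models: list[GeneModel], path: str | Path,
               utrs: Mapping[str, Interval] | None = None) -> None:
    """Write gene/mRNA/exon/CDS (and optional five_prime_UTR) features."""
    utrs = utrs or {}
    lines = ["##gff-version 3"]
    for m in models:
        attrs = f"ID={m.gene_id}"
        lines.append("\t".join(
            [m.chromosome, "famsurvey", "gene", str(m.start), str(m.end),
             ".", m.strand, ".", attrs]))
        mrna_id = f"{m.gene_id}.t1"
        lines.append("\t".join(
            [m.chromosome, "famsurvey", "mRNA", str(m.start), str(m.end),
             ".", m.strand, ".", f"ID={mrna_id};Parent={m.gene_id}"]))
        for i, (s, e) in enumerate(m.exons, 1):
            lines.append("\t".join(
                [m.chromosome, "famsurvey", "exon", str(s), str(e),
                 ".", m.strand, ".", f"ID={mrna_id}.exon{i};Parent={mrna_id}"]))
        if m.gene_id in utrs:
            s, e = utrs[m.gene_id]
            lines.append("\t".join(
                [m.chromosome, "famsurvey", "five_prime_UTR", str(s), str(e),
                 ".", m.strand, ".", f"ID={mrna_id}.utr5;Parent={mrna_id}"]))
        for i, (s, e) in enumerate(m.cds, 1):
            lines.append("\t".join(
                [m.chromosome, "famsurvey", "CDS", str(s), str(e),
                 ".", m.strand, "0" if i == 1 else ".",
                 f"ID={mrna_id}.cds;Parent={mrna_id}"]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Motif and cis-element tables
# ---------------------------------------------------------------------------

@dataclass
class MotifDefinition:
    """An extended-alphabet protein consensus motif (B={N,D}, Z={Q,E},
    J={I,L}, X=any)."""

    motif_id: str
    consensus: str
    evalue_text: str = ""
    sites: int = 0

    @property
    def width(self) -> int:
        return len(self.consensus)


@dataclass
class CisElementDefinition:
    """A promoter cis-regulatory element as an uppercase IUPAC pattern."""

    name: str
    pattern: str
    category: str = "other"


def read_motif_table(path: str | Path) -> list[MotifDefinition]:
    """Read a TSV motif table (columns motif_id, consensus, evalue, sites
    and optionally width).

    Width is always recomputed from the consensus; a declared width that
    disagrees raises :class:`ConsistencyError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"motif_id", "consensus"}
    if not required.issubset(df.columns):
        raise FormatError(f"motif table {path} lacks columns {required}")
    motifs: list[MotifDefinition] = []
    for _, row in df.iterrows():
        consensus = str(row["consensus"]).strip().upper()
        bad = set(consensus) - EXTENDED_AMINO_ALPHABET
        if bad:
            raise FormatError(
                f"motif {row['motif_id']}: characters {sorted(bad)} outside "
                "the extended amino-acid alphabet"
            )
        if not 6 <= len(consensus) <= 200:
            raise FormatError(
                f"motif {row['motif_id']}: width {len(consensus)} outside 6-200"
            )
        if "width" in df.columns and not pd.isna(row["width"]):
            declared = int(row["width"])
            if declared != len(consensus):
                raise ConsistencyError(
                    f"motif {row['motif_id']}: declared width {declared} != "
                    f"consensus length {len(consensus)}"
                )
        motifs.append(
            MotifDefinition(
                motif_id=str(row["motif_id"]),
                consensus=consensus,
                evalue_text=str(row.get("evalue", "")) if "evalue" in df.columns else "",
                sites=int(row["sites"]) if "sites" in df.columns and not pd.isna(row["sites"]) else 0,
            )
        )
    if not motifs:
        raise FormatError(f"motif table {path} is empty")
    return motifs


def read_element_table(path: str | Path) -> list[CisElementDefinition]:
    """Read a TSV cis-element dictionary (columns name, pattern, category)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"name", "pattern"}.issubset(df.columns):
        raise FormatError(f"element table {path} lacks name/pattern columns")
    elements = []
    for _, row in df.iterrows():
        pattern = str(row["pattern"]).strip().upper()
        if not pattern or set(pattern) - set(IUPAC_DNA):
            raise FormatError(
                f"element {row['name']}: pattern {pattern!r} is not uppercase IUPAC"
            )
        elements.append(
            CisElementDefinition(
                name=str(row["name"]),
                pattern=pattern,
                category=str(row.get("category", "other")) if "category" in df.columns else "other",
            )
        )
    if not elements:
        raise FormatError(f"element table {path} is empty")
    return elements
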