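"""FASTA and table I/O, the bundled gene-family metadata, and logging.

Interchange coordinates are 1-based inclusive (the style of the printed
family table); internal spans are 0-based half-open.  Conversion happens
only here and in :mod:`auxiaa.promoter_scan`.
"""
from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .errors import FormatError, SchemaError, ValidationError

log = logging.getLogger("auxiaa")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, *, keep_gaps: bool = False) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` in file order.

    Sequences are uppercased.  Gap characters (``-``) are stripped
    unless ``keep_gaps`` is set (used when reading alignments).

    Raises
    ------
    FormatError
        If the file is empty, does not start with a header (the
        offending line number is reported), or contains duplicate IDs.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: expected FASTA header '>', got {line.strip()!r}"
                )
            break
        else:
            raise FormatError(f"{path}: empty FASTA file")

    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA ID {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not keep_gaps:
            seq = seq.replace("-", "")
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write ``(id, sequence)`` pairs as FASTA, wrapping at ``width``."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            if not seq:
                fh.write("\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Family metadata

SUBGENOMES = {"1", "2", "unassigned"}

METADATA_COLUMNS = [
    "gene_name", "accession", "chromosome", "start", "end",
    "strand", "protein_length", "subgenome", "paralog_partner",
]


@dataclass(frozen=True)
class GeneMeta:
    """One gene-family member: genomic location, protein size, subgenome
    assignment from synteny, and the retained whole-genome-duplication
    paralog (if any)."""

    gene_name: str
    accession: str
    chromosome: int
    start: int          # 1-based inclusive
    end: int            # 1-based inclusive
    strand: int         # +1 / -1
    protein_length: int
    subgenome: str      # "1", "2" or "unassigned"
    paralog_partner: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"{self.gene_name}: start must be < end")
        if self.protein_length <= 0:
            raise ValidationError(f"{self.gene_name}: protein_length must be positive")
        if self.strand not in (1, -1):
            raise ValidationError(f"{self.gene_name}: strand must be +1/-1")
        if not 1 <= self.chromosome <= 10:
            raise ValidationError(f"{self.gene_name}: chromosome must be 1..10")
        if self.subgenome not in SUBGENOMES:
            raise ValidationError(f"{self.gene_name}: unknown subgenome {self.subgenome!r}")


def bundled_metadata_path() -> Path:
    """Path of the packaged 34-gene maize Aux/IAA family table."""
    return Path(importlib.resources.files("auxiaa").joinpath("data/family_metadata.tsv"))


def load_family_metadata(path: str | Path | None = None) -> list[GeneMeta]:
    """Load the gene-family metadata table (bundled fixture by default).

    Enforces paralog symmetry: if a lists b as its partner, b must list a.
    """
    path = Path(path) if path is not None else bundled_metadata_path()
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.empty:
        log.warning("%s: empty metadata table", path)
        return []
    genes = []
    for _, row in df.iterrows():
        partner = row["paralog_partner"]
        partner = None if pd.isna(partner) or str(partner).strip() == "" else str(partner)
        genes.append(
            GeneMeta(
                gene_name=row["gene_name"],
                accession=row["accession"],
                chromosome=int(row["chromosome"]),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=int(row["strand"]),
                protein_length=int(row["protein_length"]),
                subgenome=str(row["subgenome"]),
                paralog_partner=partner,
            )
        )
    by_name = {g.gene_name: g for g in genes}
    if len(by_name) != len(genes):
        raise ValidationError(f"{path}: duplicate gene names")
    for g in genes:
        if g.paralog_partner is not None:
            other = by_name.get(g.paralog_partner)
            if other is None:
                raise ValidationError(
                    f"{g.gene_name}: paralog partner {g.paralog_partner!r} not in table"
                )
            if other.paralog_partner != g.gene_name:
                raise ValidationError(
                    f"asymmetric paralog annotation: {g.gene_name} -> "
                    f"{g.paralog_partner}, but {other.gene_name} -> {other.paralog_partner}"
                )
    log.info("loaded %d gene-family records from %s", len(genes), path)
    return genes


def paralog_pairs(genes: Iterable[GeneMeta]) -> list[tuple[str, str]]:
    """Unique symmetric paralog pairs, each sorted and listed once."""
    pairs = {
        tuple(sorted((g.gene_name, g.paralog_partner)))
        for g in genes
        if g.paralog_partner is not None
    }
    return sorted(pairs)
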