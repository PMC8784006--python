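"""Domain types and file I/O shared by every survey stage.

The pipeline parses its inputs (GFF3 gene models, CDS/protein FASTA, tabular
domain-search hits) exactly once, into :class:`GeneRecord` objects; all later
stages consume these records so no stage re-opens the raw files.  Coordinates
are 1-based inclusive throughout (GFF3 convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

#: Sub-genome complement of each species of the wheat polyploidy series:
#: hexaploid bread wheat (Ta, AABBDD), wild emmer (Td, AABB) and the diploid
#: donors T. urartu (Tu, AA) and Ae. tauschii (Aet, DD).
SPECIES_SUBGENOMES: dict[str, tuple[str, ...]] = {
    "Ta": ("A", "B", "D"),
    "Td": ("A", "B"),
    "Tu": ("A",),
    "Aet": ("D",),
}

_CHROM_RE = re.compile(r"^(\d)([A-Z])$")


def chromosome_group(chromosome: str | None) -> int | None:
    """Homologous-group number of a Triticeae chromosome name ("3A" -> 3).

    Unplaced ("Un", "unknown", empty) names yield ``None``.
    """
    if not chromosome:
        return None
    m = _CHROM_RE.match(chromosome)
    return int(m.group(1)) if m else None


def chromosome_subgenome(chromosome: str | None) -> str | None:
    """Sub-genome letter of a chromosome name ("3A" -> "A"), else ``None``."""
    if not chromosome:
        return None
    m = _CHROM_RE.match(chromosome)
    return m.group(2) if m else None


@dataclass
class GeneRecord:
    """One gene with its location, sequences and species identity."""

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    cds: str = ""
    protein: str = ""
    name: str = ""
    subgenome: str = "unknown"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.protein and self.cds:
            if len(self.cds) % 3:
                raise ValueError(
                    f"{self.gene_id}: CDS length {len(self.cds)} not a "
                    "multiple of 3"
                )
            expected = len(self.cds) // 3 - 1
            if len(self.protein) != expected:
                raise ValueError(
                    f"{self.gene_id}: protein length {len(self.protein)} != "
                    f"CDS/3 - 1 = {expected}"
                )
        if self.subgenome == "unknown":
            sg = chromosome_subgenome(self.chromosome)
            if sg is None and self.species in SPECIES_SUBGENOMES:
                subs = SPECIES_SUBGENOMES[self.species]
                sg = subs[0] if len(subs) == 1 else None
            if sg is not None:
                self.subgenome = sg

    @property
    def homologous_group(self) -> int | None:
        return chromosome_group(self.chromosome)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SegmentHit:
    """A located K/Y/S segment match on a protein (1-based inclusive)."""

    segment: str  # "K", "Y" or "S"
    start: int
    end: int
    matched_seq: str
    mismatches: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("segment hit end < start")
        if self.mismatches < 0:
            raise ValueError("negative mismatch count")

    def overlaps(self, other: "SegmentHit") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class Architecture:
    """Ordered segment composition of a dehydrin ("YSK2", "K6", ...)."""

    type_string: str
    n_y: int
    n_s: int
    n_k: int
    cls: str  # YnSKn | YnKn | SKn | KnS | Kn | non_dehydrin


@dataclass(frozen=True)
class HitTableRow:
    """One row of an external domain-search hit table."""

    query_id: str
    domain_id: str
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("negative E-value")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_fasta(path) -> dict[str, str]:
    """FASTA as {first-whitespace-token: sequence}; trailing '*' stripped."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).rstrip("*").upper()
    return seqs


def _validate_gff3(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(
                    f"{path}: malformed GFF3 line {lineno}: expected 9 "
                    f"tab-separated columns"
                )


def read_gene_set(gff3_path, cds_fasta_path, protein_fasta_path) -> list[GeneRecord]:
    """Assemble one :class:`GeneRecord` per ``gene`` feature in the GFF3.

    CDS and protein sequences are cross-referenced by the feature ``ID``
    attribute; a gene absent from either FASTA raises a ``ValueError`` naming
    the orphan ID.  Optional ``species`` and ``name`` GFF3 attributes are
    carried through when present.
    """
    _validate_gff3(gff3_path)
    cds = _read_fasta(cds_fasta_path)
    proteins = _read_fasta(protein_fasta_path)
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    records = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.id
        if gene_id not in cds:
            raise ValueError(f"gene {gene_id!r} has no CDS sequence")
        if gene_id not in proteins:
            raise ValueError(f"gene {gene_id!r} has no protein sequence")
        records.append(
            GeneRecord(
                gene_id=gene_id,
                species=feat.attributes.get("species", ["unknown"])[0],
                name=feat.attributes.get("name", [""])[0],
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                cds=cds[gene_id],
                protein=proteins[gene_id],
            )
        )
    return records


def write_gff3(records: Iterable[GeneRecord], path) -> None:
    """Write gene features back out (exact coordinate/strand round trip)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            attrs = f"ID={rec.gene_id};species={rec.species}"
            if rec.name:
                attrs += f";name={rec.name}"
            fh.write(
                "\t".join(
                    [
                        rec.chromosome,
                        "dhnsurvey",
                        "gene",
                        str(rec.start),
                        str(rec.end),
                        ".",
                        rec.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


SURVEY_COLUMNS = [
    "name",
    "locus",
    "type",
    "chromosome",
    "start",
    "end",
    "strand",
    "bp",
    "gc_percent",
    "aa",
    "mw_kda",
    "pi",
]


def write_survey_table(records, architectures, properties, path) -> pd.DataFrame:
    """Write the per-gene survey table (name, locus, type, position, BP,
    GC%, AA, MW, pI) as TSV; missing values are ".".

    ``architectures`` and ``properties`` are sequences parallel to
    ``records``; a length mismatch raises ``ValueError``.
    """
    records = list(records)
    architectures = list(architectures)
    properties = list(properties)
    if not len(records) == len(architectures) == len(properties):
        raise ValueError(
            "records, architectures and properties must have equal length"
        )
    rows = []
    for rec, arch, prop in zip(records, architectures, properties):
        rows.append(
            {
                "name": rec.name or rec.gene_id,
                "locus": rec.gene_id,
                "type": arch.type_string,
                "chromosome": rec.chromosome,
                "start": rec.start,
                "end": rec.end,
                "strand": rec.strand,
                "bp": prop.bp_len,
                "gc_percent": prop.gc_percent,
                "aa": prop.aa_len,
                "mw_kda": prop.mw_kda,
                "pi": prop.pi,
            }
        )
    df = pd.DataFrame(rows, columns=SURVEY_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep=".")
    return df


def read_survey_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."])


def read_hit_table(
    path,
    query_col: str = "query_id",
    domain_col: str = "domain_id",
    evalue_col: str = "evalue",
    sep: str = "\t",
) -> list[HitTableRow]:
    """Read a tabular domain-search hit file with configurable columns."""
    df = pd.read_csv(path, sep=sep)
    for col in (query_col, domain_col, evalue_col):
        if col not in df.columns:
            raise ValueError(f"hit table {path} lacks column {col!r}")
    return [
        HitTableRow(str(q), str(d), float(e))
        for q, d, e in zip(df[query_col], df[domain_col], df[evalue_col])
    ]
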