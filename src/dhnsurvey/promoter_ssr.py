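"""Promoter extraction, cis-element scanning and SSR mining.

Promoters are the 1500 bp immediately upstream of the translation start
(strand-aware, truncated with a warning at contig edges).  Cis-acting
elements are scanned as exact IUPAC matches on both strands against a
configurable motif table; the bundled defaults cover the eight element types
recurrent in dehydrin promoters (ABA-responsive ABRE, dehydration-responsive
DRE core, MYB binding site, low-temperature LTR, TC-rich repeats, the two
MeJA-responsive boxes, the TCA element and the anaerobic ARE).  The motif
strings are PlantCARE-conventional and fully overridable — element
nomenclature is standardised but exact site definitions vary between
databases.

SSRs (microsatellites) are maximal perfect tandem repeats with unit length
2-5, reported when they meet per-unit minimum repeat counts; units are
normalised to the lexicographically smallest rotation and a repeat whose unit
is itself periodic (e.g. ATAT) is reported at the smaller unit only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

from .config import DEFAULT_CONFIG, Config
from .core import GeneRecord

logger = logging.getLogger(__name__)

#: Default cis-element motif table (IUPAC strings, PlantCARE-conventional).
DEFAULT_ELEMENTS: dict[str, tuple[str, ...]] = {
    "ABRE": ("ACGTG",),
    "DRE-core": ("RCCGAC",),
    "MBS": ("CAACTG",),
    "LTR": ("CCGAAA",),
    "MeJA-RE": ("CGTCA", "TGACG"),
    "TCA-element": ("CCATCTTTTT",),
    "TC-rich": ("ATTTTCTTCA",),
    "ARE": ("AAACCA",),
}

SSR_CLASS = {2: "di", 3: "tri", 4: "tetra", 5: "penta"}


@dataclass(frozen=True)
class ElementHit:
    """One cis-element match, positioned on the forward promoter strand."""

    element_name: str
    position: int  # 1-based start of the matched window on the + strand
    strand: str
    matched_seq: str


@dataclass(frozen=True)
class SSRRecord:
    """One microsatellite: repeat unit, count, span and class."""

    motif: str
    unit_len: int
    repeat_count: int
    start: int
    end: int
    ssr_class: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.unit_len * self.repeat_count:
            raise ValueError("SSR span inconsistent with unit x count")


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------


def extract_promoter(
    gene: GeneRecord, genome, length: int | None = None, config: Config = DEFAULT_CONFIG
) -> str:
    """Upstream promoter sequence of a gene (default 1500 bp).

    ``genome`` is a mapping from chromosome name to sequence (for example a
    :class:`pyfaidx.Fasta`).  For a + strand gene the region is
    ``[start-length, start-1]``; for a - strand gene the reverse complement
    of ``[end+1, end+length]``.  Regions are truncated at contig edges with
    a warning.
    """
    length = length or config.promoter_length_bp
    if gene.chromosome not in genome:
        raise KeyError(f"chromosome {gene.chromosome!r} absent from genome")
    contig = str(genome[gene.chromosome][:])
    if gene.strand == "+":
        lo = gene.start - length  # 1-based
        if lo < 1:
            logger.warning(
                "promoter of %s truncated to %d bp at contig start",
                gene.gene_id, gene.start - 1,
            )
            lo = 1
        return contig[lo - 1 : gene.start - 1]
    hi = gene.end + length
    if hi > len(contig):
        logger.warning(
            "promoter of %s truncated to %d bp at contig end",
            gene.gene_id, len(contig) - gene.end,
        )
        hi = len(contig)
    return reverse_complement(contig[gene.end : hi])


# ---------------------------------------------------------------------------
# cis-element scanning
# ---------------------------------------------------------------------------


def _iupac_regex(motif: str) -> str:
    parts = []
    for code in motif.upper():
        try:
            values = ambiguous_dna_values[code]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {code!r} in motif {motif!r}") from None
        parts.append(values if len(values) == 1 else f"[{values}]")
    return "".join(parts)


def scan_elements(
    promoter: str,
    motif_table: Mapping[str, Sequence[str] | str] = DEFAULT_ELEMENTS,
) -> list[ElementHit]:
    """All exact IUPAC matches of the motif table on both strands.

    Positions are 1-based starts on the forward promoter sequence regardless
    of strand; results are sorted by position, then element name.
    """
    promoter = promoter.upper()
    hits: list[ElementHit] = []
    for name, motifs in motif_table.items():
        if isinstance(motifs, str):
            motifs = (motifs,)
        for motif in motifs:
            for strand, pattern in (("+", motif), ("-", reverse_complement(motif))):
                regex = re.compile(f"(?=({_iupac_regex(pattern)}))")
                for m in regex.finditer(promoter):
                    hits.append(ElementHit(name, m.start() + 1, strand, m.group(1)))
    hits.sort(key=lambda h: (h.position, h.element_name, h.strand))
    return hits


def element_presence(hits: Sequence[ElementHit]) -> dict[str, int]:
    """Hit counts per element name (presence = count > 0)."""
    counts: dict[str, int] = {}
    for hit in hits:
        counts[hit.element_name] = counts.get(hit.element_name, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# SSR mining
# ---------------------------------------------------------------------------


def _smallest_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _is_periodic(unit: str) -> bool:
    for d in range(1, len(unit)):
        if len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d):
            return True
    return False


def mine_ssrs(
    sequence: str,
    min_repeats: Mapping[int, int] | None = None,
    config: Config = DEFAULT_CONFIG,
) -> list[SSRRecord]:
    """Maximal perfect tandem repeats of unit length 2-5.

    A repeat is reported when its count meets the per-unit minimum (defaults:
    di >= 6, tri >= 4, tetra >= 3, penta >= 3).  Overlapping reports are
    collapsed to the repeat with the smallest unit explaining the region;
    units are normalised to their lexicographically smallest rotation and
    mononucleotide runs are excluded (a unit must not be a self-repeat).
    """
    minima = dict(min_repeats or config.ssr_min_repeats)
    seq = sequence.upper()
    candidates: list[SSRRecord] = []
    for unit_len in sorted(minima):
        need = minima[unit_len]
        i = 0
        while i + unit_len * 2 <= len(seq):
            unit = seq[i : i + unit_len]
            if _is_periodic(unit) or not set(unit) <= set("ACGT"):
                i += 1
                continue
            count = 1
            while seq[i + count * unit_len : i + (count + 1) * unit_len] == unit:
                count += 1
            if count >= need:
                candidates.append(
                    SSRRecord(
                        _smallest_rotation(unit),
                        unit_len,
                        count,
                        i + 1,
                        i + count * unit_len,
                        SSR_CLASS[unit_len],
                    )
                )
                i += count * unit_len
            else:
                i += 1
    # smallest unit explaining a region wins; then leftmost
    candidates.sort(key=lambda r: (r.start, r.unit_len))
    chosen: list[SSRRecord] = []
    for cand in candidates:
        if all(cand.start > c.end or cand.end < c.start for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda r: r.start)
    return chosen


def ssr_class_proportions(records: Sequence[SSRRecord]) -> dict[str, float]:
    """Percentage of SSRs per class (di/tri/tetra/penta), to 2 decimals."""
    total = len(records)
    if not total:
        return {}
    counts: dict[str, int] = {}
    for record in records:
        counts[record.ssr_class] = counts.get(record.ssr_class, 0) + 1
    return {cls: round(100.0 * n / total, 2) for cls, n in counts.items()}
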