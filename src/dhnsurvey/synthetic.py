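"""Synthetic fixtures with known planted truth for every pipeline stage.

Real inputs to a gene-family survey are multi-gigabyte genome releases and
RNA-seq archives; these generators emulate their relevant structure at desk
scale so that each stage can be tested by parameter recovery: dehydrin-like
proteins with planted Y/S/K segment counts, polyploid gene sets with planted
homoeolog groups, tandem arrays, deletions and unplaced genes, promoters with
planted cis-elements, SSR-bearing sequences, and TPM matrices with planted
bins and regulation labels.

All randomness flows from a single integer seed through one numpy PRNG
stream per generator (``default_rng([stream, seed])``), so adding a generator
never perturbs the output of another, and regeneration with the same seed is
byte-identical.

Default condition choices (divergence 3% between sub-genome copies, <= 1%
between tandem copies spaced under 500 kb, log-normal TPM noise) mirror what
the survey stages are designed to separate: homoeologs cluster far above the
70% similarity threshold while unrelated families fall far below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq, reverse_complement

from .config import DEFAULT_CONFIG, Config
from .core import GeneRecord, SPECIES_SUBGENOMES, write_fasta, write_gff3
from .motifs import (
    ConsensusMotif,
    K_CONSENSUS,
    S_CONSENSUS,
    Y_CONSENSUS,
    find_segments,
)
from .promoter_ssr import DEFAULT_ELEMENTS, SSR_CLASS, SSRRecord, mine_ssrs, scan_elements

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NUCLEOTIDES = np.array(list("ACGT"))
STOPS = {"TAA", "TAG", "TGA"}

# one stream constant per generator
_STREAM_PROTEIN = 11
_STREAM_FAMILY = 22
_STREAM_PROMOTER = 33
_STREAM_SSR = 44
_STREAM_EXPRESSION = 55


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, seed])


# ---------------------------------------------------------------------------
# dehydrin-like proteins
# ---------------------------------------------------------------------------


def _realize_motif(motif: ConsensusMotif, rng: np.random.Generator) -> str:
    residues = [rng.choice(sorted(allowed)) for allowed in motif.pattern]
    if motif.serine_run is not None:
        lo, hi = motif.serine_run
        residues.append("S" * int(rng.integers(lo, hi + 1)))
        residues += [rng.choice(sorted(allowed)) for allowed in motif.suffix_pattern]
    return "".join(residues)


def _mutate_protein(segment: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for aa in segment:
        if rate > 0 and rng.random() < rate:
            out.append(rng.choice(AMINO_ACIDS[AMINO_ACIDS != aa]))
        else:
            out.append(aa)
    return "".join(out)


def gen_dehydrin_protein(
    n_y: int,
    n_s: int,
    n_k: int,
    background_len: int = 200,
    mutation_rate: float = 0.0,
    seed: int = 0,
    config: Config = DEFAULT_CONFIG,
) -> tuple[str, dict]:
    """A protein with planted Y, S and K segments in Y...S...K order.

    Segments are separated by random spacers of at least 5 residues; point
    mutations are applied inside segments only, at ``mutation_rate`` per
    residue.  The background is redrawn when it would create a spurious
    segment hit at the configured scanner tolerances, so at mutation rate 0
    the planted counts are recovered exactly.  Returns (protein, truth) where
    truth records the counts, segment spans and planted type string.
    """
    if min(n_y, n_s, n_k) < 0:
        raise ValueError("segment counts must be >= 0")
    if not 0 <= mutation_rate < 0.3:
        raise ValueError("mutation_rate must be in [0, 0.3)")
    rng = _rng(seed, _STREAM_PROTEIN)
    segments = (
        [("Y", Y_CONSENSUS)] * n_y + [("S", S_CONSENSUS)] * n_s + [("K", K_CONSENSUS)] * n_k
    )
    for attempt in range(100):
        realized = [(seg, _realize_motif(motif, rng)) for seg, motif in segments]
        seg_total = sum(len(s) for _, s in realized)
        min_len = seg_total + 5 * (len(realized) + 1)
        if background_len < min_len:
            raise ValueError(
                f"background_len {background_len} too short; need >= {min_len}"
            )
        extra = background_len - min_len
        bounds = np.sort(rng.integers(0, extra + 1, size=len(realized)))
        spacer_lens = np.diff(np.concatenate([[0], bounds, [extra]])) + 5
        parts, spans, cursor = [], [], 0
        for i, (seg, seq) in enumerate(realized):
            spacer = "".join(rng.choice(AMINO_ACIDS, size=int(spacer_lens[i])))
            parts.append(spacer)
            cursor += len(spacer)
            parts.append(seq)
            spans.append((seg, cursor + 1, cursor + len(seq)))
            cursor += len(seq)
        parts.append("".join(rng.choice(AMINO_ACIDS, size=int(spacer_lens[-1]))))
        clean = "".join(parts)
        found = find_segments(clean, config)
        counts = (
            sum(h.segment == "Y" for h in found),
            sum(h.segment == "S" for h in found),
            sum(h.segment == "K" for h in found),
        )
        if counts == (n_y, n_s, n_k):
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("could not build a clean background")

    protein = clean
    if mutation_rate > 0:
        chars = list(clean)
        for _, start, end in spans:
            mutated = _mutate_protein(clean[start - 1 : end], mutation_rate, rng)
            chars[start - 1 : end] = mutated
        protein = "".join(chars)
    truth = {
        "n_y": n_y,
        "n_s": n_s,
        "n_k": n_k,
        "segments": spans,
        "type_string": ("Y" if n_y else "") + (str(n_y) if n_y > 1 else "")
        + ("S" if n_s else "") + (str(n_s) if n_s > 1 else "")
        + ("K" if n_k else "") + (str(n_k) if n_k > 1 else ""),
        "seed": seed,
    }
    return protein, truth


# ---------------------------------------------------------------------------
# polyploid family sets
# ---------------------------------------------------------------------------

SlotKey = tuple[int, str, str]  # (family, species, subgenome)


@dataclass
class ScenarioTruth:
    """Planted ground truth of a synthetic polyploid family scenario."""

    planted_groups: dict[int, dict[tuple[str, str], list[str]]]
    planted_tandems: list[list[str]]
    planted_missing: list[SlotKey]
    planted_unplaced: dict[str, str]  # gene id -> true chromosome
    planted_names: dict[str, str]
    seed: int


@dataclass
class FamilySetScenario:
    """Synthetic gene set plus its :class:`ScenarioTruth`."""

    genes: list[GeneRecord]
    truth: ScenarioTruth

    def write(self, outdir) -> dict[str, Path]:
        """Emit GFF3 + CDS/protein FASTA files for end-to-end runs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gff3": outdir / "genes.gff3",
            "cds": outdir / "cds.fasta",
            "proteins": outdir / "proteins.fasta",
        }
        write_gff3(self.genes, paths["gff3"])
        write_fasta({g.gene_id: g.cds for g in self.genes}, paths["cds"])
        write_fasta({g.gene_id: g.protein for g in self.genes}, paths["proteins"])
        return paths


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(NUCLEOTIDES, size=3))
        if codon not in STOPS:
            codons.append(codon)
    return "ATG" + "".join(codons) + "TAA"


_CODONS_FOR: dict[str, list[str]] = {}


def _codons_for(aa: str) -> list[str]:
    if not _CODONS_FOR:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, residue in standard_dna_table.forward_table.items():
            _CODONS_FOR.setdefault(residue, []).append(codon)
        for residues in _CODONS_FOR.values():
            residues.sort()
    return _CODONS_FOR[aa]


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_codons_for(aa)) for aa in protein)


def _ancestral_dhn_cds(
    architecture: tuple[int, int, int],
    rng: np.random.Generator,
    config: Config = DEFAULT_CONFIG,
) -> tuple[str, list[tuple[int, int]]]:
    """An ancestral CDS encoding a dehydrin-like protein with the planted
    (n_y, n_s, n_k) architecture; returns the CDS and the nt spans of the
    planted segments (1-based, within the CDS)."""
    n_y, n_s, n_k = architecture
    segments = (
        [_realize_motif(Y_CONSENSUS, rng) for _ in range(n_y)]
        + [_realize_motif(S_CONSENSUS, rng) for _ in range(n_s)]
        + [_realize_motif(K_CONSENSUS, rng) for _ in range(n_k)]
    )
    for _ in range(50):
        parts, spans, cursor = [], [], 1  # position after the start codon
        for segment in segments:
            spacer = "".join(rng.choice(AMINO_ACIDS, size=int(rng.integers(8, 21))))
            parts.append(spacer)
            cursor += len(spacer)
            parts.append(segment)
            spans.append((cursor, cursor + len(segment) - 1))
            cursor += len(segment)
        parts.append("".join(rng.choice(AMINO_ACIDS, size=int(rng.integers(8, 21)))))
        protein = "M" + "".join(parts)
        found = find_segments(protein, config)
        counts = (
            sum(h.segment == "Y" for h in found),
            sum(h.segment == "S" for h in found),
            sum(h.segment == "K" for h in found),
        )
        if counts == (n_y, n_s, n_k):
            break
    else:  # pragma: no cover
        raise RuntimeError("could not build a clean ancestral protein")
    cds = "ATG" + _reverse_translate(protein[1:], rng) + "TAA"
    nt_spans = [(3 * start + 1, 3 * (end + 1)) for start, end in spans]
    return cds, nt_spans


def _diverge_cds(
    cds: str,
    rate: float,
    rng: np.random.Generator,
    protected: Sequence[tuple[int, int]] = (),
) -> str:
    """Substitute bases at ``rate``, preserving frame, start/stop, avoiding
    internal stop codons and skipping ``protected`` 1-based nt spans."""
    chars = list(cds)
    for i in range(3, len(cds) - 3):  # keep ATG and the stop codon intact
        if any(start - 1 <= i <= end - 1 for start, end in protected):
            continue
        if rng.random() < rate:
            codon_start = 3 * (i // 3)
            for _ in range(10):
                new = rng.choice(NUCLEOTIDES[NUCLEOTIDES != chars[i]])
                candidate = chars[codon_start:i] + [new] + chars[i + 1 : codon_start + 3]
                if "".join(candidate) not in STOPS:
                    chars[i] = new
                    break
    return "".join(chars)


def _translate(cds: str) -> str:
    return str(Seq(cds).translate()).rstrip("*")


def gen_polyploid_family_set(
    n_families: int = 13,
    species_subgenomes: Mapping[str, Sequence[str]] = SPECIES_SUBGENOMES,
    tandem_spec: Mapping[SlotKey, int] | None = None,
    missing_spec: Sequence[SlotKey] = (),
    unplaced_spec: Sequence[SlotKey] = (),
    seed: int = 0,
    divergence: float = 0.03,
    tandem_divergence: float = 0.01,
    architecture: tuple[int, int, int] = (1, 1, 2),
) -> FamilySetScenario:
    """A multi-species, multi-subgenome gene set with planted structure.

    Each family descends from one ancestral CDS encoding a dehydrin-like
    protein with the planted ``architecture`` (default YSK2; segment-coding
    regions are protected from divergence so every member keeps its planted
    type); sub-genome copies diverge by
    ``divergence`` substitutions and tandem copies by ``tandem_divergence``,
    placed < 500 kb apart.  Families are laid out on homologous groups 3-7 in
    ascending genomic order, so recovered family indices equal planted family
    numbers.  ``missing_spec`` deletes slots, ``unplaced_spec`` moves a slot's
    genes to the unplaced chromosome "Un" (true chromosome recorded in the
    truth).  A slot that is both missing and tandem-expanded is contradictory
    and raises ``ValueError``.
    """
    tandem_spec = dict(tandem_spec or {})
    missing = set(missing_spec)
    unplaced = set(unplaced_spec)
    for key in tandem_spec:
        if key in missing:
            raise ValueError(f"slot {key} is both missing and tandem-expanded")
    for key in missing & unplaced:
        raise ValueError(f"slot {key} is both missing and unplaced")

    rng = _rng(seed, _STREAM_FAMILY)
    genes: list[GeneRecord] = []
    truth = ScenarioTruth({}, [], sorted(missing), {}, {}, seed)

    group_of = {f: 3 + (f - 1) * 5 // n_families for f in range(1, n_families + 1)}
    rank_in_group: dict[int, int] = {}
    seen: dict[int, int] = {}
    for f in range(1, n_families + 1):
        g = group_of[f]
        rank_in_group[f] = seen.get(g, 0)
        seen[g] = rank_in_group[f] + 1

    for family in range(1, n_families + 1):
        ancestor, protected = _ancestral_dhn_cds(architecture, rng)
        group = group_of[family]
        base = 1_000_000 + rank_in_group[family] * 5_000_000
        slots: dict[tuple[str, str], list[str]] = {}
        for species, subgenomes in species_subgenomes.items():
            for subgenome in subgenomes:
                key = (family, species, subgenome)
                if key in missing:
                    continue
                n_copies = tandem_spec.get(key, 1)
                slot_cds = _diverge_cds(ancestor, divergence, rng, protected)
                chromosome = f"{group}{subgenome}"
                strand = str(rng.choice(["+", "-"]))
                slot_ids = []
                for copy in range(n_copies):
                    cds = (
                        slot_cds
                        if copy == 0
                        else _diverge_cds(slot_cds, tandem_divergence, rng, protected)
                    )
                    start = base + copy * 60_000
                    gene_id = f"SYN{species}{family:02d}{subgenome}{copy + 1}"
                    is_unplaced = key in unplaced
                    genes.append(
                        GeneRecord(
                            gene_id=gene_id,
                            species=species,
                            chromosome="Un" if is_unplaced else chromosome,
                            start=start,
                            end=start + len(cds) - 1,
                            strand=strand,
                            cds=cds,
                            protein=_translate(cds),
                            subgenome="unknown" if is_unplaced else subgenome,
                        )
                    )
                    slot_ids.append(gene_id)
                    if is_unplaced:
                        truth.planted_unplaced[gene_id] = chromosome
                slots[(species, subgenome)] = slot_ids
                if n_copies > 1:
                    truth.planted_tandems.append(list(slot_ids))
                diploid = len(subgenomes) == 1
                base_name = f"{species}DHN{family}"
                for ordinal, gid in enumerate(slot_ids, start=1):
                    if diploid:
                        name = base_name if len(slot_ids) == 1 else f"{base_name}-{ordinal}"
                    elif len(slot_ids) == 1:
                        name = f"{base_name}-{subgenome}"
                    else:
                        name = f"{base_name}-{subgenome}{ordinal}"
                    truth.planted_names[gid] = name
        truth.planted_groups[family] = slots
    return FamilySetScenario(genes, truth)


# ---------------------------------------------------------------------------
# promoters with planted elements
# ---------------------------------------------------------------------------


def _realize_iupac(motif: str, rng: np.random.Generator) -> str:
    from Bio.Data.IUPACData import ambiguous_dna_values

    return "".join(rng.choice(list(ambiguous_dna_values[c])) for c in motif.upper())


def gen_promoters(
    element_spec: Mapping[str, Sequence[tuple[str, int, str]]],
    length: int = 1500,
    seed: int = 0,
    motif_table: Mapping[str, Sequence[str]] = DEFAULT_ELEMENTS,
) -> tuple[dict[str, str], dict[str, list[tuple[str, int, str]]]]:
    """Random promoters carrying exactly the planted (name, position, strand)
    elements and no other motif-table matches.

    Spurious background matches are destroyed by point changes outside the
    planted spans; a spec whose planted motifs alias each other cannot be
    realised and raises ``ValueError``.
    """
    rng = _rng(seed, _STREAM_PROMOTER)
    promoters: dict[str, str] = {}
    truth: dict[str, list[tuple[str, int, str]]] = {}
    for promoter_id, planted in element_spec.items():
        seq = list(rng.choice(NUCLEOTIDES, size=length))
        spans = []
        for name, pos, strand in planted:
            motifs = motif_table[name]
            motif = motifs[0] if not isinstance(motifs, str) else motifs
            realized = _realize_iupac(motif, rng)
            if strand == "-":
                realized = reverse_complement(realized)
            if pos < 1 or pos + len(realized) - 1 > length:
                raise ValueError(f"element {name} at {pos} does not fit")
            seq[pos - 1 : pos - 1 + len(realized)] = list(realized)
            spans.append((pos, pos + len(realized) - 1))
        planted_set = {(n, p, s) for n, p, s in planted}
        for _ in range(500):
            hits = scan_elements("".join(seq), motif_table)
            unwanted = [
                h for h in hits
                if (h.element_name, h.position, h.strand) not in planted_set
            ]
            if not unwanted:
                break
            hit = unwanted[0]
            free = [
                i
                for i in range(hit.position - 1, hit.position - 1 + len(hit.matched_seq))
                if not any(s - 1 <= i <= e - 1 for s, e in spans)
            ]
            if not free:
                raise ValueError(
                    f"planted elements alias each other at position {hit.position}"
                )
            i = int(rng.choice(free))
            seq[i] = str(rng.choice(NUCLEOTIDES[NUCLEOTIDES != seq[i]]))
        else:  # pragma: no cover
            raise RuntimeError("could not clean promoter background")
        promoters[promoter_id] = "".join(seq)
        truth[promoter_id] = sorted(planted_set, key=lambda t: t[1])
    return promoters, truth


# ---------------------------------------------------------------------------
# SSR-bearing sequences
# ---------------------------------------------------------------------------


def gen_ssr_sequences(
    ssr_spec: Mapping[str, Sequence[tuple[str, int, int]]],
    length: int = 1000,
    seed: int = 0,
    config: Config = DEFAULT_CONFIG,
) -> tuple[dict[str, str], dict[str, list[SSRRecord]]]:
    """Sequences carrying exactly the planted (unit, repeat_count, position)
    microsatellites and no other SSR meeting the configured minima."""
    rng = _rng(seed, _STREAM_SSR)
    sequences: dict[str, str] = {}
    truth: dict[str, list[SSRRecord]] = {}
    for seq_id, planted in ssr_spec.items():
        seq = list(rng.choice(NUCLEOTIDES, size=length))
        spans, records = [], []
        for unit, count, pos in planted:
            unit = unit.upper()
            repeat = unit * count
            if pos < 1 or pos + len(repeat) - 1 > length:
                raise ValueError(f"SSR {unit}x{count} at {pos} does not fit")
            seq[pos - 1 : pos - 1 + len(repeat)] = list(repeat)
            spans.append((pos, pos + len(repeat)))  # guard one extra base
            from .promoter_ssr import _smallest_rotation

            records.append(
                SSRRecord(
                    _smallest_rotation(unit),
                    len(unit),
                    count,
                    pos,
                    pos + len(repeat) - 1,
                    SSR_CLASS[len(unit)],
                )
            )
        planted_keys = {(r.start, r.end) for r in records}
        for _ in range(500):
            found = mine_ssrs("".join(seq), config=config)
            unwanted = [r for r in found if (r.start, r.end) not in planted_keys]
            if not unwanted:
                break
            bad = unwanted[0]
            free = [
                i
                for i in range(bad.start - 1, bad.end)
                if not any(s - 1 <= i <= e - 1 for s, e in spans)
            ]
            if not free:
                raise ValueError("planted SSRs alias each other")
            i = int(rng.choice(free))
            seq[i] = str(rng.choice(NUCLEOTIDES[NUCLEOTIDES != seq[i]]))
        else:  # pragma: no cover
            raise RuntimeError("could not clean SSR background")
        sequences[seq_id] = "".join(seq)
        truth[seq_id] = sorted(records, key=lambda r: r.start)
    return sequences, truth


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

#: representative TPM per planted bin (well inside each bin)
BIN_VALUES = {"low": 0.2, "medium": 5.0, "high": 40.0}
#: representative (treatment, control) TPM per planted regulation label
REGULATION_VALUES = {"UR": (40.0, 3.0), "DR": (3.0, 40.0), "none": (12.0, 11.0)}


def gen_expression_matrix(
    bin_plan: Mapping[str, str],
    conditions: Sequence[str] = ("cond1",),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """TPM matrix with a planted bin per gene (same bin in every condition),
    drawn log-normally around the bin's representative value.  At sigma 0 the
    planted bins are recovered exactly."""
    rng = _rng(seed, _STREAM_EXPRESSION)
    genes = list(bin_plan)
    values = np.empty((len(genes), len(conditions)))
    for i, gene in enumerate(genes):
        base = BIN_VALUES[bin_plan[gene]]
        noise = rng.lognormal(0.0, noise_sigma, size=len(conditions)) if noise_sigma else 1.0
        values[i] = base * noise
    matrix = pd.DataFrame(values, index=genes, columns=list(conditions))
    return matrix, dict(bin_plan)


def gen_regulation_matrix(
    regulation_plan: Mapping[str, str],
    treatment: str = "treatment",
    control: str = "control",
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Two-column TPM matrix with planted UR/DR/none labels per gene."""
    rng = _rng(seed, _STREAM_EXPRESSION)
    genes = list(regulation_plan)
    rows = []
    for gene in genes:
        t, c = REGULATION_VALUES[regulation_plan[gene]]
        if noise_sigma:
            t *= rng.lognormal(0.0, noise_sigma)
            c *= rng.lognormal(0.0, noise_sigma)
        rows.append((t, c))
    matrix = pd.DataFrame(rows, index=genes, columns=[treatment, control])
    return matrix, dict(regulation_plan)
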