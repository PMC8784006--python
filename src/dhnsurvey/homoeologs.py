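"""Cross-species / cross-subgenome homoeolog grouping, naming and auditing.

Bread wheat (AABBDD) and its relatives carry corresponding gene copies —
homoeologs — on the A, B and D sub-genomes.  This module clusters a gene set
into family groups by sequence similarity restricted to agreeing homologous
groups (the 1-7 Triticeae chromosome groups; a deterministic surrogate for
the phylogenetic + syntenic evidence used in manual curation), then:

* assigns survey names (``TaDHN4-A1``, ``TuDHN7``, ...) per the naming scheme
  (species prefix + family index + sub-genome letter, with consecutive
  ordinals for tandem co-members; diploids omit the sub-genome letter),
* infers missing slots from species ploidy (Ta: A/B/D, Td: A/B, Tu: A,
  Aet: D),
* re-assigns unplaced genes to the chromosome implied by their group, and
* flags members whose architecture departs from the group majority as
  mis-annotated or truncated.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .config import DEFAULT_CONFIG, Config
from .core import (
    Architecture,
    GeneRecord,
    SPECIES_SUBGENOMES,
    chromosome_group,
)
from .tandem import align_pair

logger = logging.getLogger(__name__)

Slot = tuple[str, str]  # (species, subgenome)


@dataclass
class HomoeologGroup:
    """One gene family slot matrix across species x sub-genome."""

    family_index: int
    homologous_group_chromosome: int | None
    slots: dict[Slot, list[str]] = field(default_factory=dict)
    members: list[str] = field(default_factory=list)
    missing_slots: list[Slot] = field(default_factory=list)
    flags: dict[str, str] = field(default_factory=dict)


def compute_similarity(
    genes: Sequence[GeneRecord],
    config: Config = DEFAULT_CONFIG,
    use_protein: bool = False,
) -> pd.DataFrame:
    """Pairwise similarity matrix: identical aligned positions over the longer
    sequence length (coverage x identity of the local alignment), symmetric,
    1.0 on the diagonal."""
    ids = [g.gene_id for g in genes]
    sim = pd.DataFrame(0.0, index=ids, columns=ids)
    for gid in ids:
        sim.loc[gid, gid] = 1.0
    for a, b in combinations(genes, 2):
        seq_a = a.protein if use_protein else a.cds
        seq_b = b.protein if use_protein else b.cds
        coverage, identity = align_pair(seq_a, seq_b, config)
        value = coverage * identity
        sim.loc[a.gene_id, b.gene_id] = value
        sim.loc[b.gene_id, a.gene_id] = value
    return sim


def build_groups(
    genes: Sequence[GeneRecord],
    similarity: pd.DataFrame,
    config: Config = DEFAULT_CONFIG,
) -> list[HomoeologGroup]:
    """Single-linkage clustering at the similarity threshold, restricted to
    genes whose homologous-group numbers agree (unplaced genes are compatible
    with any group).  Groups are indexed 1..n in genomic order (homologous
    group, then start)."""
    by_id = {g.gene_id: g for g in genes}
    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    for a, b in combinations(genes, 2):
        if similarity.loc[a.gene_id, b.gene_id] < config.group_min_similarity:
            continue
        ga, gb = a.homologous_group, b.homologous_group
        if ga is not None and gb is not None and ga != gb:
            continue
        graph.add_edge(a.gene_id, b.gene_id)

    raw_groups = []
    for component in nx.connected_components(graph):
        members = sorted(component)
        chroms = [
            by_id[m].homologous_group
            for m in members
            if by_id[m].homologous_group is not None
        ]
        group_chrom = Counter(chroms).most_common(1)[0][0] if chroms else None
        order_key = (
            group_chrom if group_chrom is not None else 99,
            min(by_id[m].start for m in members),
        )
        raw_groups.append((order_key, members, group_chrom))
    raw_groups.sort(key=lambda t: t[0])

    groups = []
    for index, (_, members, group_chrom) in enumerate(raw_groups, start=1):
        group = HomoeologGroup(index, group_chrom)
        group.members = sorted(members, key=lambda m: (by_id[m].chromosome, by_id[m].start))
        for member in group.members:
            rec = by_id[member]
            slot = (rec.species, rec.subgenome)
            group.slots.setdefault(slot, []).append(member)
        for slot_members in group.slots.values():
            slot_members.sort(key=lambda m: by_id[m].start)
        groups.append(group)
    return groups


def infer_missing(
    group: HomoeologGroup,
    expected_slots: Mapping[str, Sequence[str]] = SPECIES_SUBGENOMES,
) -> list[Slot]:
    """Expected (species, subgenome) slots with no member in this group."""
    missing = [
        (species, subgenome)
        for species, subgenomes in expected_slots.items()
        for subgenome in subgenomes
        if not group.slots.get((species, subgenome))
    ]
    group.missing_slots = missing
    return missing


def assign_names(
    groups: Sequence[HomoeologGroup],
    expected_slots: Mapping[str, Sequence[str]] = SPECIES_SUBGENOMES,
    family_prefix: str = "DHN",
) -> dict[str, str]:
    """Survey names per the naming scheme.

    Polyploid members get a sub-genome letter (``TaDHN1-A``); slots holding
    several tandem copies get consecutive ordinals (``TaDHN4-A1``); diploids
    omit the sub-genome letter (``TuDHN7``, tandems ``TuDHN4-1``).  A name
    collision indicates a grouping bug and raises ``ValueError``.
    """
    names: dict[str, str] = {}
    for group in groups:
        for (species, subgenome), members in sorted(group.slots.items()):
            diploid = len(expected_slots.get(species, ("?",))) == 1
            base = f"{species}{family_prefix}{group.family_index}"
            for ordinal, member in enumerate(members, start=1):
                if diploid:
                    name = base if len(members) == 1 else f"{base}-{ordinal}"
                elif len(members) == 1:
                    name = f"{base}-{subgenome}"
                else:
                    name = f"{base}-{subgenome}{ordinal}"
                if name in names.values():
                    raise ValueError(f"duplicate name {name!r} generated")
                names[member] = name
    return names


def reassign_unplaced(
    gene: GeneRecord,
    groups: Sequence[HomoeologGroup],
    similarity: pd.DataFrame | None = None,
    expected_slots: Mapping[str, Sequence[str]] = SPECIES_SUBGENOMES,
) -> str:
    """Place an unassigned gene on the chromosome implied by its group.

    The homologous-group number comes from the group; the sub-genome letter is
    the species' only sub-genome for diploids, otherwise the best-matching
    placed slot by mean similarity.  Genes without a group, or whose group is
    ambiguous, are left unplaced (logged) and the current chromosome returned.
    """
    group = next((g for g in groups if gene.gene_id in g.members), None)
    if group is None or group.homologous_group_chromosome is None:
        logger.warning("gene %s left unplaced: no informative group", gene.gene_id)
        return gene.chromosome
    subgenomes = expected_slots.get(gene.species, ())
    if len(subgenomes) == 1:
        subgenome = subgenomes[0]
    else:
        best, best_score = None, -1.0
        for (species, slot_sub), members in group.slots.items():
            if slot_sub == "unknown":
                continue
            placed = [m for m in members if m != gene.gene_id]
            if not placed:
                continue
            if similarity is None:
                score = len(placed)
            else:
                score = float(similarity.loc[gene.gene_id, placed].mean())
            if score > best_score:
                best, best_score = slot_sub, score
        if best is None:
            logger.warning("gene %s left unplaced: ambiguous sub-genome", gene.gene_id)
            return gene.chromosome
        subgenome = best
    new_chromosome = f"{group.homologous_group_chromosome}{subgenome}"
    old_slot = (gene.species, gene.subgenome)
    gene.chromosome = new_chromosome
    gene.subgenome = subgenome
    group.flags[gene.gene_id] = "reassigned"
    members = group.slots.get(old_slot, [])
    if gene.gene_id in members:
        members.remove(gene.gene_id)
        if not members:
            del group.slots[old_slot]
        group.slots.setdefault((gene.species, subgenome), []).append(gene.gene_id)
    return new_chromosome


def flag_anomalies(
    group: HomoeologGroup,
    architectures: Mapping[str, Architecture],
    lengths: Mapping[str, int] | None = None,
) -> dict[str, str]:
    """Flag members departing from the group majority.

    A member whose class differs from the group's majority class is flagged
    ``misannotated``; a member of the majority class whose K-segment count
    (or, when supplied, protein length at under 70% of the group median) is
    below the majority is flagged ``truncated``.
    """
    archs = {m: architectures[m] for m in group.members if m in architectures}
    if len(archs) < 2:
        return {}
    majority_cls = Counter(a.cls for a in archs.values()).most_common(1)[0][0]
    majority_nk = Counter(
        a.n_k for a in archs.values() if a.cls == majority_cls
    ).most_common(1)[0][0]
    median_len = None
    if lengths:
        known = sorted(lengths[m] for m in archs if m in lengths)
        if known:
            median_len = known[len(known) // 2]
    for member, arch in archs.items():
        if arch.cls != majority_cls:
            group.flags.setdefault(member, "misannotated")
        elif arch.n_k < majority_nk:
            group.flags.setdefault(member, "truncated")
        elif median_len and lengths and lengths.get(member, median_len) < 0.7 * median_len:
            group.flags.setdefault(member, "truncated")
    return {m: f for m, f in group.flags.items() if m in archs}


def theoretical_counts(
    slot_base: Mapping[str, int],
    expected_slots: Mapping[str, Sequence[str]] = SPECIES_SUBGENOMES,
) -> dict[str, int]:
    """Expected family size per species: the per-subgenome base count summed
    over the species' sub-genomes."""
    counts = {}
    for species, subgenomes in expected_slots.items():
        missing = [s for s in subgenomes if s not in slot_base]
        if missing:
            raise ValueError(f"slot_base lacks subgenome(s) {missing} for {species}")
        counts[species] = sum(slot_base[s] for s in subgenomes)
    return counts
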