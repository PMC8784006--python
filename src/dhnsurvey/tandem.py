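"""Tandem-duplication screening.

Two genes are called a tandem pair when (i) the alignable region covers more
than 70% of the longer gene, (ii) the aligned regions are more than 70%
identical, and (iii) they sit on the same chromosome less than 500 kb apart.
All three comparisons are strict inequalities; the thresholds live in
:class:`~dhnsurvey.config.Config`.  Alignment is affine-gap local alignment
of the CDS by default (protein mode available), since "alignable sequence"
implies a local alignment and 70% similarity is the conventional nucleotide
duplicate-screen cut-off.  Tandem arrays are the connected components of the
pairwise tandem relation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import networkx as nx
from Bio.Align import PairwiseAligner

from .config import DEFAULT_CONFIG, Config
from .core import GeneRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TandemCall:
    """Evidence and verdict for one same-chromosome gene pair."""

    gene_a: str
    gene_b: str
    coverage_frac: float
    identity_frac: float
    distance_bp: int
    same_chromosome: bool
    is_tandem: bool


def _aligner(config: Config) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = config.match_score
    aligner.mismatch_score = config.mismatch_score
    aligner.open_gap_score = config.open_gap_score
    aligner.extend_gap_score = config.extend_gap_score
    return aligner


def align_pair(
    seq_a: str, seq_b: str, config: Config = DEFAULT_CONFIG
) -> tuple[float, float]:
    """Local-align two sequences; return (coverage_frac, identity_frac).

    Coverage is the aligned span on the longer sequence divided by its length;
    identity is identical columns over all aligned columns (matches,
    mismatches and gapped columns of the local alignment).
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aln = _aligner(config).align(seq_a, seq_b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    longer = 0 if len(seq_a) >= len(seq_b) else 1
    blocks = aln.aligned[longer]
    if len(blocks) == 0:
        return 0.0, 0.0
    span = int(blocks[-1][1] - blocks[0][0])
    coverage = span / max(len(seq_a), len(seq_b))
    return coverage, identity


def is_tandem_pair(
    coverage_frac: float,
    identity_frac: float,
    distance_bp: int,
    config: Config = DEFAULT_CONFIG,
) -> bool:
    """The three tandem criteria, each a strict inequality: coverage > 70%,
    identity > 70%, chromosomal distance < 500 kb (defaults)."""
    return (
        coverage_frac > config.tandem_min_coverage
        and identity_frac > config.tandem_min_identity
        and distance_bp < config.tandem_max_distance_bp
    )


def interval_distance(a: GeneRecord, b: GeneRecord) -> int:
    """Gap in bp between the closest ends of two gene intervals (0 if they
    overlap or abut)."""
    first, second = (a, b) if a.start <= b.start else (b, a)
    return max(0, second.start - first.end)


def detect_tandems(
    genes: Sequence[GeneRecord],
    config: Config = DEFAULT_CONFIG,
    use_protein: bool = False,
) -> tuple[list[TandemCall], list[list[str]]]:
    """Evaluate every same-chromosome gene pair against the tandem criteria.

    Genes without a placed chromosome are excluded with a warning.  Returns
    all pair calls plus the tandem clusters (connected components of tandem
    pairs), each cluster ordered by genomic start and the cluster list by
    (chromosome, start).
    """
    placed = []
    for gene in genes:
        if not gene.chromosome or gene.chromosome in ("Un", "unknown"):
            logger.warning("gene %s lacks a chromosome; excluded from tandem screen",
                           gene.gene_id)
            continue
        placed.append(gene)

    calls: list[TandemCall] = []
    graph = nx.Graph()
    for a, b in combinations(placed, 2):
        # chromosome names recur across species; distance is only defined
        # within one genome
        if a.species != b.species or a.chromosome != b.chromosome:
            continue
        seq_a = a.protein if use_protein else a.cds
        seq_b = b.protein if use_protein else b.cds
        coverage, identity = align_pair(seq_a, seq_b, config)
        distance = interval_distance(a, b)
        is_tandem = is_tandem_pair(coverage, identity, distance, config)
        calls.append(
            TandemCall(a.gene_id, b.gene_id, coverage, identity, distance, True, is_tandem)
        )
        if is_tandem:
            graph.add_edge(a.gene_id, b.gene_id)

    by_id = {g.gene_id: g for g in placed}
    clusters = [
        sorted(component, key=lambda gid: (by_id[gid].start, gid))
        for component in nx.connected_components(graph)
    ]
    clusters.sort(key=lambda c: (by_id[c[0]].chromosome, by_id[c[0]].start))
    return calls, clusters
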