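"""Dehydrin segment detection and architecture classification.

Dehydrins are defined by the presence of at least one K-segment, a lysine-rich
amphiphilic helix with consensus ``EKKGIM[E/D]KIKEKLPG``.  Two further motifs
refine the classification: the N-terminal Y-segment (``[T/V]D[E/Q]YGNP``) and
the serine-tract S-segment (``LHRSGS(4-10)(E/D)3`` — a fixed prefix whose last
serine opens a run of 4-10 serines, closed by three acidic residues).  The
ordered counts of these segments give the structural type ("YSK2", "K6", ...)
which collapses to one of the classes YnSKn, YnKn, SKn, KnS or Kn.

Matching is degenerate-consensus scanning with a per-segment mismatch budget.
Real Triticeae segments diverge from the consensus, so the defaults allow 2
mismatches on K, 1 on Y and 1 on the S prefix/suffix; exact consensi always
match.  ``X`` is tolerated in input but never matches any consensus position.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .config import DEFAULT_CONFIG, Config
from .core import Architecture, HitTableRow, SegmentHit

logger = logging.getLogger(__name__)

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


def _sets(spec: Sequence[str]) -> tuple[frozenset[str], ...]:
    return tuple(frozenset(s) for s in spec)


@dataclass(frozen=True)
class ConsensusMotif:
    """A degenerate consensus: one allowed-residue set per position.

    For the S-segment, ``serine_run`` gives the (min, max) length of the
    variable serine tract inserted between ``pattern`` (the scored prefix,
    ending just before the run) and ``suffix_pattern`` (the scored acidic
    tail).  Mismatches are counted on prefix + suffix only; the run itself
    must be perfect serine.
    """

    segment: str
    pattern: tuple[frozenset[str], ...]
    max_mismatches: int = 0
    serine_run: tuple[int, int] | None = None
    suffix_pattern: tuple[frozenset[str], ...] = ()

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty consensus pattern")
        if self.serine_run is not None and self.segment != "S":
            raise ValueError("variable serine run is only defined for S")


K_CONSENSUS = ConsensusMotif(
    "K", _sets(["E", "K", "K", "G", "I", "M", "ED", "K", "I", "K", "E", "K", "L", "P", "G"])
)
Y_CONSENSUS = ConsensusMotif("Y", _sets(["TV", "D", "EQ", "Y", "G", "N", "P"]))
# prefix LHRSG; the S of "LHRSGS" starts the 4-10 serine run; 3 acidic tail
S_CONSENSUS = ConsensusMotif(
    "S",
    _sets(["L", "H", "R", "S", "G"]),
    serine_run=(4, 10),
    suffix_pattern=_sets(["ED", "ED", "ED"]),
)

_DEFAULT_TOLERANCES = {"K": "k_tolerance", "Y": "y_tolerance", "S": "s_tolerance"}


def motif_with_tolerance(motif: ConsensusMotif, config: Config) -> ConsensusMotif:
    """Return ``motif`` with the configured mismatch budget for its segment."""
    tol = getattr(config, _DEFAULT_TOLERANCES[motif.segment])
    return ConsensusMotif(
        motif.segment, motif.pattern, tol, motif.serine_run, motif.suffix_pattern
    )


def _check_protein(protein: str) -> None:
    bad = set(protein) - VALID_RESIDUES
    if bad:
        raise ValueError(f"invalid residue(s) {sorted(bad)} in protein")


def _mismatches(window: str, pattern: Sequence[frozenset[str]], budget: int) -> int | None:
    """Mismatch count of ``window`` against ``pattern``, or None if > budget."""
    n = 0
    for aa, allowed in zip(window, pattern):
        if aa not in allowed:  # X never matches
            n += 1
            if n > budget:
                return None
    return n


def _candidates(protein: str, motif: ConsensusMotif):
    """All windows within the mismatch budget, as (start0, end0, mm, seq).

    For the S-segment every serine-run length is enumerated and the best
    (fewest mismatches, then longest) candidate is kept per start position.
    """
    tol = motif.max_mismatches
    out = []
    if motif.serine_run is None:
        width = len(motif.pattern)
        for i in range(len(protein) - width + 1):
            mm = _mismatches(protein[i : i + width], motif.pattern, tol)
            if mm is not None:
                out.append((i, i + width - 1, mm, protein[i : i + width]))
        return out
    lo, hi = motif.serine_run
    npre, nsuf = len(motif.pattern), len(motif.suffix_pattern)
    for i in range(len(protein)):
        best = None
        for run in range(lo, hi + 1):
            width = npre + run + nsuf
            if i + width > len(protein):
                break
            window = protein[i : i + width]
            if set(window[npre : npre + run]) != {"S"}:
                continue
            mm = _mismatches(window[:npre] + window[npre + run :],
                             tuple(motif.pattern) + tuple(motif.suffix_pattern), tol)
            if mm is None:
                continue
            if best is None or (mm, -run) < (best[2], -(best[1] - best[0] + 1 - npre - nsuf)):
                best = (i, i + width - 1, mm, window)
        if best is not None:
            out.append(best)
    return out


def _greedy_resolve(cands) -> list[tuple[int, int, int, str, str]]:
    """Leftmost-first greedy selection of non-overlapping candidates.

    Candidates are (start0, end0, mismatches, seq, segment); ties at the same
    start are broken by fewer mismatches, then longer span.
    """
    chosen: list[tuple[int, int, int, str, str]] = []
    last_end = -1
    for cand in sorted(cands, key=lambda c: (c[0], c[2], -(c[1] - c[0]))):
        if cand[0] > last_end:
            chosen.append(cand)
            last_end = cand[1]
    return chosen


def scan_segments(protein: str, motif: ConsensusMotif) -> list[SegmentHit]:
    """Locate all non-overlapping occurrences of ``motif`` in ``protein``.

    Windows within the motif's mismatch budget are resolved leftmost-first
    into non-overlapping hits.  Coordinates are 1-based inclusive.
    """
    if not protein:
        return []
    _check_protein(protein)
    chosen = _greedy_resolve(
        [(s, e, mm, seq, motif.segment) for s, e, mm, seq in _candidates(protein, motif)]
    )
    return [
        SegmentHit(motif.segment, s + 1, e + 1, seq, mm)
        for s, e, mm, seq, _ in chosen
    ]


def _type_string(segments_in_order: Sequence[str]) -> str:
    parts = []
    for seg in segments_in_order:
        if parts and parts[-1][0] == seg:
            parts[-1][1] += 1
        else:
            parts.append([seg, 1])
    return "".join(f"{seg}{n}" if n > 1 else seg for seg, n in parts)


def _classify(order: Sequence[str]) -> Architecture:
    n_y = order.count("Y")
    n_s = order.count("S")
    n_k = order.count("K")
    if n_k == 0:
        cls = "non_dehydrin"
    elif n_y > 0 and n_s > 0:
        cls = "YnSKn"
    elif n_y > 0:
        cls = "YnKn"
    elif n_s > 0:
        last_k = max(i for i, s in enumerate(order) if s == "K")
        first_s = min(i for i, s in enumerate(order) if s == "S")
        cls = "KnS" if first_s > last_k else "SKn"
    else:
        cls = "Kn"
    return Architecture(_type_string(order), n_y, n_s, n_k, cls)


def classify_architecture(hits: Sequence[SegmentHit]) -> Architecture:
    """Collapse located segments into the dehydrin structural type.

    ``hits`` must be sorted by start and non-overlapping.  The type string
    lists segment classes in N-to-C order with run counts (count 1 omitted),
    e.g. Y,S,K,K -> "YSK2"; the class follows the segment-count rules
    (no K -> non_dehydrin; Y and S -> YnSKn; Y only -> YnKn; S only -> SKn,
    or KnS when every S lies C-terminal of every K; neither -> Kn).
    """
    hits = list(hits)
    for a, b in zip(hits, hits[1:]):
        if b.start <= a.start:
            raise ValueError("hits must be sorted by start")
        if a.overlaps(b):
            raise ValueError(f"overlapping segment hits at {a.start} and {b.start}")
    if not hits:
        return Architecture("", 0, 0, 0, "non_dehydrin")
    return _classify([h.segment for h in hits])


_TYPE_RUN = re.compile(r"([YSK])(\d*)")


def parse_type_string(type_string: str) -> tuple[int, int, int]:
    """Counts (n_y, n_s, n_k) encoded in a type string like "Y2SK3"."""
    ny = ns = nk = 0
    pos = 0
    for m in _TYPE_RUN.finditer(type_string):
        if m.start() != pos:
            raise ValueError(f"unparseable type string {type_string!r}")
        pos = m.end()
        n = int(m.group(2) or 1)
        if m.group(1) == "Y":
            ny += n
        elif m.group(1) == "S":
            ns += n
        else:
            nk += n
    if pos != len(type_string):
        raise ValueError(f"unparseable type string {type_string!r}")
    return ny, ns, nk


def classify_type_string(type_string: str) -> Architecture:
    """Re-classify a printed type string ("YSK2") through the class rules."""
    order: list[str] = []
    for m in _TYPE_RUN.finditer(type_string):
        order.extend(m.group(1) * int(m.group(2) or 1))
    if not order:
        return Architecture("", 0, 0, 0, "non_dehydrin")
    arch = _classify(order)
    if arch.type_string != type_string:
        # normalisation differences (e.g. explicit count 1) are tolerated
        arch = Architecture(type_string, arch.n_y, arch.n_s, arch.n_k, arch.cls)
    return arch


def find_segments(protein: str, config: Config = DEFAULT_CONFIG) -> list[SegmentHit]:
    """Scan a protein for Y, S and K segments jointly.

    Each segment type is scanned at its configured tolerance; candidates from
    all three are then resolved together leftmost-first (ties: fewer
    mismatches, longer span) so that cross-type overlaps cannot occur.
    """
    if not protein:
        return []
    _check_protein(protein)
    cands = []
    for motif in (Y_CONSENSUS, S_CONSENSUS, K_CONSENSUS):
        motif = motif_with_tolerance(motif, config)
        cands.extend(
            (s, e, mm, seq, motif.segment) for s, e, mm, seq in _candidates(protein, motif)
        )
    return [
        SegmentHit(seg, s + 1, e + 1, seq, mm)
        for s, e, mm, seq, seg in _greedy_resolve(cands)
    ]


def is_dehydrin(
    protein: str, config: Config = DEFAULT_CONFIG
) -> tuple[bool, Architecture]:
    """Apply the family definition: a dehydrin carries >= 1 K-segment."""
    hits = find_segments(protein, config)
    arch = classify_architecture(hits)
    return arch.n_k > 0, arch


def screen_candidates(
    hit_rows: Iterable[HitTableRow],
    proteins: Mapping[str, str],
    config: Config = DEFAULT_CONFIG,
) -> dict[str, Architecture]:
    """Dehydrin identification screen over external domain-search hits.

    Rows at or below the E-value threshold are merged and de-duplicated by
    query ID; each surviving candidate is confirmed by K-segment presence.
    Rows naming unknown proteins are skipped with a warning.  Returns the
    confirmed candidates with their architectures.
    """
    candidates: set[str] = set()
    for row in hit_rows:
        if row.evalue > config.evalue_threshold:
            continue
        if row.query_id not in proteins:
            logger.warning("hit table row for unknown protein %r skipped", row.query_id)
            continue
        candidates.add(row.query_id)
    confirmed: dict[str, Architecture] = {}
    for query_id in sorted(candidates):
        ok, arch = is_dehydrin(proteins[query_id], config)
        if ok:
            confirmed[query_id] = arch
        else:
            logger.info("candidate %s rejected: no K-segment", query_id)
    return confirmed
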