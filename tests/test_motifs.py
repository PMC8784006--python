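"""Segment scanning, architecture classification and the identification screen."""

import numpy as np
import pytest

from dhnsurvey.config import DEFAULT_CONFIG
from dhnsurvey.core import HitTableRow, SegmentHit
from dhnsurvey import motifs
from dhnsurvey.motifs import (
    ConsensusMotif,
    K_CONSENSUS,
    S_CONSENSUS,
    Y_CONSENSUS,
    classify_architecture,
    classify_type_string,
    is_dehydrin,
    parse_type_string,
    scan_segments,
    screen_candidates,
)

from conftest import random_protein

K_EXACT = "EKKGIMEKIKEKLPG"
Y_EXACT = "TDEYGNP"
S_EXACT = "LHRSG" + "S" * 5 + "EDE"


def with_tol(motif, tol):
    return ConsensusMotif(motif.segment, motif.pattern, tol, motif.serine_run,
                          motif.suffix_pattern)


# ---------------------------------------------------------------------------
# brute-force oracle: scores every window (and, for S, every serine-run
# length) directly, then selects hits by an explicit left-to-right sweep
# ---------------------------------------------------------------------------

def oracle_scan(protein, motif):
    tol = motif.max_mismatches
    cands = []
    if motif.serine_run is None:
        width = len(motif.pattern)
        for i in range(len(protein) - width + 1):
            mm = sum(protein[i + j] not in motif.pattern[j] for j in range(width))
            if mm <= tol:
                cands.append((i, i + width - 1, mm))
    else:
        lo, hi = motif.serine_run
        for i in range(len(protein)):
            per_start = []
            for run in range(lo, hi + 1):
                width = len(motif.pattern) + run + len(motif.suffix_pattern)
                if i + width > len(protein):
                    continue
                if any(protein[i + len(motif.pattern) + r] != "S" for r in range(run)):
                    continue
                mm = sum(
                    protein[i + j] not in motif.pattern[j]
                    for j in range(len(motif.pattern))
                )
                mm += sum(
                    protein[i + len(motif.pattern) + run + j] not in motif.suffix_pattern[j]
                    for j in range(len(motif.suffix_pattern))
                )
                if mm <= tol:
                    per_start.append((mm, -run, i, i + width - 1))
            if per_start:
                mm, negrun, s, e = min(per_start)
                cands.append((s, e, mm))
    # left-to-right sweep, ties by fewer mismatches then longer span
    chosen, pos = [], 0
    while cands:
        at = [c for c in cands if c[0] >= pos]
        if not at:
            break
        first = min(c[0] for c in at)
        best = min((c for c in at if c[0] == first), key=lambda c: (c[2], -(c[1] - c[0])))
        chosen.append(best)
        pos = best[1] + 1
        cands = [c for c in cands if c[0] > best[1]]
    return [(s + 1, e + 1, mm) for s, e, mm in chosen]


@pytest.mark.parametrize("motif", [K_CONSENSUS, Y_CONSENSUS, S_CONSENSUS],
                         ids=["K", "Y", "S"])
@pytest.mark.parametrize("seed", range(10))
def test_scanner_matches_bruteforce_oracle(motif, seed):
    rng = np.random.default_rng(seed)
    protein = random_protein(rng, int(rng.integers(20, 201)))
    # plant one exact consensus to make hits likely
    exact = {"K": K_EXACT, "Y": Y_EXACT, "S": S_EXACT}[motif.segment]
    pos = int(rng.integers(0, len(protein) - len(exact)))
    protein = protein[:pos] + exact + protein[pos + len(exact):]
    for tol in (0, 1, 2):
        m = with_tol(motif, tol)
        got = [(h.start, h.end, h.mismatches) for h in scan_segments(protein, m)]
        assert got == oracle_scan(protein, m)


def test_exact_consensus_hits():
    hits = scan_segments(K_EXACT, with_tol(K_CONSENSUS, 2))
    assert hits == [SegmentHit("K", 1, 15, K_EXACT, 0)]
    assert scan_segments(Y_EXACT, with_tol(Y_CONSENSUS, 1))[0].mismatches == 0
    s_hits = scan_segments(S_EXACT, with_tol(S_CONSENSUS, 1))
    assert len(s_hits) == 1 and s_hits[0].matched_seq == S_EXACT


def test_background_without_motifs_yields_nothing():
    for motif in (K_CONSENSUS, Y_CONSENSUS, S_CONSENSUS):
        assert scan_segments("A" * 50, with_tol(motif, 2)) == []
    assert scan_segments("", with_tol(K_CONSENSUS, 2)) == []


def test_two_planted_k_segments_found_at_offsets():
    rng = np.random.default_rng(99)
    protein = random_protein(rng, 100)
    protein = protein[:10] + K_EXACT + protein[25:40] + K_EXACT + protein[55:]
    hits = scan_segments(protein, with_tol(K_CONSENSUS, 2))
    assert [(h.start, h.end) for h in hits] == [(11, 25), (41, 55)]


def test_x_never_matches():
    protein = K_EXACT[:6] + "XXX" + K_EXACT[9:]
    assert scan_segments(protein, with_tol(K_CONSENSUS, 2)) == []
    with pytest.raises(ValueError):
        scan_segments("EKKB", with_tol(K_CONSENSUS, 2))


@pytest.mark.parametrize("seed", range(5))
def test_more_tolerance_never_fewer_hits(seed):
    rng = np.random.default_rng(seed)
    protein = random_protein(rng, 150)
    protein = protein[:30] + K_EXACT + protein[45:]
    previous = -1
    for tol in range(0, 6):
        n = len(scan_segments(protein, with_tol(K_CONSENSUS, tol)))
        assert n >= previous
        previous = n


# ---------------------------------------------------------------------------
# architecture classification
# ---------------------------------------------------------------------------

def _hits(spec):
    return [SegmentHit(seg, start, start + 4, "", 0) for seg, start in spec]


@pytest.mark.parametrize(
    "spec, type_string, cls",
    [
        ([("Y", 5), ("S", 40), ("K", 80), ("K", 120)], "YSK2", "YnSKn"),
        ([("Y", 3), ("Y", 30), ("S", 60), ("K", 90), ("K", 120), ("K", 150)], "Y2SK3", "YnSKn"),
        ([("K", i) for i in range(1, 120, 20)], "K6", "Kn"),
        ([("S", 5), ("K", 40), ("K", 80)], "SK2", "SKn"),
        ([("K", 5), ("K", 40), ("S", 80)], "K2S", "KnS"),
        ([("Y", 5), ("K", 40)], "YK", "YnKn"),
        ([("Y", 5), ("S", 40)], "YS", "non_dehydrin"),
    ],
)
def test_classify_architecture(spec, type_string, cls):
    arch = classify_architecture(_hits(spec))
    assert arch.type_string == type_string
    assert arch.cls == cls


def test_classify_rejects_overlaps():
    with pytest.raises(ValueError):
        classify_architecture(
            [SegmentHit("K", 1, 15, "", 0), SegmentHit("K", 10, 24, "", 0)]
        )


def test_parse_type_string_roundtrip():
    assert parse_type_string("Y2SK3") == (2, 1, 3)
    assert parse_type_string("K14") == (0, 0, 14)
    assert parse_type_string("YSK2") == (1, 1, 2)
    with pytest.raises(ValueError):
        parse_type_string("Q2")


def test_published_types_collapse_to_three_classes(table1):
    classes = {classify_type_string(t).cls for t in table1["type"]}
    assert classes == {"YnSKn", "SKn", "Kn"}


# ---------------------------------------------------------------------------
# identification screen
# ---------------------------------------------------------------------------

def test_is_dehydrin_requires_k_segment():
    ok, arch = is_dehydrin(K_EXACT)
    assert ok and arch.type_string == "K"
    rng = np.random.default_rng(3)
    spacer = random_protein(rng, 10)
    no_k = Y_EXACT + spacer + S_EXACT
    ok, arch = is_dehydrin(no_k)
    assert not ok and arch.cls == "non_dehydrin"


def test_screen_candidates_threshold_dedup_and_confirmation(caplog):
    rng = np.random.default_rng(8)
    spacer = random_protein(rng, 8)
    proteins = {
        "g1": spacer + K_EXACT + spacer,            # true dehydrin
        "g2": Y_EXACT + spacer + S_EXACT,           # no K-segment
        "g3": spacer + K_EXACT,                     # true dehydrin, weak hit only
    }
    rows = [
        HitTableRow("g1", "PF00257", 1e-30),
        HitTableRow("g1", "PF00257", 1e-25),        # duplicate query
        HitTableRow("g2", "PF00257", 1e-30),        # passes E-value, fails K check
        HitTableRow("g3", "PF00257", 1e-10),        # above threshold
        HitTableRow("ghost", "PF00257", 1e-40),     # unknown protein
    ]
    confirmed = screen_candidates(rows, proteins)
    assert set(confirmed) == {"g1"}
    assert confirmed["g1"].n_k >= 1
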