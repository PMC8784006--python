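"""Promoter extraction, cis-element scanning and SSR mining."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from dhnsurvey.core import GeneRecord
from dhnsurvey.promoter_ssr import (
    ElementHit,
    SSRRecord,
    extract_promoter,
    mine_ssrs,
    scan_elements,
    ssr_class_proportions,
)
from dhnsurvey.synthetic import gen_promoters, gen_ssr_sequences


@pytest.fixture()
def contig(rng):
    return {"5A": "".join(rng.choice(list("ACGT"), size=5000))}


def _gene(chrom, start, end, strand):
    return GeneRecord("g", "Ta", chrom, start, end, strand, cds="ATGAAATAA")


def test_plus_strand_promoter_arithmetic(contig):
    promoter = extract_promoter(_gene("5A", 2001, 2500, "+"), contig)
    assert promoter == contig["5A"][500:2000]
    assert len(promoter) == 1500


def test_minus_strand_promoter_is_revcomp(contig):
    promoter = extract_promoter(_gene("5A", 2500, 3000, "-"), contig)
    assert promoter == reverse_complement(contig["5A"][3000:4500])


def test_contig_edge_truncates_with_warning(contig, caplog):
    promoter = extract_promoter(_gene("5A", 800, 900, "+"), contig)
    assert len(promoter) == 799
    promoter = extract_promoter(_gene("5A", 4000, 4500, "-"), contig)
    assert len(promoter) == 500


def test_unknown_chromosome_raises(contig):
    with pytest.raises(KeyError):
        extract_promoter(_gene("9Z", 2001, 2500, "+"), contig)


def test_planted_element_found_at_position():
    promoter = "A" * 99 + "ACGTG" + "A" * 400
    hits = scan_elements(promoter, {"ABRE": ("ACGTG",)})
    assert [(h.element_name, h.position, h.strand) for h in hits] == [("ABRE", 100, "+")]


def test_all_a_promoter_has_no_hits():
    assert scan_elements("A" * 500) == []


def test_minus_strand_only_motif_reported_on_minus():
    # CACGT is the reverse complement of ABRE's ACGTG
    promoter = "T" * 200 + "CACGT" + "T" * 200
    hits = scan_elements(promoter, {"ABRE": ("ACGTG",)})
    assert [(h.position, h.strand) for h in hits] == [(201, "-")]


def test_iupac_degeneracy_and_validation():
    hits = scan_elements("TTTACCGACTTT", {"DRE-core": ("RCCGAC",)})
    assert hits and hits[0].matched_seq == "ACCGAC"
    with pytest.raises(ValueError):
        scan_elements("ACGT", {"bad": ("QQQ",)})


def test_generator_planted_elements_recovered_exactly():
    spec = {
        "p1": [("ABRE", 100, "+"), ("MBS", 700, "-")],
        "p2": [("LTR", 50, "+"), ("ABRE", 1400, "-")],
    }
    promoters, truth = gen_promoters(spec, seed=13)
    for pid, promoter in promoters.items():
        hits = scan_elements(promoter)
        assert [(h.element_name, h.position, h.strand) for h in hits] == truth[pid]


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------

def test_at_dinucleotide_repeat():
    records = mine_ssrs("G" * 20 + "AT" * 6 + "G" * 20)
    assert records == [SSRRecord("AT", 2, 6, 21, 32, "di")]


def test_mononucleotide_run_is_not_an_ssr():
    assert mine_ssrs("C" * 10 + "AAAAAAAAAAAA" + "G" * 10) == []


def test_periodic_unit_collapses_to_smallest():
    # ATATATAT...: reportable as AT di-repeat only, never as ATAT tetra
    records = mine_ssrs("G" * 10 + "AT" * 8 + "G" * 10)
    assert len(records) == 1 and records[0].unit_len == 2


def test_unit_normalised_to_smallest_rotation():
    records = mine_ssrs("G" * 10 + "TCA" * 5 + "G" * 10)
    assert records[0].motif == "ATC"


def test_reverse_complement_mirrors_coordinates():
    # T flanks cannot extend or phase-shift the CAG run on either strand
    seq = "T" * 15 + "CAG" * 6 + "T" * 25
    forward = mine_ssrs(seq)
    backward = mine_ssrs(reverse_complement(seq))
    assert len(forward) == len(backward) == 1
    f, b = forward[0], backward[0]
    assert (b.start, b.end) == (len(seq) - f.end + 1, len(seq) - f.start + 1)
    assert b.repeat_count == f.repeat_count and b.unit_len == f.unit_len


def test_generator_planted_ssrs_recovered():
    spec = {"s1": [("AT", 7, 50), ("CAG", 5, 400), ("ACGT", 4, 700)]}
    sequences, truth = gen_ssr_sequences(spec, seed=21)
    assert mine_ssrs(sequences["s1"]) == truth["s1"]


def test_class_proportions_match_published_split():
    records = (
        [SSRRecord("AT", 2, 6, 1 + 12 * i, 12 + 12 * i, "di") for i in range(21)]
        + [SSRRecord("AAG", 3, 4, 300 + 12 * i, 311 + 12 * i, "tri") for i in range(8)]
        + [SSRRecord("AAGG", 4, 3, 600, 611, "tetra")]
        + [SSRRecord("AAGGT", 5, 3, 700, 714, "penta")]
    )
    proportions = ssr_class_proportions(records)
    assert proportions["di"] == pytest.approx(67.74, abs=0.01)
    assert proportions["tri"] == pytest.approx(25.81, abs=0.01)
    assert proportions["tetra"] == pytest.approx(3.22, abs=0.02)
    assert proportions["penta"] == pytest.approx(3.22, abs=0.02)
    assert sum(proportions.values()) == pytest.approx(100.0, abs=0.05)


@pytest.mark.parametrize("seed", range(5))
def test_proportions_always_sum_to_100(seed):
    rng = np.random.default_rng(seed)
    spec = {"s": [("AT", 6, 100), ("AAG", 4, 300), ("ACGT", 3, 500)]}
    sequences, truth = gen_ssr_sequences(spec, seed=seed)
    props = ssr_class_proportions(mine_ssrs(sequences["s"]))
    assert sum(props.values()) == pytest.approx(100.0, abs=0.05)
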