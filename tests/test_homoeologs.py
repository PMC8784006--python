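"""Homoeolog grouping, naming, missing-gene inference and anomaly flags."""

import pytest

from dhnsurvey.core import Architecture, GeneRecord
from dhnsurvey.homoeologs import (
    HomoeologGroup,
    assign_names,
    build_groups,
    compute_similarity,
    flag_anomalies,
    infer_missing,
    reassign_unplaced,
    theoretical_counts,
)
from dhnsurvey.synthetic import gen_polyploid_family_set

from conftest import random_cds


def _scenario_groups(scenario):
    sim = compute_similarity(scenario.genes)
    groups = build_groups(scenario.genes, sim)
    return sim, groups


def _slot_matrix(groups):
    return {
        g.family_index: {slot: sorted(m) for slot, m in g.slots.items() if m}
        for g in groups
    }


def test_seven_orthologs_form_one_full_group(rng):
    cds = random_cds(rng, 150)
    genes = []
    for species, subgenomes in [("Ta", "ABD"), ("Td", "AB"), ("Tu", "A"), ("Aet", "D")]:
        for sg in subgenomes:
            genes.append(
                GeneRecord(f"{species}{sg}", species, f"3{sg}", 1000, 1000 + len(cds) - 1,
                           "+", cds=cds)
            )
    sim, groups = compute_similarity(genes), None
    groups = build_groups(genes, sim)
    assert len(groups) == 1
    assert len(groups[0].slots) == 7
    assert infer_missing(groups[0]) == []


def test_unrelated_families_stay_separate(rng):
    genes = [
        GeneRecord("f1", "Tu", "3A", 1000, 1000 + 452, "+", cds=random_cds(rng, 150)),
        GeneRecord("f2", "Tu", "3A", 900_000, 900_000 + 452, "+", cds=random_cds(rng, 150)),
    ]
    groups = build_groups(genes, compute_similarity(genes))
    assert len(groups) == 2


def test_groups_partition_gene_set(rng):
    scenario = gen_polyploid_family_set(n_families=3, seed=21)
    _, groups = _scenario_groups(scenario)
    members = [m for g in groups for m in g.members]
    assert sorted(members) == sorted(g.gene_id for g in scenario.genes)


@pytest.mark.parametrize("seed", range(20))
def test_small_scenarios_recover_planted_structure(seed):
    """Slot matrices, missing slots and names recovered exactly (no mutation
    beyond the planted sub-genome divergence)."""
    scenario = gen_polyploid_family_set(
        n_families=3,
        species_subgenomes={"Ta": ("A", "B", "D"), "Tu": ("A",)},
        tandem_spec={(2, "Ta", "B"): 2},
        missing_spec=[(3, "Tu", "A")],
        seed=seed,
    )
    sim, groups = _scenario_groups(scenario)
    assert len(groups) == 3
    expected = {
        fam: {slot: sorted(m) for slot, m in slots.items() if m}
        for fam, slots in scenario.truth.planted_groups.items()
    }
    assert _slot_matrix(groups) == expected
    names = assign_names(groups, {"Ta": ("A", "B", "D"), "Tu": ("A",)})
    assert names == scenario.truth.planted_names
    missing = [
        (g.family_index, sp, sg)
        for g in groups
        for sp, sg in infer_missing(g, {"Ta": ("A", "B", "D"), "Tu": ("A",)})
    ]
    assert missing == [(3, "Tu", "A")]


def test_tandem_slot_names_use_consecutive_ordinals():
    group = HomoeologGroup(4, 5, slots={("Ta", "A"): ["x1", "x2"], ("Tu", "A"): ["y"]},
                           members=["x1", "x2", "y"])
    names = assign_names([group])
    assert names == {"x1": "TaDHN4-A1", "x2": "TaDHN4-A2", "y": "TuDHN4"}


def test_single_member_slot_has_no_ordinal():
    group = HomoeologGroup(1, 3, slots={("Ta", "A"): ["g"]}, members=["g"])
    assert assign_names([group]) == {"g": "TaDHN1-A"}


def test_duplicate_names_raise():
    group = HomoeologGroup(1, 3, slots={("Ta", "A"): ["g"]}, members=["g"])
    other = HomoeologGroup(1, 3, slots={("Ta", "A"): ["h"]}, members=["h"])
    with pytest.raises(ValueError):
        assign_names([group, other])


def test_reassign_unplaced_recovers_planted_chromosome():
    scenario = gen_polyploid_family_set(
        n_families=3, unplaced_spec=[(2, "Tu", "A")], seed=9
    )
    sim, groups = _scenario_groups(scenario)
    unplaced = [g for g in scenario.genes if g.chromosome == "Un"]
    assert len(unplaced) == 1
    gene = unplaced[0]
    new_chrom = reassign_unplaced(gene, groups, sim)
    assert new_chrom == scenario.truth.planted_unplaced[gene.gene_id]
    owner = next(g for g in groups if gene.gene_id in g.members)
    assert owner.flags[gene.gene_id] == "reassigned"


def test_reassign_without_group_is_noop(rng):
    gene = GeneRecord("lonely", "Tu", "Un", 1, 453, "+", cds=random_cds(rng, 150))
    assert reassign_unplaced(gene, []) == "Un"


def test_flag_minority_class_as_misannotated():
    group = HomoeologGroup(12, 6, slots={}, members=["a", "b", "c"])
    archs = {
        "a": Architecture("YSK2", 1, 1, 2, "YnSKn"),
        "b": Architecture("YSK2", 1, 1, 2, "YnSKn"),
        "c": Architecture("SK2", 0, 1, 2, "SKn"),
    }
    flags = flag_anomalies(group, archs)
    assert flags == {"c": "misannotated"}


def test_flag_low_k_count_as_truncated():
    group = HomoeologGroup(8, 6, slots={}, members=["a", "b", "c"])
    archs = {
        "a": Architecture("K6", 0, 0, 6, "Kn"),
        "b": Architecture("K6", 0, 0, 6, "Kn"),
        "c": Architecture("K3", 0, 0, 3, "Kn"),
    }
    assert flag_anomalies(group, archs) == {"c": "truncated"}


def test_homogeneous_group_has_no_flags():
    group = HomoeologGroup(1, 3, slots={}, members=["a", "b"])
    archs = {k: Architecture("YSK2", 1, 1, 2, "YnSKn") for k in "ab"}
    assert flag_anomalies(group, archs) == {}


def test_theoretical_counts_follow_ploidy():
    assert theoretical_counts({"A": 17, "B": 17, "D": 17}) == {
        "Ta": 51, "Td": 34, "Tu": 17, "Aet": 17,
    }
    assert theoretical_counts({"A": 0, "B": 0, "D": 0}) == {
        "Ta": 0, "Td": 0, "Tu": 0, "Aet": 0,
    }
    with pytest.raises(ValueError):
        theoretical_counts({"A": 17})
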