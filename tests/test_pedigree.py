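"""Pedigree I/O, validation, lineage tracing and propagation."""

import numpy as np
import pytest

from helpers import oracle_line_founder, random_pedigree
from uniline.pedigree import (
    FEMALE,
    MALE,
    MATERNAL,
    PATERNAL,
    Individual,
    Pedigree,
    PedigreeCycleError,
    PedigreeError,
    SexInconsistencyError,
    UnresolvedReferenceError,
    lineage_concordance,
    propagate_lineages,
    read_pedigree,
    uniparental_founder,
    write_pedigree,
)

FOUNDER_PED = "".join(
    [f"NI\tEM{i}\t0\t0\t1\teuropean\n" for i in range(1, 10)]
    + [f"NI\tPW{i}\t0\t0\t2\tpolynesian\n" for i in range(1, 13)]
)


def trio():
    return Pedigree(
        [
            Individual("gm", None, None, FEMALE, "polynesian"),
            Individual("gf", None, None, MALE, "european"),
            Individual("mo", "gf", "gm", FEMALE),
            Individual("fa", None, None, MALE, "european"),
            Individual("kid", "fa", "mo", MALE),
        ]
    )


# -- I/O and validation ------------------------------------------------------


def test_founding_cohort_roundtrip(tmp_path):
    path = tmp_path / "founders.ped"
    path.write_text(FOUNDER_PED)
    ped = read_pedigree(path)
    assert len(ped) == 21 and len(ped.founders()) == 21
    males = [f for f in ped.founders() if f.sex == MALE]
    females = [f for f in ped.founders() if f.sex == FEMALE]
    assert len(males) == 9 and all(f.origin == "european" for f in males)
    assert len(females) == 12 and all(f.origin == "polynesian" for f in females)


def test_write_then_read_is_field_identical(tmp_path, rng):
    ped = random_pedigree(rng, max_members=300)
    path = tmp_path / "r.ped"
    write_pedigree(ped, path)
    again = read_pedigree(path)
    assert set(again.individuals) == set(ped.individuals)
    for id_, ind in ped.individuals.items():
        other = again[id_]
        assert (ind.father_id, ind.mother_id, ind.sex, ind.origin) == (
            other.father_id,
            other.mother_id,
            other.sex,
            other.origin,
        )


def test_mother_reference_to_male_rejected(tmp_path):
    path = tmp_path / "bad.ped"
    path.write_text("NI\ta\t0\t0\t1\t0\nNI\tb\t0\ta\t2\t0\n")
    with pytest.raises(SexInconsistencyError, match="mother"):
        read_pedigree(path)


def test_unresolved_parent_rejected():
    with pytest.raises(UnresolvedReferenceError):
        Pedigree([Individual("a", "ghost", None, MALE)])


def test_cycle_rejected():
    with pytest.raises(PedigreeCycleError):
        Pedigree(
            [
                Individual("a", "b", None, MALE),
                Individual("b", "a", None, MALE),
            ]
        )


def test_malformed_rows_rejected(tmp_path):
    path = tmp_path / "bad.ped"
    path.write_text("NI\ta\t0\t0\n")
    with pytest.raises(PedigreeError, match="6 columns"):
        read_pedigree(path)
    path.write_text("NI\ta\t0\t0\t3\t0\n")
    with pytest.raises(PedigreeError, match="sex"):
        read_pedigree(path)


# -- uniparental founders ----------------------------------------------------


def test_founder_is_its_own_lineage_founder():
    ped = trio()
    assert uniparental_founder(ped, "gm", MATERNAL) == "gm"
    assert uniparental_founder(ped, "fa", PATERNAL) == "fa"


def test_grandmother_chain():
    ped = trio()
    assert uniparental_founder(ped, "kid", MATERNAL) == "gm"
    assert uniparental_founder(ped, "kid", PATERNAL) == "fa"


def test_paternal_line_of_female_is_undefined():
    ped = trio()
    assert uniparental_founder(ped, "mo", PATERNAL) is None


def test_random_pedigrees_agree_with_path_walk_oracle(rng):
    for _ in range(10):
        ped = random_pedigree(rng, max_members=500)
        for id_ in ped.individuals:
            for line in (MATERNAL, PATERNAL):
                assert uniparental_founder(ped, id_, line) == oracle_line_founder(
                    ped, id_, line
                )


# -- propagation -------------------------------------------------------------


def founder_map(ped):
    out = {}
    for ind in ped.individuals.values():
        if ind.mother_id is None or ind.father_id is None:
            mt = f"MT_{ind.id}"
            y = f"Y_{ind.id}" if ind.sex == MALE else None
            out[ind.id] = (mt, y)
    return out


def test_all_founder_pedigree_keeps_own_haplotypes(tmp_path):
    path = tmp_path / "founders.ped"
    path.write_text(FOUNDER_PED)
    ped = read_pedigree(path)
    haps = founder_map(ped)
    assigned = propagate_lineages(ped, haps)
    for id_, a in assigned.items():
        assert a.mt_haplotype == haps[id_][0]
        assert a.y_haplotype == haps[id_][1]
        assert a.matriline_founder == id_


def test_propagation_matches_compositional_oracle(rng):
    for _ in range(5):
        ped = random_pedigree(rng, max_members=400)
        haps = founder_map(ped)
        assigned = propagate_lineages(ped, haps)
        for id_, a in assigned.items():
            matri = oracle_line_founder(ped, id_, MATERNAL)
            assert a.matriline_founder == matri
            assert a.mt_haplotype == haps.get(matri, (None, None))[0]
            patri = oracle_line_founder(ped, id_, PATERNAL)
            assert a.patriline_founder == patri
            if ped[id_].sex == MALE:
                assert a.y_haplotype == haps.get(patri, (None, None))[1]
            else:
                assert a.y_haplotype is None


def test_missing_founder_haplotype_rejected():
    ped = trio()
    haps = founder_map(ped)
    haps.pop("gm")
    with pytest.raises(PedigreeError, match="gm"):
        propagate_lineages(ped, haps)


def test_propagation_invariant_to_row_order(rng):
    ped = random_pedigree(rng, max_members=300)
    haps = founder_map(ped)
    rows = list(ped.individuals.values())
    rng.shuffle(rows)
    assert propagate_lineages(Pedigree(rows), haps) == propagate_lineages(ped, haps)


def test_matriline_constant_along_mother_chains(rng):
    ped = random_pedigree(rng, max_members=500)
    assigned = propagate_lineages(ped, founder_map(ped))
    for ind in ped.individuals.values():
        if ind.mother_id is not None:
            assert (
                assigned[ind.id].matriline_founder
                == assigned[ind.mother_id].matriline_founder
            )


def test_distinct_matrilines_bounded_by_female_and_unmothered_count(rng):
    ped = random_pedigree(rng, max_members=500)
    assigned = propagate_lineages(ped, founder_map(ped))
    matrilines = {a.matriline_founder for a in assigned.values()}
    bound = sum(1 for i in ped.individuals.values() if i.mother_id is None)
    assert len(matrilines) <= bound


# -- concordance -------------------------------------------------------------


def test_perfect_concordance(mt_tree):
    ped = trio()
    haps = {
        "gm": ("B4a1a1m", None),
        "gf": ("H1", "Y1"),
        "fa": ("H3", "Y2"),
    }
    assigned = propagate_lineages(ped, haps)
    calls = {id_: a.mt_haplotype for id_, a in assigned.items()}
    rate, mismatches = lineage_concordance(assigned, calls, mt_tree)
    assert rate == 1.0 and mismatches == []


def test_flipping_k_of_n_observations(mt_tree):
    ped = trio()
    assigned = propagate_lineages(
        ped, {"gm": ("B4a1a1m", None), "gf": ("H1", "Y1"), "fa": ("H3", "Y2")}
    )
    calls = {id_: a.mt_haplotype for id_, a in assigned.items()}
    flipped = ["kid", "mo"]
    for id_ in flipped:
        calls[id_] = "Q1"
    rate, mismatches = lineage_concordance(assigned, calls, mt_tree)
    assert rate == pytest.approx((5 - 2) / 5)
    assert sorted(m[0] for m in mismatches) == sorted(flipped)


def test_collapse_level_forgives_subclade_disagreement(mt_tree):
    ped = trio()
    assigned = propagate_lineages(
        ped, {"gm": ("B4a1a1m", None), "gf": ("H1", "Y1"), "fa": ("H3", "Y2")}
    )
    calls = {id_: a.mt_haplotype for id_, a in assigned.items()}
    calls["kid"] = "B4a1a1a14"  # same B4a1a1 parent clade
    exact, _ = lineage_concordance(assigned, calls, mt_tree)
    coarse, _ = lineage_concordance(assigned, calls, mt_tree, level=6)
    assert exact < 1.0 and coarse == 1.0


def test_empty_overlap_rejected(mt_tree):
    ped = trio()
    assigned = propagate_lineages(
        ped, {"gm": ("B4a1a1m", None), "gf": ("H1", "Y1"), "fa": ("H3", "Y2")}
    )
    with pytest.raises(ValueError, match="overlap"):
        lineage_concordance(assigned, {"nobody": "H1"}, mt_tree)
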