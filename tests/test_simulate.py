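"""Founder-isolate simulator: demography, haplotype draws, noise model."""

import dataclasses
import warnings

import numpy as np
import pytest

from uniline.caller import call_haplogroups
from uniline.pedigree import FEMALE, MALE, propagate_lineages
from uniline.simulate import (
    ExtinctionWarning,
    SimulationConfig,
    apply_variants_to_sequence,
    assign_founder_haplotypes,
    call_based_ancestry_fractions,
    generate_variant_profiles,
    haplotype_sequence,
    simulate_pedigree,
    synthetic_mtdna_reference,
)
from uniline.pedigree import write_pedigree
from uniline.variants import parse_variant, parse_variant_list


def small_cfg(**kw):
    defaults = dict(generations=4, max_pop=300, seed=7)
    defaults.update(kw)
    return SimulationConfig(**defaults)


# -- demography --------------------------------------------------------------


def test_default_founder_set_matches_the_settlement_scenario():
    ped = simulate_pedigree(SimulationConfig(seed=1))
    founders = ped.founders()
    gen0_males = [f for f in founders if f.sex == MALE and f.generation == 0]
    gen0_females = [f for f in founders if f.sex == FEMALE and f.generation == 0]
    immigrants = [f for f in founders if f.generation and f.generation > 0]
    assert len(gen0_males) == 9 and all(f.origin == "european" for f in gen0_males)
    assert len(gen0_females) == 12 and all(f.origin == "polynesian" for f in gen0_females)
    assert len(immigrants) == 3
    assert all(f.sex == MALE and f.origin == "european" for f in immigrants)
    assert len(ped) <= 1400


def test_zero_generations_gives_founders_only():
    ped = simulate_pedigree(SimulationConfig(generations=0, seed=3))
    assert len(ped) == 21 and all(i.is_founder for i in ped.individuals.values())


def test_same_seed_gives_byte_identical_ped(tmp_path):
    paths = []
    for name in ("a.ped", "b.ped"):
        ped = simulate_pedigree(small_cfg(seed=42))
        path = tmp_path / name
        write_pedigree(ped, path)
        paths.append(path.read_bytes())
    assert paths[0] == paths[1]


def test_different_seeds_differ(tmp_path):
    a = simulate_pedigree(small_cfg(seed=1))
    b = simulate_pedigree(small_cfg(seed=2))
    assert {i.id: (i.father_id, i.mother_id) for i in a.individuals.values()} != {
        i.id: (i.father_id, i.mother_id) for i in b.individuals.values()
    }


def test_extinction_is_flagged_not_silent():
    with pytest.warns(ExtinctionWarning):
        simulate_pedigree(small_cfg(offspring_rate=0.0, generations=3))


def test_population_growth_matches_poisson_expectation():
    """Expected next-generation size = couples x offspring_rate."""
    rate, couples = 2.5, 5
    cfg = dict(
        n_male_founders=couples,
        n_female_founders=couples,
        generations=1,
        offspring_rate=rate,
        max_pop=10_000,
        immigrants=(),
    )
    sizes = []
    for seed in range(200):
        ped = simulate_pedigree(SimulationConfig(seed=seed, **cfg))
        sizes.append(len(ped) - 2 * couples)
    mean = np.mean(sizes)
    se = np.sqrt(rate * couples / 200)  # Poisson-sum variance over replicates
    assert abs(mean - rate * couples) < 3 * se


def test_invalid_rates_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(dropout_rate=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(polynesian_b_prob=-0.1)


# -- founder haplotypes ------------------------------------------------------


def test_every_founder_gets_assigned_haplotypes(mt_tree, y_tree):
    cfg = small_cfg()
    ped = simulate_pedigree(cfg)
    haps = assign_founder_haplotypes(ped, mt_tree, y_tree, cfg)
    assert set(haps) == {f.id for f in ped.founders()}
    for f in ped.founders():
        mt, y = haps[f.id]
        assert mt in mt_tree
        assert (y is None) == (f.sex == FEMALE)
        if y is not None:
            assert y in y_tree


def test_polynesian_b_fraction_within_binomial_band(mt_tree, y_tree):
    cfg = SimulationConfig(
        n_male_founders=0, n_female_founders=500, generations=0, seed=17, immigrants=()
    )
    ped = simulate_pedigree(cfg)
    haps = assign_founder_haplotypes(ped, mt_tree, y_tree, cfg)
    in_b4 = sum(mt_tree.is_descendant(mt, "B4") for mt, _ in haps.values())
    p = cfg.polynesian_b_prob
    sd = np.sqrt(500 * p * (1 - p))
    assert abs(in_b4 - 500 * p) < 3 * sd


def test_outlier_probability_zero_gives_no_e_branch(mt_tree, y_tree):
    cfg = dataclasses.replace(small_cfg(), y_outlier_prob=0.0)
    ped = simulate_pedigree(cfg)
    haps = assign_founder_haplotypes(ped, mt_tree, y_tree, cfg)
    for _, y in haps.values():
        if y is not None:
            assert y_tree.is_descendant(y, "F")


def test_fixed_seed_gives_identical_haplotype_map(mt_tree, y_tree):
    cfg = small_cfg()
    ped = simulate_pedigree(cfg)
    a = assign_founder_haplotypes(ped, mt_tree, y_tree, cfg)
    b = assign_founder_haplotypes(ped, mt_tree, y_tree, cfg)
    assert a == b


# -- variant profiles --------------------------------------------------------


def pipeline_to_profiles(cfg, mt_tree, y_tree, dropout=0.0, fp=0.0, seed=5):
    ped = simulate_pedigree(cfg)
    haps = assign_founder_haplotypes(ped, mt_tree, y_tree, cfg)
    assigned = propagate_lineages(ped, haps)
    profiles = generate_variant_profiles(
        assigned, mt_tree, dropout_rate=dropout, false_positive_rate=fp, seed=seed
    )
    return ped, assigned, profiles


def test_noise_free_profiles_recover_haplogroups_exactly(mt_tree, y_tree):
    ped, assigned, profiles = pipeline_to_profiles(small_cfg(), mt_tree, y_tree)
    for p in profiles:
        assert p.variants == mt_tree.cumulative_variants(assigned[p.sample_id].mt_haplotype)
    calls = call_haplogroups(profiles, mt_tree)
    assert all(c.best_node == assigned[c.sample_id].mt_haplotype for c in calls)


def test_dropout_fraction_within_binomial_band(mt_tree, y_tree):
    delta = 0.5
    ped, assigned, profiles = pipeline_to_profiles(
        small_cfg(max_pop=600, generations=6), mt_tree, y_tree, dropout=delta
    )
    planted = kept = 0
    for p in profiles:
        expected = mt_tree.cumulative_variants(assigned[p.sample_id].mt_haplotype)
        planted += len(expected)
        kept += len(p.variants & expected)
    assert planted >= 1000
    dropped = planted - kept
    sd = np.sqrt(planted * delta * (1 - delta))
    assert abs(dropped - planted * delta) < 3 * sd


def test_no_false_positives_when_mu_zero(mt_tree, y_tree):
    ped, assigned, profiles = pipeline_to_profiles(small_cfg(), mt_tree, y_tree, dropout=0.3)
    for p in profiles:
        expected = mt_tree.cumulative_variants(assigned[p.sample_id].mt_haplotype)
        assert p.variants <= expected


def test_false_positives_land_outside_tree_positions(mt_tree, y_tree):
    ped, assigned, profiles = pipeline_to_profiles(
        small_cfg(), mt_tree, y_tree, fp=2.0
    )
    tree_positions = {
        v.position
        for node in mt_tree.nodes.values()
        for v in node.defining_variants
    }
    extra = 0
    for p in profiles:
        expected = mt_tree.cumulative_variants(assigned[p.sample_id].mt_haplotype)
        for v in p.variants - expected:
            extra += 1
            assert v.position not in tree_positions
    assert extra > 0


def test_concordance_degrades_monotonically_in_dropout(mt_tree, y_tree):
    from uniline.pedigree import lineage_concordance

    cfg = small_cfg(max_pop=400, generations=5)
    ped = simulate_pedigree(cfg)
    haps = assign_founder_haplotypes(ped, mt_tree, y_tree, cfg)
    assigned = propagate_lineages(ped, haps)
    rates = []
    for delta in (0.0, 0.2, 0.4, 0.6, 0.8):
        profiles = generate_variant_profiles(
            assigned, mt_tree, dropout_rate=delta, seed=123
        )
        calls = {c.sample_id: c.best_node for c in call_haplogroups(profiles, mt_tree)}
        rate, _ = lineage_concordance(assigned, calls, mt_tree)
        rates.append(rate)
    assert rates[0] == 1.0
    assert all(a >= b for a, b in zip(rates, rates[1:]))


# -- sequence synthesis ------------------------------------------------------


def test_reference_has_mt_genome_length():
    assert len(synthetic_mtdna_reference()) == 16_569


def test_empty_variant_set_is_identity():
    ref = synthetic_mtdna_reference()
    assert apply_variants_to_sequence(ref, []) == ref


def test_single_substitution_changes_exactly_one_base():
    ref = synthetic_mtdna_reference()
    out = apply_variants_to_sequence(ref, [parse_variant("A1692G")])
    diffs = [i for i, (a, b) in enumerate(zip(ref, out)) if a != b]
    assert len(out) == len(ref)
    assert diffs == [1691] and out[1691] == "G"


def test_wildcard_substitution_still_changes_the_base():
    ref = synthetic_mtdna_reference()
    out = apply_variants_to_sequence(ref, [parse_variant("1692")])
    assert out[1691] != ref[1691] and len(out) == len(ref)


def test_range_deletion_shortens_by_nine_and_flips_assay_genotype(mt_tree):
    from uniline.assay import assay_sample

    ref = synthetic_mtdna_reference()
    assert assay_sample("s", ref).genotype == "deletion_absent"
    out = apply_variants_to_sequence(ref, [parse_variant("8281-8289d")])
    assert len(out) == len(ref) - 9
    assert assay_sample("s", out).genotype == "deletion_present"


def test_out_of_range_and_overlapping_edits_rejected():
    ref = "ACGT" * 10
    with pytest.raises(ValueError, match="outside"):
        apply_variants_to_sequence(ref, [parse_variant("41")])
    with pytest.raises(ValueError, match="overlap"):
        apply_variants_to_sequence(ref, parse_variant_list("5-9d,A7G"))


# -- end-to-end recovery -----------------------------------------------------


def test_noise_free_pipeline_recovers_traced_fractions_exactly(mt_tree, y_tree):
    cfg = small_cfg(max_pop=500, generations=6)
    ped = simulate_pedigree(cfg)
    haps = assign_founder_haplotypes(ped, mt_tree, y_tree, cfg)
    assigned = propagate_lineages(ped, haps)
    leaves = ped.leaves()
    profiles = generate_variant_profiles(assigned, mt_tree, seed=2, samples=leaves)
    calls = {c.sample_id: c.best_node for c in call_haplogroups(profiles, mt_tree)}
    from uniline.admixture import ancestry_fractions

    maternal, _ = ancestry_fractions(assigned, ped, leaves)
    inferred = call_based_ancestry_fractions(calls, mt_tree, cfg, leaves)
    assert inferred == maternal
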