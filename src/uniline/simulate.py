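"""Synthetic founder-isolate cohorts with the statistical structure of the
Bounty/Pitcairn/Norfolk settlement.

The default configuration encodes the historical scenario: 9 European male
and 12 Polynesian female founders, ~11 non-overlapping generations growing to
a cap of ~1400 individuals, three later European male immigrants within the
first three generations, Polynesian founders carrying haplogroup-B4 mtDNA
with probability 0.9 (the clade accounts for the large majority of Polynesian
mitochondrial lineages), European founders carrying haplogroup-H mtDNA and
F-branch Y lineages with a rare E1b1a1 outlier.

Everything downstream of the pedigree — founder haplotypes, noisy variant
profiles, consensus-like sequences for the in-silico PCR — is generated from
one seed, so the whole pipeline is reproducible and testable offline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .caller import VariantProfile
from .pedigree import FEMALE, MALE, Individual, LineageAssignment, Pedigree
from .reference import MTDNA, YCHROM, ReferenceTree
from .variants import DELETION, INSERTION, OPAQUE, SUBSTITUTION, Variant, parse_variant

MT_REFERENCE_LENGTH = 16_569

# rCRS-homologous layout of the COII/tRNA-Lys screen (1-based coordinates):
# forward primer 8196-8217, CCCCCTCTA x2 repeat 8272-8289, reverse-primer
# binding site 8307-8328 — an end-to-end product of 133 bp, or 124 bp once
# one repeat copy (8281-8289) is lost.
_FWD_SITE_START = 8196
_REPEAT_START = 8272
_REV_SITE_END = 8328

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class ExtinctionWarning(UserWarning):
    """The simulated population died out before the requested generations."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the founder-isolate simulator."""

    n_male_founders: int = 9
    n_female_founders: int = 12
    male_founder_origin: str = "european"
    female_founder_origin: str = "polynesian"
    generations: int = 11
    offspring_rate: float = 3.0
    max_pop: int = 1400
    # (generation, sex, origin, count): later settlers entering as founders
    immigrants: tuple[tuple[int, str, str, int], ...] = (
        (1, MALE, "european", 1),
        (2, MALE, "european", 1),
        (3, MALE, "european", 1),
    )
    dropout_rate: float = 0.0
    false_positive_rate: float = 0.0
    polynesian_b_prob: float = 0.9
    y_outlier_prob: float = 1 / 223
    polynesian_b_clade: str = "B4"
    # the deletion-bearing level above B4; excluded from the non-B pool so
    # the 9-bp screen remains a clean proxy for the B4 assignment
    deletion_clade: str = "B"
    european_mt_clade: str = "H"
    european_mt_stem: str = "HV"
    european_y_clade: str = "F"
    y_outlier_node: str = "E1b1a1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "false_positive_rate", "polynesian_b_prob", "y_outlier_prob"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_male_founders < 0 or self.n_female_founders < 0:
            raise ValueError("founder counts must be >= 0")


# -- pedigree growth ---------------------------------------------------------


def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Forward-time growth with non-overlapping generations and monogamous
    random pairing; offspring per couple ~ Poisson(offspring_rate); total
    size capped at ``max_pop``. Identical seeds give identical pedigrees."""
    rng = np.random.default_rng(cfg.seed)
    individuals: list[Individual] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:05d}"

    def add_founder(sex: str, origin: str, generation: int) -> Individual:
        ind = Individual(new_id(), None, None, sex, origin, generation)
        individuals.append(ind)
        return ind

    current: list[Individual] = []
    for _ in range(cfg.n_male_founders):
        current.append(add_founder(MALE, cfg.male_founder_origin, 0))
    for _ in range(cfg.n_female_founders):
        current.append(add_founder(FEMALE, cfg.female_founder_origin, 0))
    for gen, sex, origin, count in cfg.immigrants:
        if gen == 0:
            for _ in range(count):
                current.append(add_founder(sex, origin, 0))

    for gen in range(1, cfg.generations + 1):
        males = [i for i in current if i.sex == MALE]
        females = [i for i in current if i.sex == FEMALE]
        rng.shuffle(males)
        rng.shuffle(females)
        couples = list(zip(males, females))
        children: list[Individual] = []
        room = cfg.max_pop - len(individuals)
        for father, mother in couples:
            for _ in range(int(rng.poisson(cfg.offspring_rate))):
                sex = MALE if rng.random() < 0.5 else FEMALE
                children.append(
                    Individual(new_id(), father.id, mother.id, sex, "unknown", gen)
                )
        if len(children) > room:
            keep = rng.choice(len(children), size=max(room, 0), replace=False)
            children = [children[i] for i in sorted(keep)]
        individuals.extend(children)
        current = list(children)
        for g, sex, origin, count in cfg.immigrants:
            if g == gen:
                for _ in range(count):
                    current.append(add_founder(sex, origin, gen))
        # hitting the population cap is not extinction; only a generation
        # that could have reproduced but did not counts
        if not children and gen < cfg.generations and room > 0:
            warnings.warn(
                f"population extinct at generation {gen} of {cfg.generations}",
                ExtinctionWarning,
                stacklevel=2,
            )
            break
    return Pedigree(individuals)


# -- founder haplotypes ------------------------------------------------------


def clade_pools(mt_tree: ReferenceTree, cfg: SimulationConfig) -> dict[str, list[str]]:
    """Tip pools per ancestry: Polynesian B4 tips, Polynesian non-B tips,
    European H tips."""
    b_pool = [t for t in mt_tree.tips() if mt_tree.is_descendant(t, cfg.polynesian_b_clade)]
    eur_pool = [t for t in mt_tree.tips() if mt_tree.is_descendant(t, cfg.european_mt_clade)]
    alt_pool = [
        t
        for t in mt_tree.tips()
        if not mt_tree.is_descendant(t, cfg.deletion_clade)
        and not mt_tree.is_descendant(t, cfg.european_mt_stem)
    ]
    return {"polynesian_b": b_pool, "polynesian_alt": alt_pool, "european": eur_pool}


def assign_founder_haplotypes(
    ped: Pedigree,
    mt_tree: ReferenceTree,
    y_tree: ReferenceTree,
    cfg: SimulationConfig,
    seed: int | None = None,
) -> dict[str, tuple[str, str | None]]:
    """Draw an mtDNA haplogroup for every founder and a Y haplogroup for
    every male founder, from origin-specific clade pools."""
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    pools = clade_pools(mt_tree, cfg)
    y_pool = [t for t in y_tree.tips() if y_tree.is_descendant(t, cfg.european_y_clade)]
    for name, pool in list(pools.items()) + [("european_y", y_pool)]:
        if not pool:
            raise ValueError(f"empty clade pool: {name}")
    all_tips = mt_tree.tips()

    out: dict[str, tuple[str, str | None]] = {}
    for founder in sorted(ped.founders(), key=lambda i: i.id):
        if founder.origin == "polynesian":
            if rng.random() < cfg.polynesian_b_prob:
                mt = pools["polynesian_b"][rng.integers(len(pools["polynesian_b"]))]
            else:
                mt = pools["polynesian_alt"][rng.integers(len(pools["polynesian_alt"]))]
        elif founder.origin == "european":
            mt = pools["european"][rng.integers(len(pools["european"]))]
        else:
            mt = all_tips[rng.integers(len(all_tips))]
        y: str | None = None
        if founder.sex == MALE:
            if rng.random() < cfg.y_outlier_prob:
                y = cfg.y_outlier_node
            else:
                y = y_pool[rng.integers(len(y_pool))]
        out[founder.id] = (mt, y)
    return out


def origin_of_haplogroup(haplogroup: str, mt_tree: ReferenceTree, cfg: SimulationConfig) -> str:
    """Ancestry label implied by an mtDNA haplogroup under the simulator's
    origin-specific clade pools (the inverse of the founder draw)."""
    if mt_tree.is_descendant(haplogroup, cfg.deletion_clade):
        return "polynesian"
    if mt_tree.is_descendant(haplogroup, cfg.european_mt_stem):
        return "european"
    return "polynesian"


def call_based_ancestry_fractions(
    calls: Mapping[str, str],
    mt_tree: ReferenceTree,
    cfg: SimulationConfig,
    subset: Sequence[str],
) -> dict[str, float]:
    """Maternal origin fractions inferred purely from per-sample haplogroup
    calls — the sequencing-side estimator, to contrast with pedigree tracing."""
    subset = list(subset)
    if not subset:
        raise ValueError("empty subset")
    labels = [origin_of_haplogroup(calls[id_], mt_tree, cfg) for id_ in subset]
    return {
        o: labels.count(o) / len(labels) for o in sorted(set(labels))
    }


# -- variant profiles --------------------------------------------------------


def generate_variant_profiles(
    assignments: Mapping[str, LineageAssignment],
    tree: ReferenceTree,
    dropout_rate: float = 0.0,
    false_positive_rate: float = 0.0,
    seed: int = 0,
    marker: str = "mt",
    samples: Iterable[str] | None = None,
) -> list[VariantProfile]:
    """Observed profiles: each expected variant dropped with probability
    ``dropout_rate``; Poisson(``false_positive_rate``-mean) private variants
    added at positions the reference tree never uses."""
    if not 0.0 <= dropout_rate <= 1.0:
        raise ValueError("dropout_rate must be in [0, 1]")
    if false_positive_rate < 0.0:
        raise ValueError("false_positive_rate must be >= 0")
    rng = np.random.default_rng(seed)
    used_positions = {
        v.position
        for node in tree.nodes.values()
        for v in node.defining_variants
        if v.position is not None
    }
    free_positions = sorted(set(range(1, MT_REFERENCE_LENGTH + 1)) - used_positions)
    marker_type = MTDNA if marker == "mt" else YCHROM

    profiles = []
    ids = sorted(samples) if samples is not None else sorted(assignments)
    for id_ in ids:
        hap = (
            assignments[id_].mt_haplotype
            if marker == "mt"
            else assignments[id_].y_haplotype
        )
        if hap is None:
            continue
        observed = []
        for v in sorted(tree.cumulative_variants(hap)):
            if dropout_rate == 0.0 or rng.random() >= dropout_rate:
                observed.append(v)
        n_fp = int(rng.poisson(false_positive_rate)) if false_positive_rate else 0
        if n_fp:
            picks = rng.choice(len(free_positions), size=min(n_fp, len(free_positions)), replace=False)
            for i in sorted(picks):
                pos = free_positions[i]
                token = str(pos) if marker == "mt" else f"FP{pos}"
                observed.append(parse_variant(token))
        profiles.append(VariantProfile(id_, frozenset(observed), marker_type))
    return profiles


# -- sequences ---------------------------------------------------------------


def synthetic_mtdna_reference(seed: int = 2015, length: int = MT_REFERENCE_LENGTH) -> str:
    """A seeded random mitochondrial-genome-length sequence with the two
    mtDEL primer sites and the CCCCCTCTA tandem repeat implanted at the
    rCRS-homologous offsets, so the 9-bp-deletion screen runs offline."""
    from .assay import MTDEL_FORWARD, MTDEL_REVERSE, reverse_complement

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = list("".join(rng.choice(bases, size=length)))

    def implant(start_1based: int, fragment: str) -> None:
        i = start_1based - 1
        seq[i : i + len(fragment)] = list(fragment)

    implant(_FWD_SITE_START, MTDEL_FORWARD)
    implant(_REPEAT_START, "CCCCCTCTA" * 2)
    implant(_REV_SITE_END - len(MTDEL_REVERSE) + 1, reverse_complement(MTDEL_REVERSE))
    return "".join(seq)


def apply_variants_to_sequence(reference: str, variants: Iterable[Variant]) -> str:
    """Apply substitutions and range deletions to a sequence.

    Substitutions replace in place (a wildcard allele becomes the transition
    partner of the reference base); deletions remove their range, shifting
    downstream coordinates. Out-of-range positions and overlapping edits are
    errors; insertions and opaque tokens cannot be applied to a sequence.
    """
    edits = sorted(
        (v for v in variants), key=lambda v: (v.position or 0, v.token)
    )
    spans: list[tuple[int, int]] = []
    seq = list(reference)
    deletions: list[tuple[int, int]] = []
    for v in edits:
        if v.kind in (INSERTION, OPAQUE):
            raise ValueError(f"cannot apply {v.kind} token {v.token!r} to a sequence")
        start = v.position
        end = v.end if v.kind == DELETION else v.position
        assert start is not None and end is not None
        if start < 1 or end > len(reference):
            raise ValueError(f"variant {v.token!r} outside reference (len {len(reference)})")
        for s, e in spans:
            if start <= e and end >= s:
                raise ValueError(f"overlapping edit at {v.token!r}")
        spans.append((start, end))
        if v.kind == SUBSTITUTION:
            ref_base = reference[start - 1].upper()
            seq[start - 1] = v.derived_allele or _TRANSITION.get(ref_base, "A")
        else:
            deletions.append((start, end))
    for start, end in sorted(deletions, reverse=True):
        del seq[start - 1 : end]
    return "".join(seq)


def haplotype_sequence(reference: str, tree: ReferenceTree, haplogroup: str) -> str:
    """Consensus-like sequence for one haplogroup: the reference with the
    clade's cumulative variants applied."""
    return apply_variants_to_sequence(reference, tree.cumulative_variants(haplogroup))
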