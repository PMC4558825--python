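"""Sex-biased admixture statistics from uniparental lineage assignments.

The maternal (mtDNA) and paternal (Y) ancestry fractions of a cohort are the
proportions of its members whose matriline / patriline founder carries each
origin label. Contrasting the two quantifies gender-biased admixture: in a
founder isolate seeded by men of one origin and women of another the two
fractions diverge toward opposite extremes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .pedigree import MALE, MATERNAL, PATERNAL, LineageAssignment, Pedigree


@dataclass(frozen=True)
class AdmixtureEstimate:
    """Point estimates, bootstrap intervals and lineage-survival counts for
    one evaluation cohort."""

    subset: str
    maternal_fraction_by_origin: dict[str, float]
    paternal_fraction_by_origin: dict[str, float] | None
    ci: dict[str, tuple[float, float]]
    matriline_survivors: int
    patriline_survivors: int
    bias_index: float | None


def _founder_origins(
    assignments: Mapping[str, LineageAssignment],
    ped: Pedigree,
    subset: Sequence[str],
    line: str,
) -> list[str]:
    """Origin label of each subset member's lineage founder; paternal lines
    cover only males with a defined patriline."""
    out = []
    for id_ in subset:
        if id_ not in ped:
            raise KeyError(id_)
        founder = (
            assignments[id_].matriline_founder
            if line == MATERNAL
            else assignments[id_].patriline_founder
        )
        if founder is None:
            continue
        out.append(ped[founder].origin)
    return out


def ancestry_fractions(
    assignments: Mapping[str, LineageAssignment],
    ped: Pedigree,
    subset: Sequence[str] | None = None,
) -> tuple[dict[str, float], dict[str, float] | None]:
    """(maternal, paternal) origin-fraction maps over the cohort.

    Maternal fractions are over the whole subset (everyone has a matriline);
    paternal fractions are over the males with a defined patriline and are
    ``None`` — undefined, not zero — when the subset contains no such male.
    Each map sums to 1 over the origins present.
    """
    subset = list(subset) if subset is not None else ped.leaves()
    if not subset:
        raise ValueError("empty evaluation subset")
    maternal_origins = _founder_origins(assignments, ped, subset, MATERNAL)
    paternal_origins = _founder_origins(assignments, ped, subset, PATERNAL)
    maternal = {
        o: n / len(maternal_origins) for o, n in sorted(Counter(maternal_origins).items())
    }
    if paternal_origins:
        paternal = {
            o: n / len(paternal_origins)
            for o, n in sorted(Counter(paternal_origins).items())
        }
    else:
        paternal = None
    return maternal, paternal


def bootstrap_ci(
    assignments: Mapping[str, LineageAssignment],
    ped: Pedigree,
    subset: Sequence[str],
    origin: str,
    line: str = MATERNAL,
    reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for one origin's lineage fraction.

    Individuals are resampled with replacement ``reps`` times; fully
    reproducible given ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    origins = _founder_origins(assignments, ped, list(subset), line)
    if not origins:
        raise ValueError(f"no individuals with a defined {line} line in subset")
    indicator = np.array([o == origin for o in origins], dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(indicator), size=(reps, len(indicator)))
    means = indicator[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def lineage_survival(
    assignments: Mapping[str, LineageAssignment],
    ped: Pedigree,
    subset: Sequence[str] | None = None,
    line: str = MATERNAL,
    origin: str | None = None,
) -> int:
    """Number of distinct founder lineages with at least one member in the
    cohort, optionally restricted to founders of one origin."""
    subset = list(subset) if subset is not None else ped.leaves()
    if not subset:
        raise ValueError("empty evaluation subset")
    founders = set()
    for id_ in subset:
        founder = (
            assignments[id_].matriline_founder
            if line == MATERNAL
            else assignments[id_].patriline_founder
        )
        if founder is None:
            continue
        if origin is not None and ped[founder].origin != origin:
            continue
        founders.add(founder)
    return len(founders)


def gender_bias_index(
    maternal: Mapping[str, float], paternal: Mapping[str, float] | None, origin: str
) -> float:
    """maternal_fraction(origin) - paternal_fraction(origin), in [-1, 1]."""
    if paternal is None:
        raise ValueError("paternal fractions undefined (no males in subset)")
    return maternal.get(origin, 0.0) - paternal.get(origin, 0.0)


def estimate_admixture(
    assignments: Mapping[str, LineageAssignment],
    ped: Pedigree,
    subset: Sequence[str] | None = None,
    bias_origin: str = "polynesian",
    reps: int = 1000,
    seed: int = 0,
) -> AdmixtureEstimate:
    """One-call summary: fractions, CIs per origin (maternal line), survival
    counts and the gender-bias index for ``bias_origin``."""
    ids = list(subset) if subset is not None else ped.leaves()
    maternal, paternal = ancestry_fractions(assignments, ped, ids)
    ci = {
        o: bootstrap_ci(assignments, ped, ids, o, MATERNAL, reps=reps, seed=seed)
        for o in maternal
    }
    bias = (
        gender_bias_index(maternal, paternal, bias_origin)
        if paternal is not None
        else None
    )
    return AdmixtureEstimate(
        subset="leaves" if subset is None else f"{len(ids)} ids",
        maternal_fraction_by_origin=maternal,
        paternal_fraction_by_origin=paternal,
        ci=ci,
        matriline_survivors=lineage_survival(assignments, ped, ids, MATERNAL),
        patriline_survivors=lineage_survival(assignments, ped, ids, PATERNAL),
        bias_index=bias,
    )
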