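"""Assign variant profiles to their best-matching haplogroup.

The score is a Kulczynski-style symmetric mean. With E the cumulative variant
set of a candidate node, O the observed profile (both after masking) and
M their match set,

    score = 1/2 * (|M| / |E| + |M| / |O|)

where a term with an empty denominator is defined as 1, so the root (empty E)
scores 1 against an empty profile. Bare-position tokens match any allele at
that position. Ties are broken toward the deeper (more specific) node, then
lexicographically.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .reference import ReferenceTree, UnknownNodeError
from .variants import Variant

_TOP_LEVEL_RE = re.compile(r"^[A-Z]$")


@dataclass(frozen=True)
class VariantProfile:
    """One sample's observed variants on a single marker system."""

    sample_id: str
    variants: frozenset[Variant]
    marker_type: str = "mtDNA"

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")


@dataclass(frozen=True)
class HaplogroupCall:
    sample_id: str
    best_node: str
    score: float
    matched_count: int
    expected_count: int
    observed_count: int
    runners_up: tuple[tuple[str, float], ...] = field(default_factory=tuple)


def _masked(variants: Iterable[Variant], mask: frozenset[int]) -> list[Variant]:
    if not mask:
        return list(variants)
    return [v for v in variants if not (v.is_positional and v.position in mask)]


def _match_count(expected: Sequence[Variant], observed: Sequence[Variant]) -> int:
    """|E ∩ O| with wildcard-aware matching; each observed variant is consumed
    at most once so |M| <= min(|E|, |O|) holds by construction."""
    by_pos: dict = {}
    opaque: Counter[str] = Counter()
    for o in observed:
        if o.kind == "substitution":
            by_pos.setdefault(("s", o.position), []).append(o)
        elif o.kind == "deletion":
            by_pos.setdefault(("d", o.position, o.end), []).append(o)
        else:
            opaque[o.token] += 1
    matched = 0
    for e in expected:
        if e.kind == "substitution":
            candidates = by_pos.get(("s", e.position))
            if candidates:
                for i, o in enumerate(candidates):
                    if (
                        e.derived_allele is None
                        or o.derived_allele is None
                        or e.derived_allele == o.derived_allele
                    ):
                        del candidates[i]
                        matched += 1
                        break
        elif e.kind == "deletion":
            candidates = by_pos.get(("d", e.position, e.end))
            if candidates:
                candidates.pop()
                matched += 1
        elif opaque[e.token] > 0:
            opaque[e.token] -= 1
            matched += 1
    return matched


def score_profile_against_node(
    profile: VariantProfile,
    tree: ReferenceTree,
    node: str,
    mask: frozenset[int] = frozenset(),
) -> tuple[float, int, int, int]:
    """Score one candidate node; returns (score, |M|, |E|, |O|)."""
    expected = _masked(tree.cumulative_variants(node), mask)
    observed = _masked(profile.variants, mask)
    m = _match_count(expected, observed)
    term_e = m / len(expected) if expected else 1.0
    term_o = m / len(observed) if observed else 1.0
    return 0.5 * (term_e + term_o), m, len(expected), len(observed)


def call_haplogroup(
    profile: VariantProfile,
    tree: ReferenceTree,
    mask: frozenset[int] = frozenset(),
    n_runners_up: int = 5,
) -> HaplogroupCall:
    """Best-scoring node over the whole tree, with ranked runners-up."""
    if len(tree) == 0:
        raise ValueError("empty reference tree")
    scored = []
    for name in tree.nodes:
        score, m, e, o = score_profile_against_node(profile, tree, name, mask)
        # sort key: higher score, then deeper, then earlier name
        scored.append((-score, -tree.depth(name), name, score, m, e, o))
    scored.sort()
    _, _, best, score, m, e, o = scored[0]
    runners = tuple((row[2], row[3]) for row in scored[1 : 1 + n_runners_up])
    return HaplogroupCall(profile.sample_id, best, score, m, e, o, runners)


def call_haplogroups(
    profiles: Iterable[VariantProfile],
    tree: ReferenceTree,
    mask: frozenset[int] = frozenset(),
) -> list[HaplogroupCall]:
    return [call_haplogroup(p, tree, mask) for p in profiles]


def top_level_clade(tree: ReferenceTree, node: str) -> str:
    """Major-clade label for binning: the last single-letter haplogroup on the
    root path (e.g. H1 -> H, B4a1a1m -> B, E1b1a1 -> E), else the first node
    below the root."""
    path = tree.path(node)
    for name in reversed(path):
        if _TOP_LEVEL_RE.match(name):
            return name
    return path[1] if len(path) > 1 else path[0]


def collapse_haplogroup_frequencies(
    calls: Sequence[HaplogroupCall], ancestor: str, tree: ReferenceTree
) -> dict[str, float]:
    """Haplogroup frequency table collapsed around one clade of interest.

    Calls at or below ``ancestor`` are pooled into the bin ``"<ancestor>[x]"``;
    every other call is binned by its major clade. Frequencies sum to 1.
    """
    if ancestor not in tree:
        raise UnknownNodeError(ancestor)
    if not calls:
        raise ValueError("empty call list")
    counts: Counter[str] = Counter()
    for call in calls:
        if tree.is_descendant(call.best_node, ancestor):
            counts[f"{ancestor}[x]"] += 1
        else:
            counts[top_level_clade(tree, call.best_node)] += 1
    total = len(calls)
    return {bin_: n / total for bin_, n in sorted(counts.items())}
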