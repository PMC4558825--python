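"""Sample-level phylogenies from variant profiles.

Distances are Hamming-style set distances (size of the symmetric difference
of two samples' variant sets); trees are built by neighbor joining. This
mirrors the figure-style sample trees; reference-tree induced subtrees (see
:func:`uniline.reference.induced_subtree_newick`) are the other, annotation-
carrying route.
"""

from __future__ import annotations

import warnings
from typing import Sequence

from skbio import DistanceMatrix
from skbio.tree import nj

from .caller import VariantProfile


class NegativeBranchWarning(UserWarning):
    pass


def hamming_distance_matrix(
    profiles: Sequence[VariantProfile], mask: frozenset[int] = frozenset()
) -> DistanceMatrix:
    """d(x, y) = |masked variant set of x  Δ  masked variant set of y|."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    marker_types = {p.marker_type for p in profiles}
    if len(marker_types) > 1:
        raise ValueError(f"mixed marker types: {sorted(marker_types)}")
    sets = []
    for p in profiles:
        if mask:
            sets.append({v for v in p.variants if not (v.is_positional and v.position in mask)})
        else:
            sets.append(set(p.variants))
    n = len(profiles)
    data = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = float(len(sets[i] ^ sets[j]))
            data[i][j] = data[j][i] = d
    return DistanceMatrix(data, ids=[p.sample_id for p in profiles])


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Unrooted NJ tree as a Newick string; negative branch lengths are
    clamped to zero (with a warning), which keeps the output valid for strict
    parsers at the cost of slight non-additivity."""
    if dm.shape[0] < 2:
        raise ValueError("need at least 2 taxa")
    if dm.shape[0] == 2:
        a, b = dm.ids
        return f"({a}:{dm[a, b]},{b}:0.0);"
    tree = nj(dm)
    clamped = 0
    for node in tree.traverse(include_self=True):
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(
            f"clamped {clamped} negative branch length(s) to 0",
            NegativeBranchWarning,
            stacklevel=2,
        )
    return str(tree).strip()


def profiles_to_newick(
    profiles: Sequence[VariantProfile], mask: frozenset[int] = frozenset()
) -> str:
    """Convenience: Hamming distances then neighbor joining."""
    return neighbor_joining(hamming_distance_matrix(profiles, mask))
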