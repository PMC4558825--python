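"""Independent oracles and random-instance generators shared by the tests.

Everything here is deliberately written from first principles (plain path
walks, exhaustive enumeration, naive set arithmetic) so it stays independent
of the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np

from uniline.caller import VariantProfile
from uniline.pedigree import FEMALE, MALE, Individual, Pedigree
from uniline.reference import HaplogroupNode, ReferenceTree
from uniline.variants import parse_variant

BASES = "ACGT"


# -- random reference trees --------------------------------------------------


def random_tree(rng: np.random.Generator, max_nodes: int = 50) -> ReferenceTree:
    """Random rooted haplogroup tree; every non-root node gets 1-3 variants
    at globally fresh positions, so cumulative sets are pairwise distinct."""
    n = int(rng.integers(2, max_nodes + 1))
    pool = rng.permutation(np.arange(1, 16570))
    next_pos = iter(pool.tolist())
    nodes = {"N0": HaplogroupNode("N0", None)}
    for i in range(1, n):
        parent = f"N{int(rng.integers(i))}"
        tokens = []
        for _ in range(int(rng.integers(1, 4))):
            pos = next(next_pos)
            if rng.random() < 0.5:
                tokens.append(str(pos))
            else:
                anc, der = rng.choice(list(BASES), size=2, replace=False)
                tokens.append(f"{anc}{pos}{der}")
        nodes[f"N{i}"] = HaplogroupNode(
            f"N{i}", parent, tuple(parse_variant(t) for t in tokens)
        )
    return ReferenceTree(nodes)


# -- independent haplogroup scorer ------------------------------------------


def oracle_cumulative(tree: ReferenceTree, node: str) -> set:
    """Hand-walked root-to-node variant union with back-mutation removal."""
    path = []
    cur = node
    while cur is not None:
        path.append(cur)
        cur = tree.nodes[cur].parent
    acc = {}
    for name in reversed(path):
        for v in tree.nodes[name].defining_variants:
            key = (
                (v.kind, v.position, v.end)
                if v.position is not None and v.kind in ("substitution", "deletion")
                else ("token", v.token.rstrip("!"))
            )
            if v.back_mutation:
                acc.pop(key, None)
            else:
                acc[key] = v
    return set(acc.values())


def oracle_score(tree: ReferenceTree, node: str, observed: set) -> tuple[float, int, int, int]:
    """Naive Kulczynski-style score over token sets (wildcard-aware)."""
    expected = oracle_cumulative(tree, node)
    remaining = list(observed)
    m = 0
    for e in expected:
        hit = None
        for i, o in enumerate(remaining):
            if e.kind == "substitution" and o.kind == "substitution":
                if e.position == o.position and (
                    e.derived_allele is None
                    or o.derived_allele is None
                    or e.derived_allele == o.derived_allele
                ):
                    hit = i
                    break
            elif e.kind == "deletion" and o.kind == "deletion":
                if (e.position, e.end) == (o.position, o.end):
                    hit = i
                    break
            elif e.token == o.token:
                hit = i
                break
        if hit is not None:
            remaining.pop(hit)
            m += 1
    te = m / len(expected) if expected else 1.0
    to = m / len(observed) if observed else 1.0
    return 0.5 * (te + to), m, len(expected), len(observed)


def oracle_depth(tree: ReferenceTree, node: str) -> int:
    depth = 0
    cur = tree.nodes[node].parent
    while cur is not None:
        depth += 1
        cur = tree.nodes[cur].parent
    return depth


def oracle_best_node(tree: ReferenceTree, observed: set) -> str:
    """Exhaustive argmax with the declared tie-break (score, depth, name)."""
    best = None
    for name in tree.nodes:
        score, *_ = oracle_score(tree, name, observed)
        key = (-score, -oracle_depth(tree, name), name)
        if best is None or key < best[0]:
            best = (key, name)
    return best[1]


def noisy_profile(
    rng: np.random.Generator, tree: ReferenceTree, sample_id: str = "s"
) -> VariantProfile:
    """Cumulative set of a random node with some variants dropped and some
    random extras added."""
    node = list(tree.nodes)[int(rng.integers(len(tree.nodes)))]
    variants = set(tree.cumulative_variants(node))
    variants = {v for v in variants if rng.random() > 0.2}
    for _ in range(int(rng.integers(0, 3))):
        variants.add(parse_variant(str(int(rng.integers(1, 16570)))))
    return VariantProfile(sample_id, frozenset(variants))


# -- random pedigrees --------------------------------------------------------


def random_pedigree(rng: np.random.Generator, max_members: int = 2000) -> Pedigree:
    """Random acyclic genealogy with partial parentage (single recorded
    parents allowed), built generation by generation."""
    individuals: list[Individual] = []
    counter = 0

    def add(sex, father, mother, origin="unknown"):
        nonlocal counter
        counter += 1
        ind = Individual(f"R{counter:05d}", father, mother, sex, origin)
        individuals.append(ind)
        return ind

    n_founders = int(rng.integers(4, 12))
    current = [
        add(MALE if rng.random() < 0.5 else FEMALE, None, None,
            ["european", "polynesian", "other"][int(rng.integers(3))])
        for _ in range(n_founders)
    ]
    for _ in range(int(rng.integers(1, 8))):
        males = [i for i in current if i.sex == MALE]
        females = [i for i in current if i.sex == FEMALE]
        nxt = []
        for _ in range(int(rng.integers(1, max(2, len(current))))):
            if len(individuals) >= max_members:
                break
            father = males[int(rng.integers(len(males)))].id if males and rng.random() < 0.85 else None
            mother = females[int(rng.integers(len(females)))].id if females and rng.random() < 0.85 else None
            nxt.append(add(MALE if rng.random() < 0.5 else FEMALE, father, mother))
        if not nxt:
            break
        current = nxt
    return Pedigree(individuals)


def oracle_line_founder(ped: Pedigree, id_: str, line: str) -> str | None:
    """Plain iterative path walk up one parental line."""
    if line == "paternal" and ped[id_].sex != MALE:
        return None
    cur = id_
    while True:
        parent = ped[cur].mother_id if line == "maternal" else ped[cur].father_id
        if parent is None:
            return cur
        cur = parent


# -- additive trees for NJ ---------------------------------------------------


def random_additive_instance(rng: np.random.Generator, n_taxa: int):
    """A random unrooted binary tree with strictly positive branch lengths
    and its exact additive (path-length) distance matrix.

    Returns (newick, labels, matrix); inner-edge lengths are kept large
    enough that NJ must recover the topology.
    """
    import dendropy

    labels = [f"t{i}" for i in range(n_taxa)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in labels:
        leaf = dendropy.Node(taxon=taxa.get_taxon(label))
        leaf.edge.length = float(rng.uniform(0.5, 3.0))
        nodes.append(leaf)
    rng_order = list(nodes)
    while len(rng_order) > 2:
        i, j = sorted(rng.choice(len(rng_order), size=2, replace=False).tolist())
        a, b = rng_order[i], rng_order[j]
        joined = dendropy.Node()
        joined.add_child(a)
        joined.add_child(b)
        joined.edge.length = float(rng.uniform(0.5, 3.0))
        rng_order = [n for k, n in enumerate(rng_order) if k not in (i, j)]
        rng_order.append(joined)
    root = dendropy.Node()
    for n in rng_order:
        root.add_child(n)
    tree.seed_node = root
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    matrix = [
        [
            0.0 if i == j else pdm.distance(taxa.get_taxon(labels[i]), taxa.get_taxon(labels[j]))
            for j in range(n_taxa)
        ]
        for i in range(n_taxa)
    ]
    return tree.as_string(schema="newick"), labels, matrix


def rf_distance(newick_a: str, newick_b: str) -> int:
    """Unrooted Robinson-Foulds distance between two newick strings."""
    import dendropy

    taxa = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=taxa)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=taxa)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)
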