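"""Pedigree I/O, validation, and uniparental lineage propagation.

mtDNA passes from mother to every child; the Y chromosome from father to son.
Tracing those links through a genealogy assigns every individual a matriline
founder (and males a patriline founder), and propagating founder haplotypes
down the same links predicts every member's uniparental genotypes — the
pedigree-side counterpart to direct sequencing.

The file dialect is PED-like: six whitespace-delimited columns
``family_id  id  father_id  mother_id  sex  origin`` with ``0`` meaning a
missing parent or unknown origin; sex is 1 (male) / 2 (female); the origin
label (european / polynesian / other / unknown) occupies the phenotype slot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

MALE = "male"
FEMALE = "female"
ORIGINS = ("european", "polynesian", "other", "unknown")

MATERNAL = "maternal"
PATERNAL = "paternal"

_SEX_CODE = {MALE: "1", FEMALE: "2"}
_SEX_FROM_CODE = {"1": MALE, "2": FEMALE}


class PedigreeError(ValueError):
    """Base class for pedigree validation errors."""


class UnresolvedReferenceError(PedigreeError):
    pass


class SexInconsistencyError(PedigreeError):
    pass


class PedigreeCycleError(PedigreeError):
    pass


@dataclass(frozen=True)
class Individual:
    id: str
    father_id: str | None
    mother_id: str | None
    sex: str
    origin: str = "unknown"
    generation: int | None = None
    family_id: str = "FAM"

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass(frozen=True)
class LineageAssignment:
    """Per-individual uniparental lineage record."""

    id: str
    matriline_founder: str
    patriline_founder: str | None
    mt_haplotype: str | None
    y_haplotype: str | None


class Pedigree:
    """A validated genealogy: parent references resolve, parents have the
    right sex, and the parent-child graph is acyclic."""

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self.individuals[ind.id] = ind
        graph = nx.DiGraph()
        graph.add_nodes_from(self.individuals)
        for ind in self.individuals.values():
            for parent_id, want_sex, label in (
                (ind.father_id, MALE, "father"),
                (ind.mother_id, FEMALE, "mother"),
            ):
                if parent_id is None:
                    continue
                parent = self.individuals.get(parent_id)
                if parent is None:
                    raise UnresolvedReferenceError(
                        f"{ind.id}: {label} {parent_id!r} not in pedigree"
                    )
                if parent.sex != want_sex:
                    raise SexInconsistencyError(
                        f"{ind.id}: {label} {parent_id!r} has sex {parent.sex}"
                    )
                graph.add_edge(parent_id, ind.id)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise PedigreeCycleError(f"parent-child cycle: {cycle}")
        self._graph = graph

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, id_: str) -> bool:
        return id_ in self.individuals

    def __getitem__(self, id_: str) -> Individual:
        return self.individuals[id_]

    def founders(self) -> list[Individual]:
        return [i for i in self.individuals.values() if i.is_founder]

    def children_of(self, id_: str) -> list[str]:
        return sorted(self._graph.successors(id_))

    def leaves(self) -> list[str]:
        """Individuals with no recorded children — the default stand-in for
        the present-day cohort."""
        return sorted(
            i for i in self.individuals if self._graph.out_degree(i) == 0
        )

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self._graph))


# -- I/O ---------------------------------------------------------------------


def read_pedigree(path: str | Path) -> Pedigree:
    individuals = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise PedigreeError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            fam, id_, father, mother, sex_code, origin = parts
            if sex_code not in _SEX_FROM_CODE:
                raise PedigreeError(f"{path}:{lineno}: sex must be 1 or 2, got {sex_code!r}")
            origin = "unknown" if origin == "0" else origin
            if origin not in ORIGINS:
                raise PedigreeError(f"{path}:{lineno}: unknown origin {origin!r}")
            individuals.append(
                Individual(
                    id=id_,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=_SEX_FROM_CODE[sex_code],
                    origin=origin,
                    family_id=fam,
                )
            )
    return Pedigree(individuals)


def write_pedigree(ped: Pedigree, path: str | Path, header: Sequence[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for line in header:
            handle.write(f"# {line}\n")
        for ind in ped.individuals.values():
            handle.write(
                "\t".join(
                    (
                        ind.family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_CODE[ind.sex],
                        ind.origin if ind.origin != "unknown" else "0",
                    )
                )
                + "\n"
            )


# -- lineage tracing ---------------------------------------------------------


def uniparental_founder(ped: Pedigree, id_: str, line: str) -> str | None:
    """Follow mother links (maternal) or father links (paternal) to the first
    individual missing that parent; may be the query itself.

    The paternal line of a female is undefined and returns ``None``.
    """
    if id_ not in ped:
        raise KeyError(id_)
    if line == MATERNAL:
        parent_of = lambda i: ped[i].mother_id  # noqa: E731
    elif line == PATERNAL:
        if ped[id_].sex != MALE:
            return None
        parent_of = lambda i: ped[i].father_id  # noqa: E731
    else:
        raise ValueError(f"line must be {MATERNAL!r} or {PATERNAL!r}")
    cur = id_
    while (nxt := parent_of(cur)) is not None:
        cur = nxt
    return cur


def propagate_lineages(
    ped: Pedigree, founder_haplotypes: Mapping[str, tuple[str | None, str | None]]
) -> dict[str, LineageAssignment]:
    """Propagate founder mtDNA/Y haplogroups to every individual.

    ``founder_haplotypes`` maps a lineage-terminal individual (no mother for
    the mt line, no father for the Y line) to an ``(mt, y)`` pair. Every
    true founder must carry an mt haplotype and every male founder a Y
    haplotype; an individual whose single missing parent truncates one line
    inherits ``None`` on that line unless the map covers them.
    """
    for founder in ped.founders():
        mt, y = founder_haplotypes.get(founder.id, (None, None))
        if mt is None:
            raise PedigreeError(f"founder {founder.id} has no mt haplotype")
        if founder.sex == MALE and y is None:
            raise PedigreeError(f"male founder {founder.id} has no Y haplotype")

    mt_of: dict[str, str | None] = {}
    y_of: dict[str, str | None] = {}
    matri: dict[str, str] = {}
    patri: dict[str, str | None] = {}
    for id_ in ped.topological_order():
        ind = ped[id_]
        if ind.mother_id is None:
            mt_of[id_] = founder_haplotypes.get(id_, (None, None))[0]
            matri[id_] = id_
        else:
            mt_of[id_] = mt_of[ind.mother_id]
            matri[id_] = matri[ind.mother_id]
        if ind.sex != MALE:
            y_of[id_] = None
            patri[id_] = None
        elif ind.father_id is None:
            y_of[id_] = founder_haplotypes.get(id_, (None, None))[1]
            patri[id_] = id_
        else:
            y_of[id_] = y_of[ind.father_id]
            patri[id_] = patri[ind.father_id]
    return {
        id_: LineageAssignment(id_, matri[id_], patri[id_], mt_of[id_], y_of[id_])
        for id_ in sorted(ped.individuals)
    }


def lineage_concordance(
    assignments: Mapping[str, LineageAssignment],
    calls: Mapping[str, str],
    tree,
    level: int | None = None,
) -> tuple[float, list[tuple[str, str, str]]]:
    """Fraction of shared samples whose observed haplogroup call matches the
    pedigree-propagated haplotype, after collapsing both to ``level`` steps
    below the root (``None`` = exact). Mismatches are returned as
    ``(sample, propagated, observed)`` — candidate pedigree errors or new
    founders.
    """
    shared = sorted(set(assignments) & set(calls))
    if not shared:
        raise ValueError("no overlapping sample ids")

    def collapse(name: str) -> str:
        if level is None:
            return name
        path = tree.path(name)
        return path[min(level, len(path) - 1)]

    mismatches = []
    hits = 0
    for id_ in shared:
        expected = assignments[id_].mt_haplotype
        observed = calls[id_]
        if expected is not None and collapse(expected) == collapse(observed):
            hits += 1
        else:
            mismatches.append((id_, str(expected), observed))
    return hits / len(shared), mismatches
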