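"""Haplogroup reference trees (mtDNA Phylotree-style; Y skeleton tree).

The on-disk format is a 3-column TSV — ``node``, ``parent``, comma-separated
defining-variant tokens — with ``#`` comment lines. The root row has an empty
parent field. This mirrors the content of Phylotree / minimal-skeleton Y
tables in a trivially diffable form.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .variants import Variant, parse_variant_list, resolve_back_mutations

MTDNA = "mtDNA"
YCHROM = "Y"

_NEWICK_UNSAFE = set(" ()[]':;,\t\n")


class TreeError(ValueError):
    """Base class for reference-tree validation errors."""


class DuplicateNodeError(TreeError):
    pass


class UnknownParentError(TreeError):
    pass


class TreeCycleError(TreeError):
    pass


class RootError(TreeError):
    pass


class UnknownNodeError(KeyError):
    pass


@dataclass(frozen=True)
class HaplogroupNode:
    """One haplogroup: its label, parent label (None at the root) and the
    variants that define the branch leading to it."""

    name: str
    parent: str | None
    defining_variants: tuple[Variant, ...] = ()


@dataclass
class ReferenceTree:
    """A rooted haplogroup phylogeny with per-branch defining variants."""

    nodes: dict[str, HaplogroupNode]
    marker_type: str = MTDNA
    root: str = field(init=False)
    _children: dict[str, list[str]] = field(init=False, repr=False)
    _cumulative: dict[str, frozenset[Variant]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        roots = [n.name for n in self.nodes.values() if n.parent is None]
        if len(roots) == 0:
            raise RootError("tree has no root (every node has a parent)")
        if len(roots) > 1:
            raise RootError(f"tree has multiple roots: {', '.join(sorted(roots))}")
        self.root = roots[0]
        self._children = {name: [] for name in self.nodes}
        for node in self.nodes.values():
            if node.parent is not None:
                if node.parent not in self.nodes:
                    raise UnknownParentError(
                        f"node {node.name!r} references unknown parent {node.parent!r}"
                    )
                self._children[node.parent].append(node.name)
        for kids in self._children.values():
            kids.sort()
        # reachability from the root doubles as the cycle check: a parent
        # pointer cycle is exactly a component the root cannot reach
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            cur = stack.pop()
            seen.add(cur)
            stack.extend(self._children[cur])
        if len(seen) != len(self.nodes):
            stray = sorted(set(self.nodes) - seen)
            raise TreeCycleError(
                f"cycle or disconnected component involving: {', '.join(stray)}"
            )
        self._cumulative = {}
        self._depth = {self.root: 0}
        stack = [self.root]
        while stack:
            cur = stack.pop()
            for child in self._children[cur]:
                self._depth[child] = self._depth[cur] + 1
                stack.append(child)

    # -- queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def children(self, name: str) -> list[str]:
        self._require(name)
        return list(self._children[name])

    def path(self, name: str) -> list[str]:
        """Root-to-node list of names (inclusive)."""
        self._require(name)
        out = []
        cur: str | None = name
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        out.reverse()
        return out

    def depth(self, name: str) -> int:
        self._require(name)
        return self._depth[name]

    def is_descendant(self, name: str, ancestor: str) -> bool:
        """True when ``name`` is ``ancestor`` or lies below it."""
        self._require(ancestor)
        return ancestor in self.path(name)

    def tips(self) -> list[str]:
        return sorted(n for n in self.nodes if not self._children[n])

    def cumulative_variants(self, name: str) -> frozenset[Variant]:
        """Union of defining variants along the root-to-node path, with back
        mutations cancelling the earlier variant at their position."""
        self._require(name)
        if name not in self._cumulative:
            stream: list[Variant] = []
            for step in self.path(name):
                stream.extend(self.nodes[step].defining_variants)
            self._cumulative[name] = resolve_back_mutations(stream)
        return self._cumulative[name]

    def _require(self, name: str) -> None:
        if name not in self.nodes:
            raise UnknownNodeError(name)


def cumulative_variants(tree: ReferenceTree, node: str) -> frozenset[Variant]:
    """Functional alias for :meth:`ReferenceTree.cumulative_variants`."""
    return tree.cumulative_variants(node)


# -- parsing / serialisation ------------------------------------------------


def parse_reference_tree(path: str | Path, marker_type: str = MTDNA) -> ReferenceTree:
    """Read a tree TSV. Each data row: node, parent, variant tokens."""
    nodes: dict[str, HaplogroupNode] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            name = parts[0].strip()
            parent = parts[1].strip() or None if len(parts) > 1 else None
            tokens = parts[2] if len(parts) > 2 else ""
            if not name:
                raise TreeError(f"{path}:{lineno}: empty node name")
            if name in nodes:
                raise DuplicateNodeError(f"{path}:{lineno}: duplicate node {name!r}")
            nodes[name] = HaplogroupNode(name, parent, parse_variant_list(tokens))
    if not nodes:
        raise TreeError(f"{path}: no data rows")
    return ReferenceTree(nodes, marker_type=marker_type)


def write_reference_tree(tree: ReferenceTree, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# node\tparent\tvariants\n")
        for name in _preorder(tree):
            node = tree.nodes[name]
            tokens = ",".join(v.render() for v in node.defining_variants)
            handle.write(f"{name}\t{node.parent or ''}\t{tokens}\n")


def _preorder(tree: ReferenceTree) -> Iterable[str]:
    stack = [tree.root]
    while stack:
        cur = stack.pop()
        yield cur
        stack.extend(reversed(tree.children(cur)))


# -- induced subtrees --------------------------------------------------------


def induced_subtree_newick(
    tree: ReferenceTree, names: Iterable[str], annotate: bool = False
) -> str:
    """Newick of the minimal subtree spanning ``names`` and the root.

    Internal nodes are retained only when they branch within the induced
    subtree or are themselves requested. With ``annotate``, each label carries
    a square-bracket comment listing the defining variants accumulated along
    the (possibly collapsed) branch leading to it.
    """
    wanted = set(names)
    if not wanted:
        raise ValueError("empty name set")
    for name in wanted:
        if name not in tree:
            raise UnknownNodeError(name)

    keep: set[str] = set()
    for name in wanted:
        keep.update(tree.path(name))
    children = {n: [c for c in tree.children(n) if c in keep] for n in keep}

    def build(name: str, carried: list[Variant]) -> str:
        tokens = carried + list(tree.nodes[name].defining_variants)
        kids = children[name]
        # collapse unary internal nodes that were not explicitly requested
        while len(kids) == 1 and name not in wanted:
            name = kids[0]
            tokens.extend(tree.nodes[name].defining_variants)
            kids = children[name]
        label = _newick_label(name)
        if annotate and tokens:
            label += "[" + ",".join(v.render() for v in tokens) + "]"
        if not kids:
            return label
        inner = ",".join(build(k, []) for k in kids)
        return f"({inner}){label}"

    return build(tree.root, []) + ";"


def _newick_label(name: str) -> str:
    if any(ch in _NEWICK_UNSAFE for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


# -- bundled fixtures --------------------------------------------------------


def load_bundled_tree(which: str) -> ReferenceTree:
    """Load the bundled toy reference tree: ``"mt"`` or ``"y"``."""
    fname = {"mt": "mt_tree.tsv", "y": "y_tree.tsv"}.get(which)
    if fname is None:
        raise ValueError(f"unknown bundled tree {which!r} (use 'mt' or 'y')")
    marker = MTDNA if which == "mt" else YCHROM
    ref = importlib.resources.files("uniline.data").joinpath(fname)
    with importlib.resources.as_file(ref) as path:
        return parse_reference_tree(path, marker_type=marker)
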