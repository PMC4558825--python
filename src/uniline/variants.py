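"""Variant token grammar shared by the mtDNA and Y reference trees.

Tokens follow the conventions used in the human mtDNA haplogroup literature
(Phylotree-style), plus named Y-SNP markers:

* ``A1692G``       substitution with explicit ancestral and derived alleles
* ``1692``         bare position — a substitution whose allele is unspecified
                   (wildcard; matches any allele observed at that position)
* ``8281-8289d``   range deletion (1-based, inclusive); ``8281d`` deletes one base
* ``8289.1C``      insertion after a position (string-matched)
* ``P293``         named marker (e.g. a Y-SNP label); string-matched
* a trailing ``!`` marks a back mutation: in a cumulative (root-to-node)
  variant set it *removes* the earlier variant at the same position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

SUBSTITUTION = "substitution"
DELETION = "deletion"
INSERTION = "insertion"
OPAQUE = "opaque"

_SUB_FULL = re.compile(r"^([ACGTacgt])(\d+)([ACGTacgt])$")
_SUB_BARE = re.compile(r"^(\d+)$")
_DEL_RANGE = re.compile(r"^(\d+)-(\d+)d$")
_DEL_ONE = re.compile(r"^(\d+)d$")
_INS = re.compile(r"^(\d+)\.(\d+)([ACGTacgt]+)$")


class VariantTokenError(ValueError):
    """Raised for an empty or malformed variant token."""


@dataclass(frozen=True, order=True)
class Variant:
    """A single variant token.

    ``position`` is the 1-based reference coordinate (``None`` for opaque
    tokens). ``derived_allele`` is ``None`` for wildcard (bare-position)
    substitutions. ``end`` is set for range deletions. ``token`` is the
    canonical rendering; parsing then rendering is the identity.
    """

    token: str
    kind: str
    position: int | None
    derived_allele: str | None
    ancestral_allele: str | None
    end: int | None
    back_mutation: bool

    def render(self) -> str:
        return self.token

    @property
    def is_positional(self) -> bool:
        return self.position is not None and self.kind in (SUBSTITUTION, DELETION)

    def matches(self, other: "Variant") -> bool:
        """Whether an expected variant is satisfied by an observed one.

        Positional substitutions match on position, with a wildcard allele on
        either side matching any allele; deletions match on the exact range;
        insertions and opaque tokens match on the exact token string.
        """
        if self.kind == SUBSTITUTION and other.kind == SUBSTITUTION:
            if self.position != other.position:
                return False
            if self.derived_allele is None or other.derived_allele is None:
                return True
            return self.derived_allele == other.derived_allele
        if self.kind == DELETION and other.kind == DELETION:
            return (self.position, self.end) == (other.position, other.end)
        return self.token == other.token


def parse_variant(token: str) -> Variant:
    """Parse one variant token. Raises :class:`VariantTokenError` if empty."""
    raw = token.strip()
    if not raw:
        raise VariantTokenError("empty variant token")
    back = raw.endswith("!")
    body = raw[:-1] if back else raw
    if not body:
        raise VariantTokenError(f"bare back-mutation marker: {token!r}")

    m = _SUB_FULL.match(body)
    if m:
        anc, pos, der = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
        _check_pos(pos, raw)
        return Variant(raw, SUBSTITUTION, pos, der, anc, None, back)
    m = _SUB_BARE.match(body)
    if m:
        pos = int(m.group(1))
        _check_pos(pos, raw)
        return Variant(raw, SUBSTITUTION, pos, None, None, None, back)
    m = _DEL_RANGE.match(body)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        _check_pos(start, raw)
        if end < start:
            raise VariantTokenError(f"inverted deletion range: {token!r}")
        return Variant(raw, DELETION, start, None, None, end, back)
    m = _DEL_ONE.match(body)
    if m:
        pos = int(m.group(1))
        _check_pos(pos, raw)
        return Variant(raw, DELETION, pos, None, None, pos, back)
    m = _INS.match(body)
    if m:
        pos = int(m.group(1))
        _check_pos(pos, raw)
        return Variant(raw, INSERTION, pos, m.group(3).upper(), None, None, back)
    # anything else (named Y-SNP markers etc.) is an opaque string-matched token
    return Variant(raw, OPAQUE, None, None, None, None, back)


def _check_pos(pos: int, token: str) -> None:
    if pos < 1:
        raise VariantTokenError(f"position must be >= 1 in {token!r}")


def parse_variant_list(text: str) -> tuple[Variant, ...]:
    """Parse a comma-separated token list; blanks between commas are skipped."""
    out = []
    for tok in text.split(","):
        tok = tok.strip()
        if tok:
            out.append(parse_variant(tok))
    return tuple(out)


def position_key(v: Variant):
    """Key under which a back mutation cancels an earlier variant."""
    if v.is_positional:
        return (v.kind, v.position, v.end)
    return ("token", v.token.rstrip("!"))


def resolve_back_mutations(variants: Iterable[Variant]) -> frozenset[Variant]:
    """Fold a root-to-node token stream into a cumulative variant set.

    A back-mutation token removes the earlier variant at its position (or the
    identical opaque token) and does not itself enter the set: the lineage has
    reverted to the ancestral state.
    """
    acc: dict = {}
    for v in variants:
        key = position_key(v)
        if v.back_mutation:
            acc.pop(key, None)
        else:
            acc[key] = v
    return frozenset(acc.values())
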