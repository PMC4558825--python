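"""In-silico PCR screen for the COII/tRNA-Lys 9-bp deletion.

Loss of one copy of the CCCCCTCTA tandem repeat in the COII/tRNA-Lys
intergenic region (Phylotree notation 8281-8289d) is diagnostic of mtDNA
haplogroup B and near-fixed in Polynesian lineages. The fragment-length
screen amplifies across the repeat: 133 bp end-to-end without the deletion,
124 bp with it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

# the mtDEL primer pair targeting the COII/tRNA-Lys region
MTDEL_FORWARD = "AGGGCCCGTATTTACCCTATAG"
MTDEL_REVERSE = "ATTTAGTTGGGGCATTTCACTG"

LENGTH_NO_DELETION = 133
LENGTH_WITH_DELETION = 124

DELETION_PRESENT = "deletion_present"
DELETION_ABSENT = "deletion_absent"
UNKNOWN = "unknown"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class NoAmpliconError(ValueError):
    """Neither primer pair produces a product on the template."""


class MultipleProductsWarning(UserWarning):
    pass


@dataclass(frozen=True)
class AmpliconResult:
    """One sample's fragment-length genotype.

    ``fragment_length`` is end-to-end, both primers included;
    ``fwd_start``/``rev_end`` are 1-based inclusive template coordinates.
    """

    sample_id: str
    fragment_length: int | None
    genotype: str
    fwd_start: int | None
    rev_end: int | None


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _binding_sites(
    template: str, primer: str, max_mismatch: int, protect: str = "suffix"
) -> list[int]:
    """0-based start offsets where the pattern matches the plus strand.

    Mismatches in the primer's 3'-terminal 3 bases are disallowed (they would
    abolish extension); up to ``max_mismatch`` elsewhere. For a forward primer
    the 3' end is the pattern suffix; for a reverse-complemented reverse
    primer it is the pattern prefix (``protect="prefix"``).
    """
    plen = len(primer)
    protected = set(
        range(plen - 3, plen) if protect == "suffix" else range(0, min(3, plen))
    )
    t = np.frombuffer(template.upper().encode("ascii"), dtype=np.uint8)
    p = np.frombuffer(primer.upper().encode("ascii"), dtype=np.uint8)
    n = len(t) - plen + 1
    if n <= 0:
        return []
    mismatches = np.zeros(n, dtype=np.int32)
    blocked = np.zeros(n, dtype=bool)
    for i in range(plen):
        neq = t[i : i + n] != p[i]
        if i in protected:
            blocked |= neq
        else:
            mismatches += neq
    return np.nonzero(~blocked & (mismatches <= max_mismatch))[0].tolist()


def find_amplicon(
    template: str,
    fwd_primer: str = MTDEL_FORWARD,
    rev_primer: str = MTDEL_REVERSE,
    max_mismatch: int = 1,
    circular: bool = False,
    origin_window: int = 500,
    max_product: int = 2000,
) -> tuple[int, int, int]:
    """Locate the PCR product: (length, fwd_start, rev_end), 1-based inclusive.

    The forward primer anneals on the plus strand; the reverse primer's
    reverse complement must occur downstream. The shortest product is
    returned. ``circular`` appends the first ``origin_window`` bases so an
    origin-spanning product can be found on circular mtDNA.
    """
    if not fwd_primer or not rev_primer:
        raise ValueError("primers must be non-empty")
    if len(template) < len(fwd_primer) + len(rev_primer):
        raise ValueError("template shorter than the two primers")
    search = template + (template[:origin_window] if circular else "")

    fwd_sites = _binding_sites(search, fwd_primer, max_mismatch)
    rev_rc = reverse_complement(rev_primer)
    # 3' end of the reverse primer is the *left* end of its plus-strand match
    rev_sites = _binding_sites(search, rev_rc, max_mismatch, protect="prefix")

    products = []
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len(rev_rc)  # exclusive
            if end > f + len(fwd_primer):
                products.append((end - f, f, end))
    if not products:
        raise NoAmpliconError("no forward/reverse primer pairing on template")
    products.sort()
    short = [p for p in products if p[0] <= max_product]
    if len(short) > 1:
        warnings.warn(
            f"{len(short)} products under {max_product} bp; reporting the shortest",
            MultipleProductsWarning,
            stacklevel=2,
        )
    length, f, end = products[0]
    return length, f + 1, end  # 1-based inclusive coordinates


def classify_9bp_genotype(length: int | None) -> str:
    """Exact-length genotype call: 133 -> absent, 124 -> present, else unknown."""
    if length == LENGTH_NO_DELETION:
        return DELETION_ABSENT
    if length == LENGTH_WITH_DELETION:
        return DELETION_PRESENT
    return UNKNOWN


def assay_sample(
    sample_id: str,
    template: str,
    fwd_primer: str = MTDEL_FORWARD,
    rev_primer: str = MTDEL_REVERSE,
    max_mismatch: int = 1,
) -> AmpliconResult:
    """Run the full screen on one template sequence."""
    try:
        length, start, end = find_amplicon(template, fwd_primer, rev_primer, max_mismatch)
    except NoAmpliconError:
        return AmpliconResult(sample_id, None, UNKNOWN, None, None)
    return AmpliconResult(sample_id, length, classify_9bp_genotype(length), start, end)
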