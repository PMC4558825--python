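"""Flat-file I/O for the pipeline's tabular hand-offs.

All tabular outputs are TSV with ``#``-prefixed header comment lines
(run metadata such as the seed and config hash travels in those lines).
FASTA goes through Biopython.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .admixture import AdmixtureEstimate
from .assay import AmpliconResult
from .caller import HaplogroupCall, VariantProfile
from .pedigree import LineageAssignment
from .reference import MTDNA
from .variants import parse_variant_list


def _write_rows(
    path: str | Path, columns: Sequence[str], rows: Iterable[Sequence], header: Sequence[str] = ()
) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for line in header:
            handle.write(f"# {line}\n")
        handle.write("# " + "\t".join(columns) + "\n")
        for row in rows:
            handle.write("\t".join(str(x) for x in row) + "\n")


def _data_lines(path: str | Path) -> Iterable[list[str]]:
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield line.rstrip("\n").split("\t")


# -- variant profiles --------------------------------------------------------


def read_profiles(path: str | Path, marker_type: str = MTDNA) -> list[VariantProfile]:
    """TSV: sample_id <tab> comma-separated variant tokens."""
    profiles = []
    for parts in _data_lines(path):
        sample = parts[0]
        tokens = parts[1] if len(parts) > 1 else ""
        profiles.append(
            VariantProfile(sample, frozenset(parse_variant_list(tokens)), marker_type)
        )
    return profiles


def write_profiles(
    profiles: Sequence[VariantProfile], path: str | Path, header: Sequence[str] = ()
) -> None:
    rows = (
        (p.sample_id, ",".join(v.render() for v in sorted(p.variants)))
        for p in profiles
    )
    _write_rows(path, ("sample_id", "variants"), rows, header)


# -- haplogroup calls --------------------------------------------------------


def write_calls(
    calls: Sequence[HaplogroupCall], path: str | Path, header: Sequence[str] = ()
) -> None:
    rows = (
        (c.sample_id, c.best_node, f"{c.score:.6f}", c.matched_count, c.expected_count, c.observed_count)
        for c in calls
    )
    _write_rows(
        path,
        ("sample_id", "haplogroup", "score", "matched", "expected", "observed"),
        rows,
        header,
    )


def read_calls(path: str | Path) -> dict[str, str]:
    """sample_id -> called haplogroup (the columns downstream stages need)."""
    return {parts[0]: parts[1] for parts in _data_lines(path)}


# -- founder haplotypes / lineages -------------------------------------------


def write_founder_haplotypes(
    haplotypes: Mapping[str, tuple[str | None, str | None]],
    path: str | Path,
    header: Sequence[str] = (),
) -> None:
    rows = ((id_, mt or "-", y or "-") for id_, (mt, y) in sorted(haplotypes.items()))
    _write_rows(path, ("founder_id", "mt_haplogroup", "y_haplogroup"), rows, header)


def read_founder_haplotypes(path: str | Path) -> dict[str, tuple[str | None, str | None]]:
    out = {}
    for parts in _data_lines(path):
        id_, mt, y = parts[0], parts[1], parts[2]
        out[id_] = (None if mt == "-" else mt, None if y == "-" else y)
    return out


def write_lineages(
    assignments: Mapping[str, LineageAssignment], path: str | Path, header: Sequence[str] = ()
) -> None:
    rows = (
        (
            a.id,
            a.matriline_founder,
            a.patriline_founder or "-",
            a.mt_haplotype or "-",
            a.y_haplotype or "-",
        )
        for a in (assignments[k] for k in sorted(assignments))
    )
    _write_rows(
        path,
        ("id", "matriline_founder", "patriline_founder", "mt_haplotype", "y_haplotype"),
        rows,
        header,
    )


def read_lineages(path: str | Path) -> dict[str, LineageAssignment]:
    out = {}
    for parts in _data_lines(path):
        id_, matri, patri, mt, y = parts[:5]
        out[id_] = LineageAssignment(
            id_,
            matri,
            None if patri == "-" else patri,
            None if mt == "-" else mt,
            None if y == "-" else y,
        )
    return out


# -- assay results -----------------------------------------------------------


def write_assay_results(
    results: Sequence[AmpliconResult], path: str | Path, header: Sequence[str] = ()
) -> None:
    rows = (
        (r.sample_id, r.fragment_length if r.fragment_length is not None else "-", r.genotype)
        for r in results
    )
    _write_rows(path, ("sample_id", "fragment_length", "genotype"), rows, header)


# -- admixture estimates -----------------------------------------------------


def write_estimate_json(estimate: AdmixtureEstimate, path: str | Path, extra: Mapping = ()) -> None:
    payload = asdict(estimate)
    payload.update(dict(extra))
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")


# -- FASTA -------------------------------------------------------------------


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
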