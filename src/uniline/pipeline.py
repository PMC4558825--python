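"""End-to-end pipeline orchestration with flat-file hand-offs.

Stages run in dependency order: simulate -> assign -> propagate -> profiles
-> call -> sequences/assay -> concordance -> estimate -> tree. Every stage
reads and writes plain files so any single stage can be re-run in isolation,
and every output carries header lines recording the seed and a hash of the
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

from . import __version__
from .admixture import estimate_admixture
from .assay import assay_sample
from .caller import call_haplogroups
from .io import (
    read_calls,
    read_founder_haplotypes,
    read_lineages,
    read_profiles,
    write_assay_results,
    write_calls,
    write_estimate_json,
    write_fasta,
    write_founder_haplotypes,
    write_lineages,
    write_profiles,
)
from .pedigree import (
    FEMALE,
    lineage_concordance,
    propagate_lineages,
    read_pedigree,
    write_pedigree,
)
from .phylo import hamming_distance_matrix, neighbor_joining
from .reference import induced_subtree_newick, load_bundled_tree, parse_reference_tree
from .simulate import (
    SimulationConfig,
    assign_founder_haplotypes,
    generate_variant_profiles,
    haplotype_sequence,
    simulate_pedigree,
    synthetic_mtdna_reference,
)

log = logging.getLogger("uniline")

ALL_STAGES = (
    "simulate",
    "assign",
    "propagate",
    "profiles",
    "call",
    "assay",
    "concordance",
    "estimate",
    "tree",
)


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    outdir: Path = Path("uniline_out")
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    mt_tree_path: Path | None = None  # default: bundled toy tree
    y_tree_path: Path | None = None
    ped_path: Path | None = None  # required when 'simulate' is disabled
    founders_path: Path | None = None
    profiles_path: Path | None = None
    lineages_path: Path | None = None
    calls_path: Path | None = None
    bootstrap_reps: int = 1000
    assay_max_samples: int = 70  # females screened for the 9-bp deletion
    tree_max_samples: int = 40
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PipelineConfigError(f"unknown stage(s): {sorted(unknown)}")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Flat ``key: value`` config; simulator keys use a ``sim.`` prefix."""
    pipeline_kwargs: dict = {}
    sim_kwargs: dict = {}
    pipeline_fields = {f.name: f for f in fields(PipelineConfig)}
    sim_fields = {f.name: f for f in fields(SimulationConfig)}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise PipelineConfigError(f"{path}:{lineno}: expected 'key: value'")
            key, value = (part.strip() for part in line.split(":", 1))
            if key.startswith("sim."):
                name = key[4:]
                if name not in sim_fields:
                    raise PipelineConfigError(f"{path}:{lineno}: unknown key {key!r}")
                sim_kwargs[name] = _coerce(value, name, sim_fields[name].type)
            else:
                if key not in pipeline_fields:
                    raise PipelineConfigError(f"{path}:{lineno}: unknown key {key!r}")
                pipeline_kwargs[key] = _coerce(value, key, pipeline_fields[key].type)
    if "seed" in pipeline_kwargs and "seed" not in sim_kwargs:
        sim_kwargs["seed"] = pipeline_kwargs["seed"]
    pipeline_kwargs["sim"] = SimulationConfig(**sim_kwargs)
    return PipelineConfig(**pipeline_kwargs)


def _coerce(value: str, name: str, type_hint) -> object:
    hint = str(type_hint)
    if name == "stages":
        return tuple(s.strip() for s in value.split(",") if s.strip())
    if "Path" in hint:
        return Path(value)
    if "bool" in hint:
        return value.lower() in ("1", "true", "yes")
    if "int" in hint:
        return int(value)
    if "float" in hint:
        return float(value)
    return value


def config_hash(cfg: PipelineConfig) -> str:
    payload = dataclasses.asdict(cfg)
    payload.pop("outdir", None)  # identical analyses hash alike wherever written
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the run manifest (also written to
    ``<outdir>/manifest.json``)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    header = (f"seed: {cfg.seed}", f"config: {config_hash(cfg)}", f"uniline: {__version__}")
    manifest: dict = {
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "version": __version__,
        "stages": {},
        "outputs": {},
    }
    stages = set(cfg.stages)

    def record(stage: str, n: int, *paths: Path) -> None:
        manifest["stages"][stage] = {"records": n}
        for p in paths:
            manifest["outputs"][p.name] = str(p)
        log.info("stage %s: %d records", stage, n)

    def need(path: Path | None, key: str, stage: str) -> Path:
        if path is None:
            raise PipelineConfigError(
                f"stage {stage!r} is enabled but config key {key!r} is not set"
            )
        if not Path(path).exists():
            raise PipelineConfigError(f"stage {stage!r}: input {path} does not exist")
        return Path(path)

    mt_tree = (
        parse_reference_tree(need(cfg.mt_tree_path, "mt_tree_path", "call"))
        if cfg.mt_tree_path is not None
        else load_bundled_tree("mt")
    )
    y_tree = (
        parse_reference_tree(need(cfg.y_tree_path, "y_tree_path", "call"), marker_type="Y")
        if cfg.y_tree_path is not None
        else load_bundled_tree("y")
    )

    ped = None
    if "simulate" in stages:
        sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
        ped = simulate_pedigree(sim_cfg)
        ped_path = out / "pedigree.ped"
        write_pedigree(ped, ped_path, header=header)
        record("simulate", len(ped), ped_path)
    elif cfg.ped_path is not None:
        ped = read_pedigree(need(cfg.ped_path, "ped_path", "propagate"))
    sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)

    founders = None
    if "assign" in stages:
        if ped is None:
            raise PipelineConfigError("stage 'assign' needs a pedigree (simulate or ped_path)")
        founders = assign_founder_haplotypes(ped, mt_tree, y_tree, sim_cfg)
        founders_path = out / "founders.tsv"
        write_founder_haplotypes(founders, founders_path, header=header)
        record("assign", len(founders), founders_path)
    elif cfg.founders_path is not None:
        founders = read_founder_haplotypes(cfg.founders_path)

    assignments = None
    if "propagate" in stages:
        if ped is None or founders is None:
            raise PipelineConfigError(
                "stage 'propagate' needs a pedigree and founder haplotypes "
                "(enable simulate/assign or set ped_path/founders_path)"
            )
        assignments = propagate_lineages(ped, founders)
        lineages_path = out / "lineages.tsv"
        write_lineages(assignments, lineages_path, header=header)
        record("propagate", len(assignments), lineages_path)
    elif cfg.lineages_path is not None:
        assignments = read_lineages(cfg.lineages_path)

    profiles = None
    if "profiles" in stages:
        if assignments is None:
            raise PipelineConfigError("stage 'profiles' needs lineage assignments")
        profiles = generate_variant_profiles(
            assignments,
            mt_tree,
            dropout_rate=sim_cfg.dropout_rate,
            false_positive_rate=sim_cfg.false_positive_rate,
            seed=cfg.seed + 2,
            samples=ped.leaves() if ped is not None else None,
        )
        profiles_path = out / "profiles.tsv"
        write_profiles(profiles, profiles_path, header=header)
        record("profiles", len(profiles), profiles_path)
    elif cfg.profiles_path is not None:
        profiles = read_profiles(need(cfg.profiles_path, "profiles_path", "call"))

    calls = None
    if "call" in stages:
        if profiles is None:
            raise PipelineConfigError(
                "stage 'call' is enabled but no profiles are available "
                "(enable 'profiles' or set profiles_path)"
            )
        calls = call_haplogroups(profiles, mt_tree)
        calls_path = out / "calls.tsv"
        write_calls(calls, calls_path, header=header)
        record("call", len(calls), calls_path)
    elif cfg.calls_path is not None:
        calls = None  # re-read below as a mapping when needed

    if "assay" in stages:
        if assignments is None or ped is None:
            raise PipelineConfigError("stage 'assay' needs a pedigree and lineages")
        reference = synthetic_mtdna_reference()
        females = [i for i in ped.leaves() if ped[i].sex == FEMALE]
        screened = females[: cfg.assay_max_samples]
        sequences = {
            id_: haplotype_sequence(reference, mt_tree, assignments[id_].mt_haplotype)
            for id_ in screened
            if assignments[id_].mt_haplotype is not None
        }
        fasta_path = out / "sequences.fa"
        write_fasta(sequences, fasta_path)
        results = [assay_sample(id_, seq) for id_, seq in sequences.items()]
        assay_path = out / "assay.tsv"
        write_assay_results(results, assay_path, header=header)
        record("assay", len(results), fasta_path, assay_path)

    if "concordance" in stages:
        if assignments is None:
            raise PipelineConfigError("stage 'concordance' needs lineage assignments")
        if calls is not None:
            call_map = {c.sample_id: c.best_node for c in calls}
        elif cfg.calls_path is not None:
            call_map = read_calls(need(cfg.calls_path, "calls_path", "concordance"))
        else:
            raise PipelineConfigError("stage 'concordance' needs calls (enable 'call' or set calls_path)")
        rate, mismatches = lineage_concordance(assignments, call_map, mt_tree)
        manifest["stages"]["concordance"] = {
            "records": len(call_map),
            "rate": rate,
            "mismatches": len(mismatches),
        }

    if "estimate" in stages:
        if assignments is None or ped is None:
            raise PipelineConfigError("stage 'estimate' needs a pedigree and lineages")
        estimate = estimate_admixture(
            assignments, ped, reps=cfg.bootstrap_reps, seed=cfg.seed + 3
        )
        est_path = out / "estimate.json"
        write_estimate_json(
            estimate, est_path, extra={"seed": cfg.seed, "config_hash": config_hash(cfg)}
        )
        record("estimate", 1, est_path)

    if "tree" in stages:
        if profiles is None:
            raise PipelineConfigError("stage 'tree' needs profiles")
        subset = profiles[: cfg.tree_max_samples]
        newick = neighbor_joining(hamming_distance_matrix(subset))
        tree_path = out / "tree.nwk"
        tree_path.write_text(newick + "\n")
        outputs = [tree_path]
        if calls is not None:
            called_nodes = {c.best_node for c in calls}
            induced_path = out / "haplogroups.nwk"
            induced_path.write_text(
                induced_subtree_newick(mt_tree, called_nodes, annotate=True) + "\n"
            )
            outputs.append(induced_path)
        record("tree", len(subset), *outputs)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
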