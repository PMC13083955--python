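"""End-to-end study orchestration.

``run_study`` takes one YAML (or dict) config and produces, per topology
variant, replica trajectories, groove-occupancy profiles, excess profiles
against the excluded-volume baseline, Rg summaries and the tethered-domain
effective concentration, written as TSV/JSON (plots optional).  Replica
trajectories are cached on disk keyed by a manifest hash so an identical
re-run reuses them, and every output is traceable to the run manifest
(config snapshot, seeds, parameter-table version, software version).

Config schema (all sections optional unless noted)::

    chain: toy                      # or {fasta: ..., structure: ...}
    domains: [{name, start, end, group}]
    variants: [unbound, excluded_volume]
    simulation: {temperature, ph, ionic_strength, duration_ns,
                 equilibration_ns, friction_per_ps, timestep_fs,
                 save_interval_ps, n_replicas}
    groove: {interior: [...], exterior: [...], threshold: 1.0}   # 1-based
    probe_residues: [[start, end], ...]                          # 1-based spans
    regions: {TH1: [114, 134], TH2: [279, 291], TH3: [303, 313]}
    effective_concentration: {group_a: [s, e], group_b: [s, e],
                              contact_distance_nm: ..., shell_width_nm: 0.2}
    outputs: {plots: false}
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .cg_model import (
    ChainTopology,
    DomainAnnotation,
    SimulationConfig,
    ValidationError,
    bound_complex_variant,
    build_topology,
    excluded_volume_variant,
    load_parameter_table,
    read_fasta_sequence,
    residue_com_from_structure,
)
from .ensemble_metrics import (
    EffectiveConcentration,
    RgSummary,
    ScatteringProfile,
    effective_concentration,
    guinier_fit,
    rg_summary,
)
from .groove_analysis import (
    ExcessProfile,
    GrooveDefinition,
    OccupancyProfile,
    excess_occupancy,
    occupancy_profile,
    region_enrichment,
    write_profile_tsv,
)
from .simulator import Trajectory, run_replicas
from .synthetic_data import make_toy_multidomain_chain

log = logging.getLogger("stigroove")

# The study's three transient-helix regions (1-based inclusive); the
# deletion-construct coordinates for the third are available as a preset.
DEFAULT_TH_REGIONS = {"TH1": (114, 134), "TH2": (279, 291), "TH3": (303, 313)}
TH_REGIONS_DELETION_PRESET = {"TH1": (114, 134), "TH2": (279, 291), "TH3": (301, 314)}


@dataclass
class RunManifest:
    """Traceability record for one study run."""

    config: dict
    seeds: dict[str, list[int]]
    parameter_table_version: str
    software_version: str
    input_digests: dict[str, str]

    def write(self, path: Path) -> None:
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class StudyBundle:
    """All per-variant results of one study run."""

    trajectories: dict[str, list[Trajectory]]
    occupancy: dict[str, OccupancyProfile]
    rg: dict[str, RgSummary]
    excess: dict[str, ExcessProfile]
    enrichment: dict[str, dict[str, float]]
    ceff: dict[str, EffectiveConcentration]
    manifest: RunManifest
    out_dir: Path


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _resolve_chain(config: Mapping[str, Any]):
    chain_cfg = config.get("chain", "toy")
    if chain_cfg == "toy":
        toy = make_toy_multidomain_chain()
        return toy.sequence, toy.reference_coords, toy.domains, toy
    if not isinstance(chain_cfg, Mapping):
        raise ValidationError(f"unrecognised chain config {chain_cfg!r}")
    sequence = (chain_cfg["literal"] if "literal" in chain_cfg
                else read_fasta_sequence(chain_cfg["fasta"]))
    coords = None
    if "structure" in chain_cfg:
        struct_seq, coords = residue_com_from_structure(chain_cfg["structure"])
        if len(struct_seq) != len(sequence):
            raise ValidationError(
                f"structure has {len(struct_seq)} residues, sequence {len(sequence)}")
    domains = [DomainAnnotation(d["name"], d["start"], d["end"], d.get("group"))
               for d in config.get("domains", [])]
    return sequence, coords, domains, None


def _groove_from_config(config: Mapping[str, Any], toy) -> GrooveDefinition | None:
    if "groove" in config:
        g = config["groove"]
        return GrooveDefinition(
            interior=np.asarray(g["interior"], dtype=int) - 1,
            exterior=np.asarray(g["exterior"], dtype=int) - 1,
            axis_threshold=float(g.get("threshold", 1.0)),
        )
    if toy is not None:
        return toy.groove
    return None


def _probe_residues(config: Mapping[str, Any], toy, n: int,
                    domains: list[DomainAnnotation]) -> np.ndarray:
    if "probe_residues" in config:
        spans = config["probe_residues"]
        idx: list[int] = []
        for start, end in spans:
            idx.extend(range(start - 1, end))
        return np.array(sorted(set(idx)), dtype=int)
    # default: everything outside the folded domains (the disordered residues)
    in_domain = np.zeros(n, dtype=bool)
    for d in domains:
        in_domain[d.indices] = True
    return np.flatnonzero(~in_domain)


def _cache_key(topology: ChainTopology, sim: SimulationConfig, seeds: list[int]) -> str:
    h = hashlib.sha256()
    h.update(topology.config_hash().encode())
    h.update(repr(sorted(asdict(sim).items())).encode())
    h.update(repr(seeds).encode())
    return h.hexdigest()[:20]


def _simulate_cached(variant: str, topology: ChainTopology, sim: SimulationConfig,
                     seed_base: int, cache_dir: Path) -> list[Trajectory]:
    seeds = list(sim.seeds or range(seed_base, seed_base + sim.n_replicas))
    key = _cache_key(topology, sim, seeds)
    cache = cache_dir / f"{variant}_{key}.npz"
    if cache.exists():
        log.info("variant %s: reusing cached trajectories (%s)", variant, cache.name)
        data = np.load(cache)
        return [
            Trajectory(xyz=data[f"xyz_{r}"], dt_ps=float(data["dt_ps"]),
                       replica_id=r, config_hash=topology.config_hash(),
                       time_origin_ps=float(data["t0_ps"]))
            for r in range(int(data["n_replicas"]))
        ]
    t0 = time.perf_counter()
    trajs = run_replicas(topology, sim, seed_base)
    log.info("variant %s: %d replicas simulated in %.1f s", variant,
             len(trajs), time.perf_counter() - t0)
    cache_dir.mkdir(parents=True, exist_ok=True)
    payload = {f"xyz_{t.replica_id}": t.xyz for t in trajs}
    payload.update(n_replicas=len(trajs), dt_ps=trajs[0].dt_ps,
                   t0_ps=trajs[0].time_origin_ps)
    np.savez_compressed(cache, **payload)
    return trajs


def load_config(path: str | Path) -> dict:
    config = yaml.safe_load(Path(path).read_text())
    if not isinstance(config, dict):
        raise ValidationError("study config must be a YAML mapping")
    return config


def run_study(config: Mapping[str, Any] | str | Path, out_dir: str | Path,
              seed_base: int = 1000) -> StudyBundle:
    """Run the configured variants end to end and write the report bundle.

    Validates the config before any compute; caches trajectories per
    variant so a re-run with the same manifest is idempotent.
    """
    input_digests: dict[str, str] = {}
    if isinstance(config, (str, Path)):
        path = Path(config)
        input_digests[str(path)] = _digest(path)
        config = load_config(path)
    config = dict(config)

    sim = SimulationConfig(**config.get("simulation", {}))   # validates early
    sequence, coords, domains, toy = _resolve_chain(config)
    params = load_parameter_table(config.get("parameter_table"))
    if config.get("parameter_table"):
        input_digests[str(config["parameter_table"])] = _digest(Path(config["parameter_table"]))
    groove = _groove_from_config(config, toy)
    regions = {k: tuple(v) for k, v in config.get(
        "regions", (toy.regions if toy is not None else {})).items()}
    variants = list(config.get("variants", ["unbound", "excluded_volume"]))

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cache_dir = out_dir / "cache"

    topo_cfg = dict(config.get("topology", {}))
    if toy is not None:
        topo_cfg.setdefault("enm_cutoff", toy.enm_cutoff)
    base_topo = build_topology(
        sequence, params, reference_coords=coords, domains=domains,
        ph=sim.ph, **topo_cfg,
    )
    probe = _probe_residues(config, toy, base_topo.n_beads, domains)

    trajectories: dict[str, list[Trajectory]] = {}
    occupancy: dict[str, OccupancyProfile] = {}
    rg: dict[str, RgSummary] = {}
    failures: dict[str, str] = {}
    for variant in variants:
        if variant == "unbound":
            topo = base_topo
        elif variant == "excluded_volume":
            topo = excluded_volume_variant(base_topo)
        elif variant == "bound":
            bound_cfg = config.get("bound")
            if not bound_cfg:
                raise ValidationError(
                    "variant 'bound' needs a 'bound' config section "
                    "(structure + groups)")
            _, bound_coords = residue_com_from_structure(bound_cfg["structure"])
            topo = bound_complex_variant(
                base_topo, bound_cfg["groups"], bound_coords,
                enm_cutoff=topo_cfg.get("enm_cutoff", 0.9))
            input_digests[str(bound_cfg["structure"])] = _digest(
                Path(bound_cfg["structure"]))
        else:
            raise ValidationError(f"unknown variant {variant!r}")
        try:
            trajs = _simulate_cached(variant, topo, sim, seed_base, cache_dir)
            trajectories[variant] = trajs
            rg[variant] = rg_summary(trajs, topo.masses)
            if groove is not None:
                occupancy[variant] = occupancy_profile(trajs, groove, probe)
        except Exception as err:   # isolate the failed stage
            failures[variant] = f"{type(err).__name__}: {err}"
            log.error("variant %s failed: %s", variant, failures[variant])
            continue

    excess: dict[str, ExcessProfile] = {}
    enrichment: dict[str, dict[str, float]] = {}
    if "excluded_volume" in occupancy:
        for variant, prof in occupancy.items():
            if variant == "excluded_volume":
                continue
            excess[variant] = excess_occupancy(prof, occupancy["excluded_volume"])
            if regions:
                enrichment[variant] = region_enrichment(excess[variant], regions)

    ceff: dict[str, EffectiveConcentration] = {}
    ceff_cfg = config.get("effective_concentration")
    if ceff_cfg:
        for variant, trajs in trajectories.items():
            ceff[variant] = effective_concentration(
                trajs, base_topo.masses,
                group_a=tuple(ceff_cfg["group_a"]),
                group_b=tuple(ceff_cfg["group_b"]),
                contact_distance_nm=float(ceff_cfg["contact_distance_nm"]),
                shell_width_nm=float(ceff_cfg.get("shell_width_nm", 0.2)),
                distance=ceff_cfg.get("distance", "com"),
            )

    seeds = {v: list(sim.seeds or range(seed_base, seed_base + sim.n_replicas))
             for v in trajectories}
    manifest = RunManifest(
        config=json.loads(json.dumps(config, default=str)),
        seeds=seeds,
        parameter_table_version=params.version,
        software_version=__version__,
        input_digests=input_digests,
    )
    bundle = StudyBundle(trajectories, occupancy, rg, excess, enrichment,
                         ceff, manifest, out_dir)
    _write_bundle(bundle, failures, config.get("outputs", {}))
    return bundle


def _write_bundle(bundle: StudyBundle, failures: dict[str, str],
                  outputs: Mapping[str, Any]) -> None:
    out = bundle.out_dir
    bundle.manifest.write(out / "manifest.yaml")
    report: dict[str, Any] = {"failures": failures}
    for variant, prof in bundle.occupancy.items():
        write_profile_tsv(prof, out / f"occupancy_{variant}.tsv")
    for variant, ex in bundle.excess.items():
        write_profile_tsv(ex, out / f"excess_{variant}.tsv")
    for variant, summary in bundle.rg.items():
        summary.to_frame().to_csv(out / f"rg_{variant}.tsv", sep="\t",
                                  index=False, float_format="%.10g")
        report.setdefault("rg_A", {})[variant] = {
            "mean": round(summary.grand_mean, 6), "sem": round(summary.sem, 6)}
    for variant, enr in bundle.enrichment.items():
        report.setdefault("region_enrichment", {})[variant] = {
            k: (None if np.isnan(v) else round(float(v), 6)) for k, v in enr.items()}
    for variant, c in bundle.ceff.items():
        report.setdefault("effective_concentration_uM", {})[variant] = {
            "value": round(c.value_uM, 6), "sem": round(c.sem_uM, 6),
            "empty_shell": c.empty_shell}
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    if outputs.get("plots"):
        from .groove_analysis import plot_occupancy

        if bundle.occupancy:
            plot_occupancy(bundle.occupancy, out / "occupancy.png")


def compare_to_experiment(rg: RgSummary, saxs_profile: ScatteringProfile,
                          qrg_max: float = 1.3) -> dict[str, Any]:
    """Simulated mean Rg ± SEM against the Guinier Rg of a SAXS profile.

    Returns the two estimates, their difference (simulated − experimental, Å)
    and ratio; a Guinier failure is propagated as a flagged comparison.
    """
    report: dict[str, Any] = {
        "simulated_rg_A": rg.grand_mean,
        "simulated_rg_sem_A": rg.sem,
    }
    try:
        fit = guinier_fit(saxs_profile, qrg_max=qrg_max)
    except ValidationError as err:
        report.update(guinier_failed=True, guinier_error=str(err))
        return report
    report.update(
        guinier_failed=False,
        experimental_rg_A=fit.rg_A,
        experimental_rg_err_A=fit.rg_err_A,
        difference_A=rg.grand_mean - fit.rg_A,
        ratio=rg.grand_mean / fit.rg_A,
    )
    return report
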