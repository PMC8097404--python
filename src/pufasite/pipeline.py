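"""End-to-end site-mapping workflow: one config in, a report + files out.

The pipeline is pure composition of the library stages — load (or
synthesize) a trajectory, build contact tensors, classify high-/stable-
contact residues with subunit symmetry averaging, identify UQ and constant
binders, map occupancy/slab/RDF enrichment, cluster constant-binder poses
— with every stage also invokable standalone on the same objects.  Given a
fixed seed and config the report is byte-identical across reruns (no
wall-clock values are recorded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .binders import (
    classify_binder_residues,
    identify_constant_binders,
    identify_uq_binders,
    lipid_interaction_stats,
)
from .clustering import PoseSet, gromos_cluster, pose_rmsd_matrix
from .contacts import (
    classify_contact_residues,
    compute_contact_tensor,
    count_lipids_near_protein,
    residue_stats,
    symmetry_average,
)
from .core import AnalysisConfig, Selection
from .density import (
    fold_enrichment,
    lateral_rdf,
    occupancy_grid,
    slab_contact_profile,
    threshold_contour,
    write_opendx,
)
from .errors import ConfigError, PufasiteError
from .io import headgroup_selection, load_trajectory, protein_selection, write_bfactor_pdb
from .synthetic import SyntheticSystemSpec, simulate_lipid_trajectory

__all__ = ["RunConfig", "validate_config", "run_site_mapping"]

log = logging.getLogger("pufasite")


@dataclass
class RunConfig:
    """Configuration of one site-mapping run.

    Input is either a (topology, coordinates, annotation) file triple or
    the built-in synthetic system (``synthetic=True``, with optional
    overrides applied to :class:`SyntheticSystemSpec`).
    """

    output_dir: str = "pufasite_out"
    seed: int = 42
    synthetic: bool = True
    synthetic_overrides: dict = field(default_factory=dict)
    topology_path: str | None = None
    coordinates_path: str | None = None
    annotation: dict | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    species: list[str] = field(default_factory=lambda: ["LIN", "STE"])
    fold_change_pair: tuple[str, str] = ("LIN", "STE")
    run_contacts: bool = True
    run_binders: bool = True
    run_maps: bool = True
    run_clustering: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "analysis" in d and isinstance(d["analysis"], dict):
            d["analysis"] = AnalysisConfig(**d["analysis"])
        if "fold_change_pair" in d:
            d["fold_change_pair"] = tuple(d["fold_change_pair"])
        return cls(**d)

    def to_canonical_dict(self) -> dict:
        """Analysis-defining fields only (output location and logging excluded)."""
        d = dataclasses.asdict(self)
        d.pop("output_dir", None)
        d.pop("log_level", None)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_canonical_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Collect configuration problems; an empty list means valid."""
    problems: list[str] = []
    if not config.synthetic:
        for name in ("topology_path", "coordinates_path"):
            p = getattr(config, name)
            if name == "topology_path" and (p is None or not Path(p).exists()):
                problems.append(f"{name} missing or does not exist: {p}")
            if name == "coordinates_path" and p is not None and not Path(p).exists():
                problems.append(f"{name} does not exist: {p}")
        if config.annotation is None:
            problems.append("annotation rules required for file input")
    try:
        AnalysisConfig(**dataclasses.asdict(config.analysis))
    except PufasiteError as exc:
        problems.append(str(exc))
    if config.synthetic:
        try:
            spec = SyntheticSystemSpec(seed=config.seed, **config.synthetic_overrides)
            available = set(spec.n_lipids_per_species)
        except PufasiteError as exc:
            problems.append(str(exc))
            available = set()
    else:
        available = None  # unknown until load
    if available is not None:
        for sp in config.species:
            if sp not in available:
                problems.append(
                    f"unknown species {sp!r}; available: {sorted(available)}"
                )
    if not config.species:
        problems.append("no species configured")
    return problems


def _obtain_trajectory(config: RunConfig):
    if config.synthetic:
        spec = SyntheticSystemSpec(seed=config.seed, **config.synthetic_overrides)
        traj, truth = simulate_lipid_trajectory(spec)
        return traj, truth
    traj = load_trajectory(
        config.topology_path, config.coordinates_path, rules=config.annotation
    )
    return traj, None


def run_site_mapping(config: RunConfig) -> dict:
    """Execute the full workflow; returns the report dict (also written).

    Stage failures abort with the failing stage named; outputs already
    written are retained alongside a FAILED marker file.
    """
    problems = validate_config(config)
    if problems:
        raise ConfigError("invalid configuration", problems=problems)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.analysis
    report: dict = {
        "provenance": {
            "pufasite_version": __version__,
            "numpy_version": np.__version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
        },
        "warnings": [],
        "stages": {},
    }

    stage = "load"
    try:
        traj, truth = _obtain_trajectory(config)
        report["stages"]["load"] = {
            "n_frames": traj.n_frames,
            "n_atoms": traj.topology.n_atoms,
            "dt_ns": traj.dt,
            "species": sorted(set(traj.topology.species_table.values())),
        }
        tensors = {}
        if config.run_contacts:
            stage = "contacts"
            contacts_report = {}
            for sp in config.species:
                tensor = compute_contact_tensor(
                    traj, sp, cutoff=cfg.contact_cutoff, mode="whole_lipid"
                )
                tensors[sp] = tensor
                stats = residue_stats(tensor, quantile_convention=cfg.quantile_convention)
                stats.to_dataframe().to_csv(out / f"residue_stats_{sp}.csv", index=False)
                if traj.topology.subunit_map:
                    avg = symmetry_average(stats, traj.topology.subunit_map)
                else:
                    avg = stats
                cls = classify_contact_residues(avg)
                counts = count_lipids_near_protein(
                    traj, sp, cutoff=cfg.contact_cutoff,
                    window=min(cfg.running_average_window,
                               traj.duration if traj.dt else cfg.running_average_window),
                )
                counts.to_csv(out / f"lipid_counts_{sp}.csv", index=False)
                write_bfactor_pdb(
                    traj,
                    {k: v for k, v in zip(stats.residue_keys, stats.total_time)},
                    out / f"total_time_bfactor_{sp}.pdb",
                )
                contacts_report[sp] = {
                    "high_contact": sorted(map(list, cls.high_contact)),
                    "stable_contact": sorted(map(list, cls.stable_contact)),
                    "fences": cls.fence_values,
                    "mean_lipids_within_cutoff": float(counts["count"].mean()),
                }
            report["stages"]["contacts"] = contacts_report

        binder_sets = {}
        if config.run_binders:
            stage = "binders"
            binders_report = {}
            for sp in config.species:
                tensor = tensors.get(sp) or compute_contact_tensor(
                    traj, sp, cutoff=cfg.contact_cutoff, mode="whole_lipid"
                )
                lstats = lipid_interaction_stats(tensor)
                lstats.to_dataframe().to_csv(out / f"lipid_stats_{sp}.csv", index=False)
                uq = identify_uq_binders(lstats, q_method=cfg.quantile_convention)
                const = identify_constant_binders(lstats, tensor.duration)
                binder_sets[sp] = (uq, const)
                roles = {}
                for mol in sorted(const.constant_binders):
                    rr = classify_binder_residues(
                        traj, mol, traj.topology.residue_keys(), config=cfg
                    )
                    roles[str(mol)] = {
                        f"{k.residue_key[0]}:{k.residue_key[1]}": k.role
                        for k in rr
                        if k.role != "none"
                    }
                binders_report[sp] = {
                    "uq_binders": sorted(uq.uq_binders),
                    "uq_threshold_ns": uq.uq_threshold,
                    "constant_binders": sorted(const.constant_binders),
                    "binder_residue_roles": roles,
                }
            report["stages"]["binders"] = binders_report

        if config.run_maps:
            stage = "maps"
            maps_report = {}
            prot = protein_selection(traj)
            spA, spB = config.fold_change_pair
            profiles = {}
            for sp in config.species:
                heads = headgroup_selection(traj, sp, label=f"{sp}_heads")
                grid = occupancy_grid(traj, heads, resolution=cfg.grid_resolution)
                write_opendx(grid, out / f"occupancy_{sp}.dx", field_name=f"{sp}_occupancy")
                masks = {
                    str(t): int(threshold_contour(grid, t).sum())
                    for t in cfg.occupancy_thresholds
                }
                # slab profile around the highest-contact residues of this species
                ref = _slab_reference(report, traj, sp)
                prof = slab_contact_profile(
                    traj, heads, ref, shell_cutoff=cfg.shell_cutoff,
                    slab=cfg.slab_thickness, species=sp,
                )[0]
                profiles[sp] = prof
                box = traj.boxes[0]
                r_edges = np.arange(0.0, min(box[0], box[1]) / 2.0, 1.0)
                rdf = lateral_rdf(traj, heads, prot, r_edges)
                maps_report[sp] = {
                    "voxels_above_threshold": masks,
                    "max_occupancy": float(grid.occupancy.max()),
                    "slab_total_contacts": int(prof.counts.sum()),
                    "rdf_peak_r": float(rdf.r[int(np.argmax(rdf.g))]),
                }
            if spA in profiles and spB in profiles:
                fc = fold_enrichment(profiles[spA], profiles[spB])
                finite = fc.ratio[np.isfinite(fc.ratio)]
                maps_report["fold_change"] = {
                    "pair": [spA, spB],
                    "max_ratio": float(finite.max()) if finite.size else None,
                }
            report["stages"]["maps"] = maps_report

        if config.run_clustering:
            stage = "clustering"
            cluster_report = {}
            for sp in config.species:
                const = binder_sets.get(sp, (None, None))[1]
                mols = sorted(const.constant_binders) if const else []
                if not mols:
                    cluster_report[sp] = {"note": "no constant binders"}
                    continue
                mol = mols[0]
                idx = traj.topology.molecule_atoms(mol, head_only=True)
                stride = max(1, traj.n_frames // 200)
                poses = PoseSet(traj.coords[::stride][:, idx, :])
                dm = pose_rmsd_matrix(poses, superpose=False)
                res = gromos_cluster(dm, cutoff=5.0)
                cluster_report[sp] = {
                    "molecule_id": mol,
                    "n_clusters": len(res.cluster_ids),
                    "top_population": max(res.populations.values()),
                    "representatives": {str(k): int(v) for k, v in res.representatives.items()},
                }
            report["stages"]["clustering"] = cluster_report

        if truth is not None:
            report["ground_truth"] = {
                "planted_site_residues": {
                    s: sorted(map(list, v)) for s, v in truth.planted_site_residues.items()
                },
                "pinned_molecule_id": truth.pinned_molecule_id,
                "mean_dwell_frames": truth.mean_dwell_frames,
            }
    except PufasiteError:
        (out / "FAILED").write_text(f"stage failed: {stage}\n")
        raise
    except Exception as exc:
        (out / "FAILED").write_text(f"stage failed: {stage}\n")
        raise PufasiteError(f"stage {stage!r} failed: {exc}") from exc

    blob = json.dumps(report, indent=2, sort_keys=True, default=_json_default)
    (out / "report.json").write_text(blob + "\n")
    return report


def _slab_reference(report, traj, sp):
    """Reference residues for slab profiles: classified high-contact set if
    available, else all protein residues."""
    try:
        hc = report["stages"]["contacts"][sp]["high_contact"]
        if hc:
            # classification is on the first subunit after averaging; expand
            # each position to every subunit
            subs = list(traj.topology.subunit_map)
            return [(s, int(r)) for (_, r) in map(tuple, hc) for s in subs]
    except KeyError:
        pass
    return traj.topology.residue_keys()


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
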