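"""Per-lipid interaction statistics and binder classification.

Aggregating the contact tensor over residues gives each lipid a total
interaction time with the protein and a longest uninterrupted contact run.
Lipids whose total time reaches the upper quartile (inclusive) are the UQ
binders; lipids in contact in literally every frame are the constant
binders.  For a chosen bound lipid, residues are discriminated into
*binder* residues (persistent direct atomic contact) and *proximal*
residues (persistently within the generic contact shell but never in
direct contact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactTensor, longest_run_lengths
from .core import AnalysisConfig, ElementClass, Trajectory
from .errors import ArgumentError, InsufficientDataError

__all__ = [
    "LipidStats",
    "BinderSets",
    "ResidueRole",
    "lipid_interaction_stats",
    "identify_uq_binders",
    "identify_constant_binders",
    "residue_lipid_min_distance",
    "classify_binder_residues",
]


@dataclass
class LipidStats:
    """Per-lipid total interaction time / longest lifetime with the protein."""

    lipid_ids: list[int]
    total_time: np.ndarray  # ns
    longest_lifetime: np.ndarray  # ns
    dt: float
    duration: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "molecule_id": self.lipid_ids,
                "total_time_ns": self.total_time,
                "longest_lifetime_ns": self.longest_lifetime,
            }
        )


@dataclass
class BinderSets:
    uq_binders: set = field(default_factory=set)
    constant_binders: set = field(default_factory=set)
    uq_threshold: float | None = None  # ns


@dataclass
class ResidueRole:
    residue_key: tuple[str, int]
    lipid_id: int
    role: str  # "binder" | "proximal" | "none"
    direct_fraction: float
    shell_fraction: float
    min_distance_mean: float


def lipid_interaction_stats(tensor: ContactTensor) -> LipidStats:
    """Aggregate the contact tensor over residues, per lipid."""
    if tensor.presence.size == 0:
        raise ArgumentError("empty contact tensor")
    any_res = tensor.presence.any(axis=2)  # (F, L)
    total = any_res.sum(axis=0) * tensor.dt
    longest = longest_run_lengths(any_res.T) * tensor.dt
    return LipidStats(
        lipid_ids=list(tensor.lipid_ids),
        total_time=total,
        longest_lifetime=longest,
        dt=tensor.dt,
        duration=tensor.duration,
    )


def identify_uq_binders(stats: LipidStats, q_method: str = "linear") -> BinderSets:
    """Lipids whose total interaction time reaches the upper quartile.

    Membership is inclusive (total time >= Q3); the threshold is reported.
    """
    n = len(stats.lipid_ids)
    if n < 4:
        raise InsufficientDataError(f"need >= 4 lipids for quartile selection, got {n}")
    q3 = float(np.quantile(stats.total_time, 0.75, method=q_method))
    uq = {m for m, t in zip(stats.lipid_ids, stats.total_time) if t >= q3}
    return BinderSets(uq_binders=uq, uq_threshold=q3)


def identify_constant_binders(
    stats: LipidStats, duration: float, max_missing_frames: int = 0
) -> BinderSets:
    """Lipids bound for the entire trajectory (longest lifetime = duration).

    ``max_missing_frames`` relaxes the all-frames requirement by allowing
    the longest run to fall short by that many frames (default 0: strict).
    """
    slack = max_missing_frames * stats.dt
    constant = {
        m
        for m, l in zip(stats.lipid_ids, stats.longest_lifetime)
        if l >= duration - slack - 1e-9
    }
    return BinderSets(constant_binders=constant)


def residue_lipid_min_distance(
    traj: Trajectory, residue: tuple[str, int], lipid: int
) -> np.ndarray:
    """Per-frame minimum heavy-atom distance (Å) between a residue and a lipid."""
    top = traj.topology
    r_idx = [
        i
        for i in top.residue_atom_indices(residue)
        if top.atoms[i].element_class is not ElementClass.H
    ]
    l_idx = [
        int(i)
        for i in top.molecule_atoms(lipid)
        if top.atoms[i].element_class is not ElementClass.H
    ]
    if not r_idx:
        raise ArgumentError(f"residue {residue} not found or has no heavy atoms")
    if not l_idx:
        raise ArgumentError(f"lipid molecule {lipid} not found or has no heavy atoms")
    ra = traj.coords[:, r_idx, :]
    la = traj.coords[:, l_idx, :]
    box = traj.boxes[:, None, None, :]
    d = ra[:, :, None, :] - la[:, None, :, :]
    d -= box * np.round(d / box)
    dist = np.sqrt(np.einsum("fijk,fijk->fij", d, d))
    return dist.min(axis=(1, 2))


def classify_binder_residues(
    traj: Trajectory,
    lipid: int,
    candidate_residues: list[tuple[str, int]],
    config: AnalysisConfig | None = None,
    frames: np.ndarray | None = None,
) -> list[ResidueRole]:
    """Discriminate binder vs proximal residues for one bound lipid.

    A residue is a *binder* when direct contact (minimum heavy-atom
    distance <= the hydrophobic cutoff, 4.0 Å by default) persists in at
    least the configured fraction of frames (default 0.5); *proximal* when
    it persistently sits within the generic contact cutoff (6 Å) without
    qualifying as a binder; otherwise *none*.  ``frames`` optionally
    restricts the analysis to a boolean frame mask (e.g. bound frames).
    """
    config = config or AnalysisConfig()
    theta = config.binder_persistence
    roles = []
    for key in candidate_residues:
        dist = residue_lipid_min_distance(traj, key, lipid)
        if frames is not None:
            dist = dist[np.asarray(frames, dtype=bool)]
        if dist.size == 0:
            raise ArgumentError("no frames selected for role classification")
        direct = float(np.mean(dist <= config.hydrophobic_cutoff))
        shell = float(np.mean(dist <= config.contact_cutoff))
        if direct >= theta:
            role = "binder"
        elif shell >= theta:
            role = "proximal"
        else:
            role = "none"
        roles.append(
            ResidueRole(
                residue_key=key,
                lipid_id=lipid,
                role=role,
                direct_fraction=direct,
                shell_fraction=shell,
                min_distance_mean=float(dist.mean()),
            )
        )
    return roles
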