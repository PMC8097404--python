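"""Contact detection and per-residue interaction statistics.

A contact exists when any atom of a lipid (or only its head-group atoms,
depending on mode) lies within the cutoff of any atom of a residue under
the minimum-image convention.  Two statistics summarize each residue's
lipid engagement: the *total interaction time* (time with at least one
lipid in contact, union over lipids so simultaneous contacts are not
double-counted) and the *longest lifetime* (the single longest
uninterrupted contact run with any one lipid; one absent frame breaks a
run).  Residues whose statistic falls above Q3 + 1.5·IQR across all
residues are the high-contact (total time) and stable-contact (longest
lifetime) residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Role, Trajectory
from .errors import ArgumentError, InsufficientDataError, StructureError

__all__ = [
    "ContactTensor",
    "ResidueStats",
    "ResidueClassification",
    "compute_contact_tensor",
    "count_lipids_near_protein",
    "residue_total_interaction_time",
    "residue_longest_lifetime",
    "residue_stats",
    "symmetry_average",
    "classify_contact_residues",
    "longest_run_lengths",
    "tukey_fence",
]


# ---------------------------------------------------------------------------
# Run-length machinery (shared with lipid- and bond-level statistics)
# ---------------------------------------------------------------------------

def longest_run_lengths(mask: np.ndarray) -> np.ndarray:
    """Longest run of consecutive True per row of a (n_series, n_frames) array."""
    mask = np.atleast_2d(np.asarray(mask, dtype=bool))
    n = mask.shape[0]
    pad = np.zeros((n, 1), dtype=np.int8)
    m = np.hstack([pad, mask.astype(np.int8), pad])
    d = np.diff(m, axis=1)
    rs, cs = np.nonzero(d == 1)
    re, ce = np.nonzero(d == -1)
    out = np.zeros(n, dtype=int)
    if rs.size:
        np.maximum.at(out, rs, ce - cs)  # starts/ends pair up in row-major order
    return out


def tukey_fence(values: np.ndarray, q_method: str = "linear") -> tuple[float, float, float]:
    """(Q3, IQR, fence) with fence = Q3 + 1.5*IQR."""
    values = np.asarray(values, dtype=float)
    q1, q3 = np.quantile(values, [0.25, 0.75], method=q_method)
    iqr = q3 - q1
    return float(q3), float(iqr), float(q3 + 1.5 * iqr)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ContactTensor:
    """Boolean contact presence per (frame, lipid molecule, residue)."""

    presence: np.ndarray  # (n_frames, n_lipids, n_residues) bool
    lipid_ids: list[int]
    residue_keys: list[tuple[str, int]]
    dt: float
    mode: str  # "whole_lipid" | "headgroup_only"
    cutoff: float

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.ndim != 3:
            raise ArgumentError("presence must be (n_frames, n_lipids, n_residues)")
        if self.presence.shape[1] != len(self.lipid_ids):
            raise StructureError("lipid axis inconsistent with lipid_ids")
        if self.presence.shape[2] != len(self.residue_keys):
            raise StructureError("residue axis inconsistent with residue_keys")
        if self.cutoff <= 0:
            raise ArgumentError("cutoff must be > 0")

    @property
    def n_frames(self) -> int:
        return self.presence.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames * self.dt


@dataclass
class ResidueStats:
    """Per-residue total interaction time and longest lifetime (ns)."""

    residue_keys: list[tuple[str, int]]
    total_time: np.ndarray
    longest_lifetime: np.ndarray
    dt: float
    duration: float
    averaged: bool = False
    quantile_convention: str = "linear"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subunit": [k[0] for k in self.residue_keys],
                "residue_index": [k[1] for k in self.residue_keys],
                "total_time_ns": self.total_time,
                "longest_lifetime_ns": self.longest_lifetime,
                "averaged": self.averaged,
            }
        )


@dataclass
class ResidueClassification:
    """Outlier residues above the Tukey fence for each statistic."""

    high_contact: set
    stable_contact: set
    fence_values: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Contact tensor
# ---------------------------------------------------------------------------

def _within_cutoff(a: np.ndarray, b: np.ndarray, boxes: np.ndarray, cutoff: float) -> np.ndarray:
    """(F, nA, nB) within-cutoff booleans under minimum image.

    Coordinates are wrapped into the box first, so component differences
    lie in (−L, L) and the minimum image reduces to one comparison per
    dimension; accumulation is per-dimension in float32 to keep the
    workspace at a single (F, nA, nB) array.
    """
    boxes = np.asarray(boxes, dtype=np.float32)
    box = boxes[:, None, None, :]
    a = np.mod(a, boxes[:, None, :]).astype(np.float32)
    b = np.mod(b, boxes[:, None, :]).astype(np.float32)
    d2 = None
    for k in range(3):
        d = a[:, :, None, k] - b[:, None, :, k]
        L = box[..., k]
        half = 0.5 * L
        d += L * (d < -half)
        d -= L * (d >= half)
        d *= d
        d2 = d if d2 is None else d2 + d
    return d2 <= np.float32(cutoff * cutoff)

def _grouped_atom_arrays(traj: Trajectory, lipid_species: str, mode: str,
                         protein_residues=None):
    top = traj.topology
    mols = top.lipid_molecules(lipid_species)
    if not mols:
        raise ArgumentError(
            f"no lipid molecules of species {lipid_species!r}; available: "
            f"{sorted(set(top.species_table.values()))}"
        )
    head_only = mode == "headgroup_only"
    lip_atoms, lip_starts = [], []
    for m in mols:
        idx = top.molecule_atoms(m, head_only=head_only)
        if idx.size == 0:
            raise ArgumentError(f"lipid molecule {m} has no atoms in mode {mode!r}")
        lip_starts.append(len(lip_atoms))
        lip_atoms.extend(idx.tolist())

    keys = top.residue_keys()
    if protein_residues is not None:
        wanted = set(protein_residues)
        keys = [k for k in keys if k in wanted or k[1] in wanted]
    if not keys:
        raise ArgumentError("no protein residues selected")
    res_atoms, res_starts = [], []
    for k in keys:
        idx = top.residue_atom_indices(k)
        res_starts.append(len(res_atoms))
        res_atoms.extend(idx.tolist())
    return (mols, np.array(lip_atoms), np.array(lip_starts),
            keys, np.array(res_atoms), np.array(res_starts))


def compute_contact_tensor(
    traj: Trajectory,
    lipid_species: str,
    protein_residues=None,
    cutoff: float = 6.0,
    mode: str = "whole_lipid",
) -> ContactTensor:
    """Boolean (frame, lipid, residue) contact tensor at the given cutoff.

    ``mode`` selects whether any lipid atom (``whole_lipid``) or only
    head-group atoms (``headgroup_only``) can register a contact.
    """
    if mode not in ("whole_lipid", "headgroup_only"):
        raise ArgumentError(f"unknown mode {mode!r}")
    if cutoff <= 0:
        raise ArgumentError("cutoff must be > 0")
    mols, lip_atoms, lip_starts, keys, res_atoms, res_starts = _grouped_atom_arrays(
        traj, lipid_species, mode, protein_residues
    )
    F = traj.n_frames
    presence = np.empty((F, len(mols), len(keys)), dtype=bool)
    # chunk frames to bound the (chunk, n_lip_atoms, n_res_atoms) workspace
    per_frame = len(lip_atoms) * len(res_atoms)
    chunk = max(1, int(4e7 // max(per_frame, 1)))
    for f0 in range(0, F, chunk):
        f1 = min(F, f0 + chunk)
        within = _within_cutoff(
            traj.coords[f0:f1][:, lip_atoms, :],
            traj.coords[f0:f1][:, res_atoms, :],
            traj.boxes[f0:f1],
            cutoff,
        )
        within = np.logical_or.reduceat(within, lip_starts, axis=1)
        within = np.logical_or.reduceat(within, res_starts, axis=2)
        presence[f0:f1] = within
    return ContactTensor(
        presence=presence,
        lipid_ids=list(mols),
        residue_keys=keys,
        dt=traj.dt if traj.dt is not None else 1.0,
        mode=mode,
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# Lipid counting near the protein surface
# ---------------------------------------------------------------------------

def count_lipids_near_protein(
    traj: Trajectory,
    lipid_species: str,
    cutoff: float = 6.0,
    window: float | None = None,
    leaflet: str | None = None,
) -> pd.DataFrame:
    """Per-frame count of lipids with a head-group atom near the protein.

    A lipid counts in a frame when at least one of its head-group atoms
    lies within ``cutoff`` of any protein atom.  ``window`` (ns) adds a
    centered running average (shrinking at the edges); ``leaflet``
    restricts counting to "outer" or "inner" lipids (assigned per frame
    from the head-group midplane).
    """
    top = traj.topology
    mols, lip_atoms, lip_starts, _, res_atoms, _ = _grouped_atom_arrays(
        traj, lipid_species, "headgroup_only", None
    )
    if window is not None:
        if traj.dt is None:
            raise ArgumentError("running average needs a defined dt")
        if window < traj.dt:
            raise ArgumentError(f"window {window} ns < frame spacing {traj.dt} ns")

    leaflet_mask = None
    if leaflet is not None:
        from .core import Selection, assign_leaflets

        head_all = top.atom_indices(lambda a: a.role is Role.lipid_head)
        all_mols, labels = assign_leaflets(
            traj, Selection("heads", list(head_all))
        )
        cols = [all_mols.index(m) for m in mols]
        leaflet_mask = labels[:, cols] == leaflet  # (F, n_lip)

    F = traj.n_frames
    counts = np.empty(F, dtype=int)
    per_frame = len(lip_atoms) * len(res_atoms)
    chunk = max(1, int(4e7 // max(per_frame, 1)))
    for f0 in range(0, F, chunk):
        f1 = min(F, f0 + chunk)
        near_atom = _within_cutoff(
            traj.coords[f0:f1][:, lip_atoms, :],
            traj.coords[f0:f1][:, res_atoms, :],
            traj.boxes[f0:f1],
            cutoff,
        ).any(axis=2)
        near_mol = np.logical_or.reduceat(near_atom, lip_starts, axis=1)
        if leaflet_mask is not None:
            near_mol &= leaflet_mask[f0:f1]
        counts[f0:f1] = near_mol.sum(axis=1)

    out = pd.DataFrame({"time_ns": traj.times, "count": counts})
    if window is not None:
        w = max(1, int(round(window / traj.dt)))
        out["running_average"] = (
            pd.Series(counts).rolling(window=w, center=True, min_periods=1).mean().to_numpy()
        )
    return out


# ---------------------------------------------------------------------------
# Residue statistics
# ---------------------------------------------------------------------------

def residue_total_interaction_time(tensor: ContactTensor, union: bool = True) -> np.ndarray:
    """Per-residue total interaction time (ns).

    With ``union`` (default) a frame counts once however many lipids touch
    the residue; the sum variant adds per-lipid contact frames instead.
    """
    if tensor.presence.size == 0:
        raise ArgumentError("empty contact tensor")
    if union:
        frames = tensor.presence.any(axis=1).sum(axis=0)
    else:
        frames = tensor.presence.sum(axis=(0, 1))
    return frames * tensor.dt


def residue_longest_lifetime(tensor: ContactTensor) -> np.ndarray:
    """Per-residue longest uninterrupted contact run with any one lipid (ns)."""
    if tensor.presence.size == 0:
        raise ArgumentError("empty contact tensor")
    F, L, R = tensor.presence.shape
    series = np.moveaxis(tensor.presence, 0, -1).reshape(L * R, F)
    runs = longest_run_lengths(series).reshape(L, R)
    return runs.max(axis=0) * tensor.dt


def residue_stats(tensor: ContactTensor, union: bool = True,
                  quantile_convention: str = "linear") -> ResidueStats:
    return ResidueStats(
        residue_keys=list(tensor.residue_keys),
        total_time=residue_total_interaction_time(tensor, union=union),
        longest_lifetime=residue_longest_lifetime(tensor),
        dt=tensor.dt,
        duration=tensor.duration,
        quantile_convention=quantile_convention,
    )


def symmetry_average(stats: ResidueStats, subunit_map: dict[str, list[int]]) -> ResidueStats:
    """Average per-residue statistics across symmetric subunits.

    Position i of every subunit (in ``subunit_map`` order) is averaged;
    the result is reported against the first subunit's residue numbering.
    """
    subs = list(subunit_map)
    lengths = {s: len(subunit_map[s]) for s in subs}
    if len(set(lengths.values())) > 1:
        raise StructureError(f"unequal subunit residue counts: {lengths}")
    n_pos = lengths[subs[0]]
    index = {k: i for i, k in enumerate(stats.residue_keys)}
    total = np.zeros(n_pos)
    longest = np.zeros(n_pos)
    for s in subs:
        for pos, resid in enumerate(subunit_map[s]):
            try:
                i = index[(s, resid)]
            except KeyError:
                raise StructureError(f"residue ({s}, {resid}) missing from stats")
            total[pos] += stats.total_time[i]
            longest[pos] += stats.longest_lifetime[i]
    total /= len(subs)
    longest /= len(subs)
    first = subs[0]
    keys = [(first, r) for r in subunit_map[first]]
    return ResidueStats(
        residue_keys=keys,
        total_time=total,
        longest_lifetime=longest,
        dt=stats.dt,
        duration=stats.duration,
        averaged=True,
        quantile_convention=stats.quantile_convention,
    )


def classify_contact_residues(stats: ResidueStats) -> ResidueClassification:
    """Tukey-fence outlier calling of high-contact and stable-contact residues.

    Residues whose statistic is strictly above Q3 + 1.5·IQR (computed over
    all residues with linear-interpolation quantiles) are flagged; ties at
    the fence are excluded.
    """
    n = len(stats.residue_keys)
    if n < 4:
        raise InsufficientDataError(f"need >= 4 residues for quartile fence, got {n}")
    out = ResidueClassification(high_contact=set(), stable_contact=set())
    for name, values, target in (
        ("total_time", stats.total_time, "high_contact"),
        ("longest_lifetime", stats.longest_lifetime, "stable_contact"),
    ):
        q3, iqr, fence = tukey_fence(values, stats.quantile_convention)
        flagged = {k for k, v in zip(stats.residue_keys, values) if v > fence}
        setattr(out, target, flagged)
        out.fence_values[name] = {"Q3": q3, "IQR": iqr, "fence": fence}
    return out
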