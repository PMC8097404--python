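"""Distance-criterion detection of hydrogen bonds, salt bridges, and
hydrophobic contacts, with run-length lifetime statistics.

The hydrogen-bond criterion is purely geometric: a donor hydrogen (a
hydrogen covalently bound to N/O/S, identified from the bond list or a
<=1.2-Å heavy-atom heuristic) within 3.5 Å of an electronegative acceptor
(any N/O/S).  No angle term is applied by default; a conventional
donor–acceptor distance + angle mode exists but is off by default.  Salt
bridges are N–O pairs within 4 Å; hydrophobic contacts are C–C pairs
within 4.0 Å.  All distances are minimum-image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import longest_run_lengths
from .core import ElementClass, Selection, Trajectory
from .errors import ArgumentError, CriteriaError

__all__ = [
    "BondCriteria",
    "BondSeries",
    "detect_hbonds",
    "detect_salt_bridges",
    "detect_hydrophobic_contacts",
    "bond_time_stats",
]

_ELECTRONEGATIVE = {ElementClass.N, ElementClass.O, ElementClass.S}


@dataclass
class BondCriteria:
    hbond_cutoff: float = 3.5  # hydrogen-to-acceptor, Å
    saltbridge_cutoff: float = 4.0  # N–O, Å
    hydrophobic_cutoff: float = 4.0  # C–C, Å
    covalent_h_cutoff: float = 1.2  # heavy-atom–H heuristic when bonds absent
    angle_mode: bool = False  # donor–acceptor distance + D-H..A angle variant
    angle_min_deg: float = 130.0

    def __post_init__(self):
        for name in ("hbond_cutoff", "saltbridge_cutoff", "hydrophobic_cutoff"):
            if getattr(self, name) <= 0:
                raise ArgumentError(f"{name} must be > 0")


@dataclass
class BondSeries:
    """Boolean presence per (pair descriptor, frame)."""

    presence: np.ndarray  # (n_pairs, n_frames) bool
    pairs: list[tuple]  # descriptors: (atom_i, atom_j, kind)
    dt: float
    kind: str

    def __post_init__(self):
        self.presence = np.atleast_2d(np.asarray(self.presence, dtype=bool))
        if self.presence.shape[0] != len(self.pairs):
            raise ArgumentError("presence rows inconsistent with pair descriptors")

    def any_series(self) -> np.ndarray:
        """Union over pairs: bond of this kind present at all, per frame."""
        return self.presence.any(axis=0)


def _donor_hydrogens(traj: Trajectory, donor_group: Selection, criteria: BondCriteria):
    """Hydrogens in the donor group covalently bound to an N/O/S atom."""
    top = traj.topology
    donor_group.validate(top)
    h_idx = [
        i for i in donor_group.atom_indices if top.atoms[i].element_class is ElementClass.H
    ]
    heavies = {}
    if top.bonds:
        bonded: dict[int, list[int]] = {}
        for i, j in top.bonds:
            bonded.setdefault(i, []).append(j)
            bonded.setdefault(j, []).append(i)
        for h in h_idx:
            for j in bonded.get(h, []):
                if top.atoms[j].element_class in _ELECTRONEGATIVE:
                    heavies[h] = j
                    break
    else:
        # nearest heavy atom within the covalent heuristic in the first frame
        frame0 = traj.coords[0]
        box = traj.boxes[0]
        en_idx = [
            a.atom_index for a in top.atoms if a.element_class in _ELECTRONEGATIVE
        ]
        if en_idx:
            for h in h_idx:
                d = frame0[en_idx] - frame0[h]
                d -= box * np.round(d / box)
                dist = np.sqrt((d * d).sum(axis=1))
                j = int(np.argmin(dist))
                if dist[j] <= criteria.covalent_h_cutoff:
                    heavies[h] = en_idx[j]
    donors = [(h, heavies[h]) for h in h_idx if h in heavies]
    if not donors:
        raise CriteriaError(
            "no donor hydrogens bound to N/O/S found in the donor group; "
            "for coarse-grained systems use bead-level contact analysis instead"
        )
    return donors


def _pair_presence(traj: Trajectory, idx_a, idx_b, cutoff: float) -> np.ndarray:
    """(n_a*n_b, n_frames) within-cutoff booleans for all cross pairs."""
    a = traj.coords[:, idx_a, :]
    b = traj.coords[:, idx_b, :]
    box = traj.boxes[:, None, None, :]
    d = a[:, :, None, :] - b[:, None, :, :]
    d -= box * np.round(d / box)
    within = np.einsum("fijk,fijk->fij", d, d) <= cutoff * cutoff
    F = traj.n_frames
    return within.reshape(F, -1).T


def detect_hbonds(
    traj: Trajectory,
    donor_group: Selection,
    acceptor_group: Selection,
    criteria: BondCriteria | None = None,
) -> BondSeries:
    """Frame-wise hydrogen-bond presence between donor and acceptor groups.

    A bond is present when a qualifying donor hydrogen lies within the
    hydrogen-to-acceptor cutoff of an N/O/S acceptor.  One series per
    (hydrogen, acceptor) pair is returned.
    """
    criteria = criteria or BondCriteria()
    top = traj.topology
    acceptor_group.validate(top)
    donors = _donor_hydrogens(traj, donor_group, criteria)
    acc = [
        i
        for i in acceptor_group.atom_indices
        if top.atoms[i].element_class in _ELECTRONEGATIVE
    ]
    if not acc:
        raise CriteriaError("acceptor group contains no N/O/S atoms")
    h_atoms = [h for h, _ in donors]
    presence = _pair_presence(traj, h_atoms, acc, criteria.hbond_cutoff)
    if criteria.angle_mode:
        # D-H...A angle filter on top of a donor-heavy-atom distance check
        box = traj.boxes[:, None, :]
        keep_rows = []
        for r, ((h, dheavy), a) in enumerate((dd, aa) for dd in donors for aa in acc):
            hv = traj.coords[:, h, :]
            dv = traj.coords[:, dheavy, :] - hv
            av = traj.coords[:, a, :] - hv
            dv -= traj.boxes * np.round(dv / traj.boxes)
            av -= traj.boxes * np.round(av / traj.boxes)
            cosang = np.einsum("fk,fk->f", dv, av) / (
                np.linalg.norm(dv, axis=1) * np.linalg.norm(av, axis=1) + 1e-12
            )
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            keep_rows.append(presence[r] & (ang >= criteria.angle_min_deg))
        presence = np.array(keep_rows)
    pairs = [(h, a, "hbond") for h, _ in donors for a in acc]
    return BondSeries(presence=presence, pairs=pairs, dt=traj.dt or 1.0, kind="hbond")


def detect_salt_bridges(
    traj: Trajectory,
    basic_nitrogens: Selection,
    acidic_oxygens: Selection,
    criteria: BondCriteria | None = None,
) -> BondSeries:
    """Frame-wise salt-bridge presence: N–O pairs within the cutoff."""
    criteria = criteria or BondCriteria()
    top = traj.topology
    basic_nitrogens.validate(top)
    acidic_oxygens.validate(top)
    bad_n = [i for i in basic_nitrogens.atom_indices
             if top.atoms[i].element_class is not ElementClass.N]
    bad_o = [i for i in acidic_oxygens.atom_indices
             if top.atoms[i].element_class is not ElementClass.O]
    if bad_n or bad_o:
        raise ArgumentError(
            f"salt-bridge selections must be N and O atoms; offending indices "
            f"N-side {bad_n}, O-side {bad_o}"
        )
    presence = _pair_presence(
        traj, list(basic_nitrogens.atom_indices), list(acidic_oxygens.atom_indices),
        criteria.saltbridge_cutoff,
    )
    pairs = [
        (i, j, "saltbridge")
        for i in basic_nitrogens.atom_indices
        for j in acidic_oxygens.atom_indices
    ]
    return BondSeries(presence=presence, pairs=pairs, dt=traj.dt or 1.0, kind="saltbridge")


def detect_hydrophobic_contacts(
    traj: Trajectory,
    carbonsA: Selection,
    carbonsB: Selection,
    criteria: BondCriteria | None = None,
) -> BondSeries:
    """Frame-wise hydrophobic contacts: C–C pairs within the cutoff."""
    criteria = criteria or BondCriteria()
    top = traj.topology
    carbonsA.validate(top)
    carbonsB.validate(top)
    for sel in (carbonsA, carbonsB):
        bad = [i for i in sel.atom_indices
               if top.atoms[i].element_class is not ElementClass.C]
        if bad:
            raise ArgumentError(
                f"hydrophobic-contact selection {sel.label!r} must contain only "
                f"carbons; offending indices {bad}"
            )
    presence = _pair_presence(
        traj, list(carbonsA.atom_indices), list(carbonsB.atom_indices),
        criteria.hydrophobic_cutoff,
    )
    pairs = [
        (i, j, "hydrophobic")
        for i in carbonsA.atom_indices
        for j in carbonsB.atom_indices
    ]
    return BondSeries(presence=presence, pairs=pairs, dt=traj.dt or 1.0, kind="hydrophobic")


def bond_time_stats(series: BondSeries, union: bool = False) -> pd.DataFrame:
    """Total interaction time and longest lifetime per pair descriptor (ns).

    Same run-length semantics as the residue-level contact statistics.
    With ``union`` a single row aggregates all pairs (bond of this kind
    present at all).
    """
    if series.presence.size == 0:
        raise ArgumentError("empty bond series")
    if union:
        mask = series.any_series()[None, :]
        descriptors = [("any", "any", series.kind)]
    else:
        mask = series.presence
        descriptors = series.pairs
    total = mask.sum(axis=1) * series.dt
    longest = longest_run_lengths(mask) * series.dt
    return pd.DataFrame(
        {
            "atom_i": [p[0] for p in descriptors],
            "atom_j": [p[1] for p in descriptors],
            "kind": [p[2] for p in descriptors],
            "total_time_ns": total,
            "longest_lifetime_ns": longest,
        }
    )
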