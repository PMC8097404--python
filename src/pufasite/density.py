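"""Spatial enrichment representations: occupancy grids, layered maps,
slab contact profiles, fold enrichment, and radial distribution functions.

Occupancy is binary per frame per voxel — the fraction of frames in which
at least one selected atom visits the voxel — so a value of 0.03 reads as
"present in 3% of frames".  Grids are axis-aligned, origin at the box
corner, with half-open voxel intervals [lo, hi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Selection, Trajectory
from .errors import ArgumentError

__all__ = [
    "OccupancyGrid",
    "SlabProfile",
    "FoldChangeProfile",
    "RDFProfile",
    "occupancy_grid",
    "threshold_contour",
    "layered_occupancy_maps",
    "slab_contact_profile",
    "fold_enrichment",
    "lateral_rdf",
    "write_opendx",
]


@dataclass
class OccupancyGrid:
    origin: np.ndarray  # (3,) Å
    spacing: float  # Å
    counts: np.ndarray  # (nx, ny, nz) int, frames with >=1 selected atom
    n_frames: int

    @property
    def occupancy(self) -> np.ndarray:
        return self.counts / self.n_frames


@dataclass
class SlabProfile:
    """Contact counts between head-group atoms and a reference set, binned
    along the bilayer normal in fixed-thickness z layers."""

    edges: np.ndarray  # (n_bins+1,) Å
    counts: np.ndarray  # (n_bins,) contact events
    interval_label: str
    species: str = ""

    @property
    def thickness(self) -> float:
        return float(self.edges[1] - self.edges[0])


@dataclass
class FoldChangeProfile:
    edges: np.ndarray
    ratio: np.ndarray  # nan where undefined
    numerator_only: np.ndarray  # bool, A>0 with B=0
    empty: np.ndarray  # bool, A=B=0
    interval_label: str = ""


@dataclass
class RDFProfile:
    r: np.ndarray  # bin centers Å
    g: np.ndarray
    counts: np.ndarray
    reference: str = ""
    mode: str = "axis"


def _constant_box(traj: Trajectory) -> np.ndarray:
    box = traj.boxes[0]
    if not np.allclose(traj.boxes, box, rtol=1e-6, atol=1e-6):
        warnings.warn("box fluctuates; using the first frame's box for gridding")
    return box


def occupancy_grid(
    traj: Trajectory,
    selection: Selection,
    resolution: float = 1.0,
    weighted: bool = False,
) -> OccupancyGrid:
    """3-D voxel occupancy of a selection over the trajectory.

    Binary per frame per voxel by default; ``weighted`` counts atoms
    instead (a density rather than an occupancy).
    """
    if resolution <= 0:
        raise ArgumentError("resolution must be > 0")
    if len(selection) == 0:
        raise ArgumentError("selection is empty")
    selection.validate(traj.topology)
    box = _constant_box(traj)
    shape = np.maximum(np.ceil(box / resolution).astype(int), 1)
    nvox = int(np.prod(shape))
    idx = np.asarray(selection.atom_indices, dtype=int)
    pos = np.mod(traj.coords[:, idx, :], box)
    vox = np.minimum((pos / resolution).astype(int), shape - 1)  # (F, n, 3)
    flat = (vox[..., 0] * shape[1] + vox[..., 1]) * shape[2] + vox[..., 2]
    counts = np.zeros(nvox, dtype=int)
    if weighted:
        np.add.at(counts, flat.ravel(), 1)
    else:
        f_ids = np.repeat(np.arange(traj.n_frames, dtype=np.int64), idx.size)
        combined = f_ids * nvox + flat.ravel()
        uniq = np.unique(combined)
        np.add.at(counts, (uniq % nvox).astype(int), 1)
    return OccupancyGrid(
        origin=np.zeros(3),
        spacing=resolution,
        counts=counts.reshape(tuple(shape)),
        n_frames=traj.n_frames,
    )


def threshold_contour(grid: OccupancyGrid, threshold: float) -> np.ndarray:
    """Boolean mask of voxels whose occupancy reaches the threshold."""
    if not (0 < threshold < 1):
        raise ArgumentError("threshold must lie in (0, 1)")
    return grid.occupancy >= threshold


def layered_occupancy_maps(
    traj: Trajectory,
    headgroup_selection: Selection,
    z_layers: list[tuple[float, float]],
    resolution: float = 1.0,
) -> list[OccupancyGrid]:
    """Per-z-layer 2-D x–y occupancy maps (binary per frame per cell).

    Each returned grid has shape (nx, ny, 1); a cell counts in a frame when
    a selected atom lies in that x–y cell with z inside the layer.
    """
    if not z_layers:
        raise ArgumentError("z_layers is empty")
    if len(headgroup_selection) == 0:
        raise ArgumentError("selection is empty")
    box = _constant_box(traj)
    for lo, hi in z_layers:
        if not (0 <= lo < hi <= box[2] + 1e-9):
            raise ArgumentError(f"layer ({lo}, {hi}) outside box z range [0, {box[2]}]")
    shape = np.maximum(np.ceil(box[:2] / resolution).astype(int), 1)
    ncell = int(np.prod(shape))
    idx = np.asarray(headgroup_selection.atom_indices, dtype=int)
    pos = np.mod(traj.coords[:, idx, :], box)
    cell = np.minimum((pos[..., :2] / resolution).astype(int), shape - 1)
    flat = cell[..., 0] * shape[1] + cell[..., 1]
    f_ids = np.repeat(np.arange(traj.n_frames, dtype=np.int64), idx.size)
    maps = []
    for lo, hi in z_layers:
        inside = ((pos[..., 2] >= lo) & (pos[..., 2] < hi)).ravel()
        combined = f_ids[inside] * ncell + flat.ravel()[inside]
        counts = np.zeros(ncell, dtype=int)
        if combined.size:
            uniq = np.unique(combined)
            np.add.at(counts, (uniq % ncell).astype(int), 1)
        maps.append(
            OccupancyGrid(
                origin=np.array([0.0, 0.0, lo]),
                spacing=resolution,
                counts=counts.reshape(shape[0], shape[1], 1),
                n_frames=traj.n_frames,
            )
        )
    return maps


def slab_contact_profile(
    traj: Trajectory,
    headgroup_selection: Selection,
    reference_residues: list[tuple[str, int]],
    shell_cutoff: float = 3.0,
    slab: float = 0.5,
    interval: float | None = None,
    species: str = "",
) -> list[SlabProfile]:
    """Contact counts in 0.5-Å z layers, per consecutive time interval.

    A contact event is one (frame, head-group atom) pair within
    ``shell_cutoff`` of any atom of the reference residues; events are
    binned by the head-group atom's z coordinate.  ``interval`` (ns)
    splits the trajectory into consecutive windows (one profile each);
    None gives a single profile over the whole run.
    """
    if shell_cutoff <= 0:
        raise ArgumentError("shell_cutoff must be > 0")
    if slab <= 0:
        raise ArgumentError("slab thickness must be > 0")
    if len(headgroup_selection) == 0:
        raise ArgumentError("selection is empty")
    top = traj.topology
    ref_idx = np.concatenate(
        [top.residue_atom_indices(k) for k in reference_residues]
    ).astype(int)
    if ref_idx.size == 0:
        raise ArgumentError(f"reference residues {reference_residues} not found")
    box = _constant_box(traj)
    edges = np.arange(0.0, box[2] + slab, slab)
    idx = np.asarray(headgroup_selection.atom_indices, dtype=int)

    if interval is None:
        bounds = [(0, traj.n_frames, "all")]
    else:
        if traj.dt is None:
            raise ArgumentError("intervals need a defined dt")
        per = max(1, int(round(interval / traj.dt)))
        bounds = [
            (f0, min(f0 + per, traj.n_frames), f"{f0 * traj.dt:g}-{min(f0 + per, traj.n_frames) * traj.dt:g}ns")
            for f0 in range(0, traj.n_frames, per)
        ]

    cut2 = shell_cutoff * shell_cutoff
    profiles = []
    for f0, f1, label in bounds:
        ha = traj.coords[f0:f1][:, idx, :]
        ra = traj.coords[f0:f1][:, ref_idx, :]
        b = traj.boxes[f0:f1][:, None, None, :]
        d = ha[:, :, None, :] - ra[:, None, :, :]
        d -= b * np.round(d / b)
        within = (np.einsum("fijk,fijk->fij", d, d) <= cut2).any(axis=2)
        z = np.mod(ha[..., 2], box[2])[within]
        counts, _ = np.histogram(z, bins=edges)
        profiles.append(
            SlabProfile(edges=edges, counts=counts, interval_label=label, species=species)
        )
    return profiles


def fold_enrichment(profileA: SlabProfile, profileB: SlabProfile) -> FoldChangeProfile:
    """Per-bin A/B contact-count ratio with degenerate bins flagged."""
    if profileA.edges.shape != profileB.edges.shape or not np.allclose(
        profileA.edges, profileB.edges
    ):
        raise ArgumentError("slab profiles have mismatched binning")
    a = profileA.counts.astype(float)
    b = profileB.counts.astype(float)
    ratio = np.full(a.shape, np.nan)
    ok = b > 0
    ratio[ok] = a[ok] / b[ok]
    return FoldChangeProfile(
        edges=profileA.edges.copy(),
        ratio=ratio,
        numerator_only=(a > 0) & (b == 0),
        empty=(a == 0) & (b == 0),
        interval_label=profileA.interval_label,
    )


def lateral_rdf(
    traj: Trajectory,
    headgroup_selection: Selection,
    protein_reference: Selection,
    r_bins: np.ndarray,
    mode: str = "axis",
) -> RDFProfile:
    """Radial distribution function of selected atoms around the protein.

    ``axis`` mode (default): lateral (x–y) distance from the protein's
    center-of-geometry axis, normalized by the uniform-density expectation
    over annular areas, so g(r) → 1 for a laterally uniform distribution.
    ``surface`` mode: 3-D minimum distance to any reference atom,
    normalized by mean sample density in equal-width shells of the
    empirical distance distribution (a qualitative profile; the axis mode
    carries the quantitative normalization).
    """
    if len(protein_reference) == 0:
        raise ArgumentError("protein reference selection is empty")
    if len(headgroup_selection) == 0:
        raise ArgumentError("head-group selection is empty")
    r_bins = np.asarray(r_bins, dtype=float)
    if r_bins.ndim != 1 or r_bins.size < 2:
        raise ArgumentError("r_bins must be a 1-D array of bin edges")
    box = _constant_box(traj)
    rmax_ok = min(box[0], box[1]) / 2.0
    if r_bins[-1] > rmax_ok + 1e-9:
        warnings.warn(
            f"r bins beyond half the lateral box ({rmax_ok:.1f} Å) truncated"
        )
        r_bins = r_bins[r_bins <= rmax_ok + 1e-9]
        if r_bins.size < 2:
            raise ArgumentError("no valid r bins after truncation")
    h_idx = np.asarray(headgroup_selection.atom_indices, dtype=int)
    p_idx = np.asarray(protein_reference.atom_indices, dtype=int)

    if mode == "axis":
        center = traj.coords[:, p_idx, :2].mean(axis=1)  # (F, 2)
        d = traj.coords[:, h_idx, :2] - center[:, None, :]
        d -= box[:2] * np.round(d / box[:2])
        r = np.sqrt((d * d).sum(axis=2)).ravel()
        counts, _ = np.histogram(r, bins=r_bins)
        area = np.pi * (r_bins[1:] ** 2 - r_bins[:-1] ** 2)
        expected = r.size * area / (box[0] * box[1])
        g = counts / expected
    elif mode == "surface":
        chunks = []
        for f in range(traj.n_frames):
            d = traj.coords[f, h_idx, None, :] - traj.coords[f, None, p_idx, :]
            d -= box * np.round(d / box)
            chunks.append(np.sqrt((d * d).sum(axis=2)).min(axis=1))
        r = np.concatenate(chunks)
        counts, _ = np.histogram(r, bins=r_bins)
        width = np.diff(r_bins)
        dens = counts / width
        mean_dens = r.size / (r_bins[-1] - r_bins[0])
        g = dens / mean_dens
    else:
        raise ArgumentError(f"unknown RDF mode {mode!r}")
    centers = 0.5 * (r_bins[1:] + r_bins[:-1])
    return RDFProfile(r=centers, g=g, counts=counts, reference=protein_reference.label, mode=mode)


def write_opendx(grid: OccupancyGrid, path, field_name: str = "occupancy") -> None:
    """Write a grid as an OpenDX scalar field (the common volumetric format)."""
    nx, ny, nz = grid.counts.shape
    data = grid.occupancy.ravel(order="C")
    with open(path, "w") as fh:
        fh.write(f"# pufasite {field_name} grid\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {grid.origin[0]:.3f} {grid.origin[1]:.3f} {grid.origin[2]:.3f}\n")
        fh.write(f"delta {grid.spacing:.6f} 0 0\n")
        fh.write(f"delta 0 {grid.spacing:.6f} 0\n")
        fh.write(f"delta 0 0 {grid.spacing:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {data.size} data follows\n"
        )
        for i in range(0, data.size, 3):
            fh.write(" ".join(f"{v:.6g}" for v in data[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write(f'object "{field_name}" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')
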