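"""Core domain model: annotated topologies, trajectories, periodic geometry.

Coordinates are stored in Å and times in ns throughout the package.  Boxes
are orthorhombic; distance computations use the minimum-image convention.
Residues are identified by ``(subunit_id, residue_index)`` pairs so that the
same author numbering can repeat across the four subunits of a symmetric
channel; lipids are identified by an integer ``molecule_id``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ArgumentError, StructureError

__all__ = [
    "Role",
    "ElementClass",
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "Selection",
    "AnalysisConfig",
    "minimum_image_displacement",
    "minimum_image_distance",
    "map_residue_numbering",
    "assign_leaflets",
]


class Role(enum.Enum):
    protein = "protein"
    lipid_head = "lipid_head"
    lipid_tail = "lipid_tail"
    other = "other"


class ElementClass(enum.Enum):
    C = "C"
    N = "N"
    O = "O"
    S = "S"
    H = "H"
    bead = "bead"
    other = "other"


@dataclass(frozen=True)
class AtomRecord:
    """One atom (or CG bead) with its species/role annotation."""

    atom_index: int
    atom_name: str
    residue_index: int
    residue_name: str
    subunit_id: str
    molecule_id: int
    species: str
    role: Role
    element_class: ElementClass


@dataclass
class Topology:
    """Ordered atom records plus molecule/subunit bookkeeping.

    ``subunit_map`` lists, per subunit label, the ordered residue indices of
    the protein; symmetry averaging requires all subunits to have the same
    residue count.
    """

    atoms: list[AtomRecord]
    species_table: dict[int, str] = field(default_factory=dict)
    bonds: list[tuple[int, int]] | None = None
    subunit_map: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        for i, a in enumerate(self.atoms):
            if a.atom_index != i:
                raise StructureError(
                    f"atom_index must be contiguous 0..n-1; atom {i} has index {a.atom_index}"
                )
        if not self.species_table:
            self.species_table = {a.molecule_id: a.species for a in self.atoms}
        missing = {a.molecule_id for a in self.atoms} - set(self.species_table)
        if missing:
            raise StructureError(f"species_table missing molecule_ids {sorted(missing)}")
        counts = {k: len(v) for k, v in self.subunit_map.items()}
        if counts and len(set(counts.values())) > 1:
            raise StructureError(f"unequal subunit residue counts: {counts}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    # --- cached index helpers -------------------------------------------------
    def atom_indices(self, predicate) -> np.ndarray:
        return np.array([a.atom_index for a in self.atoms if predicate(a)], dtype=int)

    def protein_atoms(self) -> np.ndarray:
        return self.atom_indices(lambda a: a.role is Role.protein)

    def lipid_molecules(self, species: str | None = None) -> list[int]:
        """Sorted molecule_ids of lipids, optionally restricted to one species."""
        mols = sorted(
            {
                a.molecule_id
                for a in self.atoms
                if a.role in (Role.lipid_head, Role.lipid_tail)
                and (species is None or a.species == species)
            }
        )
        return mols

    def molecule_atoms(self, molecule_id: int, head_only: bool = False) -> np.ndarray:
        return self.atom_indices(
            lambda a: a.molecule_id == molecule_id
            and (a.role is Role.lipid_head if head_only else True)
        )

    def residue_keys(self, subunits: list[str] | None = None) -> list[tuple[str, int]]:
        """Ordered (subunit_id, residue_index) keys of protein residues."""
        keys = []
        for sub, resids in self.subunit_map.items():
            if subunits is not None and sub not in subunits:
                continue
            keys.extend((sub, r) for r in resids)
        return keys

    def residue_atom_indices(self, key: tuple[str, int]) -> np.ndarray:
        sub, resid = key
        return self.atom_indices(
            lambda a: a.subunit_id == sub and a.residue_index == resid and a.role is Role.protein
        )

    def species_of_molecule(self, molecule_id: int) -> str:
        return self.species_table[molecule_id]


@dataclass
class Frame:
    """Coordinates (Å) + orthorhombic box lengths (Å) at one time (ns)."""

    coordinates: np.ndarray  # (n_atoms, 3)
    box: np.ndarray  # (3,)
    time: float

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ArgumentError("coordinates must be (n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ArgumentError("box lengths must be three positive values")


@dataclass
class Trajectory:
    """A topology plus a stack of frames with uniform spacing ``dt`` (ns).

    ``coords`` is the (n_frames, n_atoms, 3) coordinate array; ``boxes`` the
    per-frame box lengths.  ``dt`` is None for single-frame input, in which
    case time-based statistics are unavailable.
    """

    topology: Topology
    coords: np.ndarray
    boxes: np.ndarray
    times: np.ndarray
    dt: float | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ArgumentError("coords must be (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ArgumentError("trajectory needs at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise StructureError(
                f"coordinate atom count {self.coords.shape[1]} != topology "
                f"atom count {self.topology.n_atoms}"
            )
        if self.dt is None and len(self.times) > 1:
            steps = np.diff(self.times)
            dt = float(steps[0])
            if dt <= 0 or not np.allclose(steps, dt, atol=1e-6 * max(dt, 1e-12)):
                raise ArgumentError("frame times must increase with uniform spacing")
            self.dt = dt

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def duration(self) -> float:
        """Total sampled time: n_frames * dt (each frame counts one dt)."""
        if self.dt is None:
            raise ArgumentError("duration undefined for a single-frame trajectory")
        return self.n_frames * self.dt

    def frame(self, i: int) -> Frame:
        return Frame(self.coords[i], self.boxes[i], float(self.times[i]))

    def select(self, label: str, predicate) -> "Selection":
        return Selection(label, list(self.topology.atom_indices(predicate)))


@dataclass
class Selection:
    """A named, ordered, duplicate-free list of atom indices."""

    label: str
    atom_indices: list[int]

    def __post_init__(self):
        if len(set(self.atom_indices)) != len(self.atom_indices):
            raise ArgumentError(f"selection {self.label!r} contains duplicate indices")

    def __len__(self):
        return len(self.atom_indices)

    def validate(self, topology: Topology) -> None:
        n = topology.n_atoms
        bad = [i for i in self.atom_indices if not (0 <= i < n)]
        if bad:
            raise ArgumentError(f"selection {self.label!r} has out-of-range indices {bad}")


@dataclass
class AnalysisConfig:
    """Analysis cutoffs and conventions.

    Defaults follow the contact-analysis conventions for CG/AA membrane
    simulations: a 6-Å generic contact cutoff, 4.0-Å hydrophobic (C–C)
    cutoff, 3.5-Å hydrogen-bond and 4.0-Å salt-bridge (N–O) cutoffs, 1-Å
    occupancy grids, 0.5-Å slabs along the bilayer normal, 3-Å contact
    shells, and a 500-ns running-average window.
    """

    contact_cutoff: float = 6.0
    hydrophobic_cutoff: float = 4.0
    hbond_cutoff: float = 3.5
    saltbridge_cutoff: float = 4.0
    grid_resolution: float = 1.0
    slab_thickness: float = 0.5
    shell_cutoff: float = 3.0
    occupancy_thresholds: tuple[float, ...] = (0.10, 0.15, 0.20, 0.30)
    running_average_window: float = 500.0  # ns
    binder_persistence: float = 0.5  # fraction of frames for binder/proximal roles
    quantile_convention: str = "linear"
    numbering_offset: int = 10  # xKCNQ1 -> hKCNQ1 residue-number offset
    seed: int = 0

    def __post_init__(self):
        for name in (
            "contact_cutoff",
            "hydrophobic_cutoff",
            "hbond_cutoff",
            "saltbridge_cutoff",
            "grid_resolution",
            "slab_thickness",
            "shell_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ArgumentError(f"{name} must be > 0")
        if any(not (0 < t < 1) for t in self.occupancy_thresholds):
            raise ArgumentError("occupancy thresholds must lie in (0, 1)")

    def with_(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Periodic geometry
# ---------------------------------------------------------------------------

def minimum_image_displacement(a, b, box) -> np.ndarray:
    """Minimum-image displacement vector(s) b−a in an orthorhombic box."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ArgumentError("box lengths must be positive")
    d = b - a
    return d - box * np.round(d / box)


def minimum_image_distance(a, b, box) -> float | np.ndarray:
    """Euclidean distance(s) under the orthorhombic minimum-image convention."""
    d = minimum_image_displacement(a, b, box)
    return np.sqrt(np.sum(d * d, axis=-1))


def pairwise_min_image_distances(xa: np.ndarray, xb: np.ndarray, box) -> np.ndarray:
    """(len(xa), len(xb)) distance matrix under minimum image."""
    xa = np.atleast_2d(np.asarray(xa, dtype=float))
    xb = np.atleast_2d(np.asarray(xb, dtype=float))
    d = minimum_image_displacement(xa[:, None, :], xb[None, :, :], box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


# ---------------------------------------------------------------------------
# Residue numbering
# ---------------------------------------------------------------------------

def map_residue_numbering(residue_index: int, direction: str, offset: int = 10) -> int:
    """Translate between Xenopus (x) and human (h) KCNQ1 residue numbering.

    The two orthologs are offset by a constant: R218/K316 in xKCNQ1
    correspond to R228/K326 in hKCNQ1, i.e. ``x_to_h`` adds the offset and
    ``h_to_x`` subtracts it.
    """
    if direction == "x_to_h":
        return residue_index + offset
    if direction == "h_to_x":
        return residue_index - offset
    raise ArgumentError(f"direction must be 'x_to_h' or 'h_to_x', got {direction!r}")


# ---------------------------------------------------------------------------
# Leaflet assignment
# ---------------------------------------------------------------------------

def assign_leaflets(traj: Trajectory, headgroup_sel: Selection):
    """Assign each lipid to the outer or inner leaflet, per frame.

    The membrane midplane in a frame is the mean z of all head-group atoms
    in that frame; a lipid whose head-group centroid lies above it is
    ``outer``, otherwise ``inner``.

    Returns (molecule_ids, labels) where labels is an (n_frames, n_lipids)
    array of "outer"/"inner" strings.
    """
    if len(headgroup_sel) == 0:
        raise ArgumentError("head-group selection is empty")
    headgroup_sel.validate(traj.topology)
    idx = np.asarray(headgroup_sel.atom_indices, dtype=int)
    atoms = traj.topology.atoms
    mol_of = np.array([atoms[i].molecule_id for i in idx])
    mols = sorted(set(mol_of.tolist()))
    z = traj.coords[:, idx, 2]  # (F, n_head_atoms)
    midplane = z.mean(axis=1, keepdims=True)
    labels = np.empty((traj.n_frames, len(mols)), dtype=object)
    for j, m in enumerate(mols):
        zc = z[:, mol_of == m].mean(axis=1)
        labels[:, j] = np.where(zc > midplane[:, 0], "outer", "inner")
    if len(mols) > 1 and (np.all(labels == "outer") or np.all(labels == "inner")):
        warnings.warn("all lipids assigned to a single leaflet (degenerate z spread)")
    return mols, labels
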