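"""Trajectory/topology reading and writing (PDB, GRO, XTC, DCD).

MDAnalysis does the format work; this module converts its Universe into the
package's annotated :class:`~pufasite.core.Trajectory`, applying rule-driven
species/role annotation so that both coarse-grained bead naming and
all-atom naming can be handled without hard-coded residue tables.
"""

from __future__ import annotations

import fnmatch
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import AtomRecord, ElementClass, Role, Selection, Topology, Trajectory
from .errors import AnnotationError, ArgumentError, FormatError

__all__ = ["AnnotationRules", "load_trajectory", "write_trajectory", "write_bfactor_pdb"]

_ELEMENTS = {"C", "N", "O", "S", "H"}


@dataclass
class AnnotationRules:
    """Residue-name → species and atom-name → head/tail annotation rules.

    ``species_by_resname`` maps residue names (fnmatch patterns allowed) to
    species labels; species in ``protein_species`` are protein, everything
    else with a head pattern is a lipid.  ``head_patterns`` maps a lipid
    species to the atom-name patterns of its head-group atoms; remaining
    lipid atoms are tail.  ``coarse_grained`` marks every particle as a bead
    for element classification.
    """

    species_by_resname: dict[str, str]
    protein_species: set[str] = field(default_factory=lambda: {"PROT"})
    head_patterns: dict[str, list[str]] = field(default_factory=dict)
    coarse_grained: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationRules":
        return cls(
            species_by_resname=dict(d["species_by_resname"]),
            protein_species=set(d.get("protein_species", {"PROT"})),
            head_patterns={k: list(v) for k, v in d.get("head_patterns", {}).items()},
            coarse_grained=bool(d.get("coarse_grained", False)),
        )

    def species_of(self, resname: str) -> str | None:
        if resname in self.species_by_resname:
            return self.species_by_resname[resname]
        for pat, sp in self.species_by_resname.items():
            if fnmatch.fnmatchcase(resname, pat):
                return sp
        return None

    def role_of(self, species: str, atom_name: str) -> Role:
        if species in self.protein_species:
            return Role.protein
        pats = self.head_patterns.get(species)
        if pats is None:
            return Role.other
        if any(fnmatch.fnmatchcase(atom_name, p) for p in pats):
            return Role.lipid_head
        return Role.lipid_tail

    def element_of(self, atom_name: str, element: str | None = None) -> ElementClass:
        if self.coarse_grained:
            return ElementClass.bead
        sym = (element or "").strip().upper()
        if not sym:
            stripped = atom_name.strip().lstrip("0123456789")
            sym = stripped[:1].upper()
        if sym in _ELEMENTS:
            return ElementClass[sym]
        return ElementClass.other


def _orthorhombic_box(dimensions) -> np.ndarray:
    if dimensions is None or np.all(np.asarray(dimensions)[:3] == 0):
        raise FormatError("frame has no box information")
    dims = np.asarray(dimensions, dtype=float)
    if not np.allclose(dims[3:], 90.0, atol=1e-3):
        raise FormatError(f"only orthorhombic boxes are supported; angles {dims[3:]}")
    return dims[:3].copy()


def load_trajectory(
    topology_path,
    coordinates_path=None,
    rules: AnnotationRules | dict | None = None,
) -> Trajectory:
    """Read topology + coordinates into an annotated :class:`Trajectory`.

    ``topology_path`` is a PDB or GRO file; ``coordinates_path`` an XTC,
    DCD, or multi-model PDB (omitted for a single-structure file, giving a
    one-frame trajectory with undefined dt).  ``rules`` supplies the
    species/role annotation; unannotatable residue names raise
    :class:`AnnotationError` listing the offenders.
    """
    import MDAnalysis as mda

    if rules is None:
        raise ArgumentError("annotation rules are required")
    if isinstance(rules, dict):
        rules = AnnotationRules.from_dict(rules)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if coordinates_path is None:
                u = mda.Universe(str(topology_path))
            else:
                u = mda.Universe(str(topology_path), str(coordinates_path))
        except Exception as exc:  # MDAnalysis raises various types here
            raise FormatError(f"could not load trajectory: {exc}") from exc

    offenders = sorted({r.resname for r in u.residues if rules.species_of(r.resname) is None})
    if offenders:
        raise AnnotationError(
            f"no species rule for residue names: {offenders}", offenders=offenders
        )

    atoms = []
    species_table: dict[int, str] = {}
    subunit_map: dict[str, list[int]] = {}
    for a in u.atoms:
        res = a.residue
        species = rules.species_of(res.resname)
        role = rules.role_of(species, a.name)
        try:
            element = a.element
        except Exception:
            element = None
        segid = str(getattr(a, "chainID", "") or a.segid or "A")
        mol_id = int(res.resindex)
        atoms.append(
            AtomRecord(
                atom_index=int(a.index),
                atom_name=str(a.name),
                residue_index=int(res.resid),
                residue_name=str(res.resname),
                subunit_id=segid,
                molecule_id=mol_id,
                species=species,
                role=role,
                element_class=rules.element_of(a.name, element),
            )
        )
        species_table[mol_id] = species
        if role is Role.protein:
            subunit_map.setdefault(segid, [])
            if int(res.resid) not in subunit_map[segid]:
                subunit_map[segid].append(int(res.resid))

    counts = {k: len(v) for k, v in subunit_map.items()}
    if counts and len(set(counts.values())) > 1:
        warnings.warn(f"unequal protein subunit residue counts: {counts}")
        subunit_map = {}  # symmetry averaging unavailable

    try:
        bonds = [(int(i), int(j)) for i, j in u.bonds.indices] or None
    except Exception:
        bonds = None

    top = Topology(atoms=atoms, species_table=species_table, bonds=bonds, subunit_map=subunit_map)

    n = len(u.trajectory)
    coords = np.empty((n, top.n_atoms, 3), dtype=float)
    boxes = np.empty((n, 3), dtype=float)
    times = np.empty(n, dtype=float)
    fallback_box = None
    if coordinates_path is not None:
        # multi-model PDB often carries one CRYST1 in the header only;
        # the topology file then provides the box
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u_top = mda.Universe(str(topology_path))
            fallback_box = _orthorhombic_box(u_top.dimensions)
        except Exception:
            fallback_box = None
    for i, ts in enumerate(u.trajectory):
        if ts.positions.shape[0] != top.n_atoms:
            raise FormatError(
                f"frame {i} has {ts.positions.shape[0]} atoms; topology has {top.n_atoms}"
            )
        coords[i] = ts.positions  # MDAnalysis positions are in Å
        try:
            boxes[i] = _orthorhombic_box(ts.dimensions)
        except FormatError:
            if i > 0:
                boxes[i] = boxes[i - 1]
            elif fallback_box is not None:
                boxes[i] = fallback_box
            else:
                raise
        times[i] = ts.time / 1000.0  # ps -> ns

    dt = None
    if n > 1:
        steps = np.diff(times)
        if np.all(steps <= 0) or not np.allclose(steps, steps[0], atol=1e-6 * max(steps[0], 1e-9)):
            # fall back to unit frame numbering when the reader gives no times
            times = np.arange(n, dtype=float)
            dt = 1.0
        else:
            dt = float(steps[0])
    else:
        warnings.warn("single-frame trajectory: dt undefined")

    return Trajectory(topology=top, coords=coords, boxes=boxes, times=times, dt=dt)


def _universe_from(traj: Trajectory):
    import MDAnalysis as mda

    top = traj.topology
    # one MDAnalysis residue per (subunit, residue, molecule) identity
    keys = [(a.subunit_id, a.residue_index, a.molecule_id) for a in top.atoms]
    uniq: dict[tuple, int] = {}
    resindices = np.empty(len(keys), dtype=int)
    for i, k in enumerate(keys):
        resindices[i] = uniq.setdefault(k, len(uniq))
    n_res = len(uniq)
    resnames = [""] * n_res
    resids = [0] * n_res
    segids = [""] * n_res
    for a, ri in zip(top.atoms, resindices):
        resnames[ri] = a.residue_name
        resids[ri] = a.residue_index
        segids[ri] = a.subunit_id
    seg_labels = sorted(set(segids))
    seg_of_res = np.array([seg_labels.index(s) for s in segids])
    u = mda.Universe.empty(
        n_atoms=top.n_atoms,
        n_residues=n_res,
        n_segments=len(seg_labels),
        atom_resindex=resindices,
        residue_segindex=seg_of_res,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.atom_name for a in top.atoms])
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids)
    u.add_TopologyAttr("segids", seg_labels)
    u.add_TopologyAttr("chainIDs", [a.subunit_id[:1] for a in top.atoms])
    return u


def write_trajectory(traj: Trajectory, topology_path, coordinates_path=None) -> None:
    """Write topology (GRO or PDB) and optionally coordinates (XTC/DCD/PDB)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    u = _universe_from(traj)
    dims = np.hstack([traj.boxes, np.full((traj.n_frames, 3), 90.0)])
    u.trajectory = MemoryReader(
        traj.coords.astype(np.float32),
        dimensions=dims,
        dt=(traj.dt or 1.0) * 1000.0,  # ns -> ps
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.trajectory[0]
        u.atoms.write(str(topology_path))
        if coordinates_path is not None:
            with mda.Writer(str(coordinates_path), n_atoms=traj.topology.n_atoms) as w:
                for ts in u.trajectory:
                    w.write(u.atoms)


def write_bfactor_pdb(
    traj: Trajectory,
    values: dict[tuple[str, int], float],
    path,
    frame: int = 0,
) -> None:
    """Write a PDB copy with per-residue values in the B-factor column.

    ``values`` maps (subunit_id, residue_index) to the statistic; atoms of
    unlisted residues get 0.00.  Values are clipped to the fixed-format
    two-decimal field of the PDB B-factor column.
    """
    import warnings as _w

    u = _universe_from(traj)
    u.load_new(traj.coords[frame].astype(np.float32))
    u.dimensions = np.hstack([traj.boxes[frame], [90.0, 90.0, 90.0]])
    b = np.zeros(traj.topology.n_atoms)
    for a in traj.topology.atoms:
        b[a.atom_index] = values.get((a.subunit_id, a.residue_index), 0.0)
    b = np.clip(b, -99.99, 999.99)
    u.add_TopologyAttr("tempfactors", np.round(b, 2))
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        u.atoms.write(str(path))


def protein_selection(traj: Trajectory, label: str = "protein") -> Selection:
    return Selection(label, list(traj.topology.protein_atoms()))


def headgroup_selection(traj: Trajectory, species: str | None = None, label: str = "heads") -> Selection:
    top = traj.topology
    idx = top.atom_indices(
        lambda a: a.role is Role.lipid_head and (species is None or a.species == species)
    )
    return Selection(label, list(idx))
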