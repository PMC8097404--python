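"""Hand-built miniature systems for geometry-level tests."""

from __future__ import annotations

import numpy as np

from pufasite.core import AtomRecord, ElementClass, Role, Topology, Trajectory


def build_system(protein=(), lipids=(), box=(50.0, 50.0, 50.0), n_frames=1,
                 dt=1.0, bonds=None):
    """Construct a Trajectory from explicit atom descriptions.

    ``protein``: sequence of dicts with keys sub, resid, xyz (static (3,) or
    per-frame (F, 3)), optional name/elem.  ``lipids``: sequence of dicts
    with keys species and atoms=[(name, role, elem, xyz), ...]; each lipid
    becomes one molecule.  Static coordinates are broadcast over frames.
    """
    atoms, coord_list = [], []
    subunit_map: dict[str, list[int]] = {}
    idx = 0
    n_sub_mols = 0
    sub_mol = {}
    for p in protein:
        sub = p.get("sub", "A")
        if sub not in sub_mol:
            sub_mol[sub] = n_sub_mols
            n_sub_mols += 1
    for p in protein:
        sub = p.get("sub", "A")
        atoms.append(AtomRecord(
            atom_index=idx, atom_name=p.get("name", "CA"),
            residue_index=p["resid"], residue_name=p.get("resname", "RES"),
            subunit_id=sub, molecule_id=sub_mol[sub], species="PROT",
            role=Role.protein,
            element_class=p.get("elem", ElementClass.bead),
        ))
        subunit_map.setdefault(sub, [])
        if p["resid"] not in subunit_map[sub]:
            subunit_map[sub].append(p["resid"])
        coord_list.append(p["xyz"])
        idx += 1
    for li, lip in enumerate(lipids):
        mol = n_sub_mols + li
        for name, role, elem, xyz in lip["atoms"]:
            atoms.append(AtomRecord(
                atom_index=idx, atom_name=name, residue_index=li + 1,
                residue_name=lip["species"], subunit_id="L", molecule_id=mol,
                species=lip["species"], role=role, element_class=elem,
            ))
            coord_list.append(xyz)
            idx += 1
    # symmetry averaging needs equal subunit sizes; drop the map otherwise
    if len({len(v) for v in subunit_map.values()}) > 1:
        subunit_map = {}
    top = Topology(atoms=atoms, subunit_map=subunit_map, bonds=bonds)
    coords = np.empty((n_frames, len(atoms), 3))
    for i, xyz in enumerate(coord_list):
        xyz = np.asarray(xyz, dtype=float)
        coords[:, i, :] = xyz if xyz.ndim == 2 else xyz[None, :]
    return Trajectory(
        topology=top,
        coords=coords,
        boxes=np.tile(np.asarray(box, dtype=float), (n_frames, 1)),
        times=np.arange(n_frames) * dt,
        dt=dt if n_frames > 1 else dt,
    )


def head(name, xyz):
    return (name, Role.lipid_head, ElementClass.bead, xyz)


def lipid_bead(species, xyz):
    return {"species": species, "atoms": [head("HD", xyz)]}


def aa_atom(name, role, elem, xyz):
    return (name, role, elem, xyz)
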