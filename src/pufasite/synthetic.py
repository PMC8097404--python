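"""Ground-truthed synthetic inputs: a toy channel with planted lipid-binding
kinetics, and forward-modelled electrophysiology curves.

The trajectory generator emulates the statistical structure that the
interaction analyses assume — lipids diffusing laterally in a periodic
bilayer patch around a static, four-fold symmetric "channel", binding
planted sites with Markov on/off kinetics — without any physics.  Bound
lipids are pinned at a fixed offset from their site anchor, which makes the
planted binder residues unambiguous; dwell times are geometric in frames
(mean 1/k_off exactly), the discrete-time analogue of exponential dwells.

The defaults describe a stable-binding regime: a mean planted dwell of 200
frames versus diffusive passages of a few frames through the contact
shell at the default step size, and per-frame binding probabilities small
enough that per-passage binding stays roughly linear in p_on, so a planted
3-fold species affinity ratio is expressed as a comparable occupancy
ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AtomRecord, ElementClass, Frame, Role, Topology, Trajectory
from .errors import ArgumentError, SpecError

__all__ = [
    "SiteSpec",
    "SyntheticSystemSpec",
    "GroundTruth",
    "generate_toy_channel",
    "simulate_lipid_trajectory",
    "toy_annotation_rules",
    "BoltzmannCurveSpec",
    "HillCurveSpec",
    "ExpCurveSpec",
    "generate_gv_data",
    "generate_dose_response",
    "generate_exponential_trace",
]


@dataclass
class SiteSpec:
    """A planted binding site, replicated on every subunit.

    ``anchor_residues`` are 0-based residue positions within a subunit; the
    bound lipid head is pinned ``bound_offset`` Å radially outward from the
    anchor centroid.  A free lipid whose head lies within ``capture_radius``
    (lateral) of the site binds with probability ``p_on`` per frame
    (species-specific overrides via ``p_on_by_species``) and releases with
    probability ``k_off`` per frame.
    """

    site_id: str
    anchor_residues: list[int]
    capture_radius: float = 12.0
    p_on: float = 0.03
    k_off: float = 0.005
    p_on_by_species: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.p_on <= 1) and self.p_on != 0:
            raise SpecError(f"site {self.site_id}: p_on must be in [0, 1]")
        if not (0 <= self.k_off <= 1):
            raise SpecError(f"site {self.site_id}: k_off must be in [0, 1]")
        if self.capture_radius <= 0:
            raise SpecError(f"site {self.site_id}: capture_radius must be > 0")

    def p_on_for(self, species: str) -> float:
        return self.p_on_by_species.get(species, self.p_on)


def _default_sites() -> list[SiteSpec]:
    # Two sites per subunit, well separated along the ring; the second
    # species binds 3x more weakly, emulating PUFA-vs-saturated selectivity.
    return [
        SiteSpec("site_I", [5], p_on_by_species={"STE": 0.01}),
        SiteSpec("site_II", [14], p_on_by_species={"STE": 0.01}),
    ]


@dataclass
class SyntheticSystemSpec:
    """Toy tetramer + diffusing-lipid system specification.

    The protein is a ring of one-bead pseudo-residues (``bead_spacing`` Å
    apart) at the outer-leaflet z; lipids are two-bead (head + tail)
    particles performing lateral random walks at a leaflet-fixed z.  Frame
    spacing defaults to 0.5 ns (trajectories saved every 500 ps).
    """

    n_subunits: int = 4
    residues_per_subunit: int = 20
    box: tuple[float, float, float] = (180.0, 180.0, 100.0)
    n_lipids_per_species: dict[str, int] = field(
        default_factory=lambda: {"LIN": 12, "STE": 12}
    )
    diffusion_sigma: float = 4.0  # Å per frame, lateral
    n_frames: int = 2000
    dt: float = 0.5  # ns
    sites: list[SiteSpec] = field(default_factory=_default_sites)
    seed: int = 42
    bead_spacing: float = 6.0  # Å along the ring
    leaflet_offset: float = 18.0  # |z - midplane| of each leaflet
    anchor_depth: float = 2.5  # Å below the outer head plane, site anchors
    depth_min: float = 0.5  # Å, shallowest non-anchor residue depth
    depth_max: float = 4.0  # Å, deep (crevice-wall) residue depth
    depth_profile: list[float] | None = None  # explicit per-position override
    bound_offset: float = 0.0  # Å, radial pin offset of a bound head
    tail_drop: float = 10.0  # Å, tail bead sits this much toward the midplane
    pin_first_lipid: bool = True  # one permanently bound lipid (constant binder)
    exclusive_sites: bool = False  # if True, one lipid per site copy at a time

    def __post_init__(self):
        if self.n_subunits < 1:
            raise SpecError("n_subunits must be >= 1")
        if self.residues_per_subunit < 1 or self.n_frames < 1:
            raise SpecError("counts must be positive")
        if any(n <= 0 for n in self.n_lipids_per_species.values()):
            raise SpecError("lipid counts must be positive")
        for s in self.sites:
            if s.anchor_residues and max(s.anchor_residues) >= self.residues_per_subunit:
                raise SpecError(
                    f"site {s.site_id}: anchor residue beyond residues_per_subunit"
                )

    @property
    def ring_radius(self) -> float:
        n_beads = self.n_subunits * self.residues_per_subunit
        return n_beads * self.bead_spacing / (2.0 * math.pi)

    @property
    def outer_z(self) -> float:
        return self.box[2] / 2.0 + self.leaflet_offset

    @property
    def inner_z(self) -> float:
        return self.box[2] / 2.0 - self.leaflet_offset


@dataclass
class GroundTruth:
    """What the generator planted, for use as an analysis oracle."""

    planted_site_residues: dict[str, set]  # site_id -> {(subunit_id, resid), ...}
    mean_dwell_frames: dict[str, float]  # species -> 1/k_off
    bound_fraction: dict[str, float]  # species -> realized bound lipid-frame fraction
    completed_dwells: dict[str, list[int]]  # species -> completed episode lengths
    pinned_molecule_id: int | None  # the constant binder, if planted
    site_centers: dict[str, np.ndarray]  # site_id -> (n_subunits, 2) bound xy
    leaflet_by_molecule: dict[int, str] = field(default_factory=dict)
    bound_species_frames: dict[str, dict[str, int]] = field(default_factory=dict)
    # site_id -> species -> total bound lipid-frames at that site


_SUBUNIT_LABELS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _residue_depths(spec: SyntheticSystemSpec) -> np.ndarray:
    """Per-position depth below the outer head-group plane, one subunit.

    The profile emulates the rugged topography of a real protein surface
    with binding sites in crevices: residues flanking a site anchor are
    deep (they shield the site), remote residues alternate between
    shallow and deep, and anchors sit at ``anchor_depth``.  A perfectly
    uniform surface would be both unrealistic and a degenerate input for
    quartile-based outlier calling (every residue would share one narrow
    contact distribution), so the bimodal background is the designed
    normal case.  ``depth_profile`` overrides the whole pattern.
    """
    n = spec.residues_per_subunit
    if spec.depth_profile is not None:
        if len(spec.depth_profile) != n:
            raise SpecError("depth_profile length must equal residues_per_subunit")
        depth = np.asarray(spec.depth_profile, dtype=float).copy()
    else:
        anchors = sorted({a for s in spec.sites for a in s.anchor_residues})
        depth = np.empty(n)
        for i in range(n):
            if anchors:
                d_slot = min(min(abs(i - a), n - abs(i - a)) for a in anchors)
            else:
                d_slot = 99
            if anchors and i in anchors:
                depth[i] = spec.anchor_depth
            elif d_slot == 1:
                depth[i] = spec.depth_max + 1.0  # first shell: crevice wall
            elif d_slot == 2:
                depth[i] = spec.depth_max + 0.5
            elif i % 2 == 0:
                depth[i] = spec.depth_min + 0.1 * ((i * 3) % 5)
            else:
                depth[i] = spec.depth_max + 0.2 * ((i * 3) % 5)
    for site in spec.sites:
        depth[np.asarray(site.anchor_residues, dtype=int)] = spec.anchor_depth
    return depth


def _bead_positions(spec: SyntheticSystemSpec) -> np.ndarray:
    """(n_subunits*rps, 3) ring coordinates, subunit-major order."""
    n = spec.n_subunits * spec.residues_per_subunit
    g = np.arange(n)
    theta = 2.0 * math.pi * g / n
    cx, cy = spec.box[0] / 2.0, spec.box[1] / 2.0
    r = spec.ring_radius
    depth = np.tile(_residue_depths(spec), spec.n_subunits)
    xyz = np.stack(
        [cx + r * np.cos(theta), cy + r * np.sin(theta), spec.outer_z - depth], axis=1
    )
    return xyz


def generate_toy_channel(spec: SyntheticSystemSpec) -> tuple[Topology, Frame]:
    """Build the four-fold symmetric ring of pseudo-residues.

    One bead per residue; subunit k is subunit 0 rotated by k*(360/n) about
    the box axis.  Returns the protein-only topology and a reference frame.
    """
    xyz = _bead_positions(spec)
    atoms = []
    subunit_map: dict[str, list[int]] = {}
    for k in range(spec.n_subunits):
        sub = _SUBUNIT_LABELS[k]
        subunit_map[sub] = []
        for i in range(spec.residues_per_subunit):
            gi = k * spec.residues_per_subunit + i
            atoms.append(
                AtomRecord(
                    atom_index=gi,
                    atom_name="BB",
                    residue_index=i + 1,
                    residue_name="RES",
                    subunit_id=sub,
                    molecule_id=k,
                    species="PROT",
                    role=Role.protein,
                    element_class=ElementClass.bead,
                )
            )
            subunit_map[sub].append(i + 1)
    top = Topology(atoms=atoms, subunit_map=subunit_map)
    frame = Frame(coordinates=xyz, box=np.array(spec.box), time=0.0)
    return top, frame


def _site_copy_centers(spec: SyntheticSystemSpec) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Bound-position xy for every (site, subunit) copy.

    Returns (centers (n_copies, 2), copy index -> (site_idx, subunit_idx)).
    """
    xyz = _bead_positions(spec)
    cx, cy = spec.box[0] / 2.0, spec.box[1] / 2.0
    centers = []
    labels = []
    for si, site in enumerate(spec.sites):
        for k in range(spec.n_subunits):
            gi = [k * spec.residues_per_subunit + a for a in site.anchor_residues]
            anchor = xyz[gi, :2].mean(axis=0)
            radial = anchor - np.array([cx, cy])
            radial /= np.linalg.norm(radial)
            centers.append(anchor + spec.bound_offset * radial)
            labels.append((si, k))
    return np.asarray(centers).reshape(-1, 2), labels


def _check_no_overlap(spec: SyntheticSystemSpec, centers, labels) -> None:
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            ra = spec.sites[labels[a][0]].capture_radius
            rb = spec.sites[labels[b][0]].capture_radius
            if np.linalg.norm(centers[a] - centers[b]) < ra + rb:
                raise SpecError(
                    f"capture radii of site copies {labels[a]} and {labels[b]} overlap: "
                    "site ownership would be ambiguous"
                )


def toy_annotation_rules() -> dict:
    """Annotation rules matching the toy system's residue/atom naming."""
    return {
        "species_by_resname": {"RES": "PROT", "LIN": "LIN", "STE": "STE"},
        "protein_species": ["PROT"],
        "head_patterns": {"LIN": ["HD"], "STE": ["HD"]},
        "coarse_grained": True,
    }


def planted_site_residues(spec: SyntheticSystemSpec, cutoff: float = 6.0) -> dict[str, set]:
    """Residues within ``cutoff`` of each site's bound head position.

    This is the residue set a contact analysis at that cutoff should flag,
    computed exactly from the planted geometry.
    """
    xyz = _bead_positions(spec)
    centers, labels = _site_copy_centers(spec)
    out: dict[str, set] = {s.site_id: set() for s in spec.sites}
    for c, (si, k) in zip(centers, labels):
        pos = np.array([c[0], c[1], spec.outer_z])
        d = np.linalg.norm(xyz - pos, axis=1)
        for gi in np.nonzero(d <= cutoff)[0]:
            sub = _SUBUNIT_LABELS[int(gi) // spec.residues_per_subunit]
            resid = int(gi) % spec.residues_per_subunit + 1
            out[spec.sites[si].site_id].add((sub, resid))
    return out


def simulate_lipid_trajectory(spec: SyntheticSystemSpec) -> tuple[Trajectory, GroundTruth]:
    """Simulate the diffusing-lipid toy system and return it with its truth.

    Lipids are split evenly between leaflets per species; only outer-leaflet
    lipids can bind (the planted sites sit at the outer-leaflet z).  The
    first outer-leaflet lipid of the first species is pinned to the first
    site copy for the whole run when ``pin_first_lipid`` is set, planting a
    constant binder.  Fully reproducible given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    prot_top, prot_frame = generate_toy_channel(spec)
    centers, copy_labels = _site_copy_centers(spec)
    _check_no_overlap(spec, centers, labels=copy_labels)
    n_copies = len(copy_labels)
    copy_site = np.array([si for si, _ in copy_labels])
    box_xy = np.array(spec.box[:2])

    species_list = []
    leaflet = []  # +1 outer, -1 inner
    for sp, n in spec.n_lipids_per_species.items():
        for j in range(n):
            species_list.append(sp)
            leaflet.append(1 if j < (n + 1) // 2 else -1)
    n_lip = len(species_list)
    species_arr = np.array(species_list)
    leaflet_arr = np.array(leaflet)
    z_lip = np.where(leaflet_arr > 0, spec.outer_z, spec.inner_z)
    z_tail = z_lip - leaflet_arr * spec.tail_drop

    # per-(lipid, site) binding probability table
    p_on = np.zeros((n_lip, len(spec.sites)))
    for si, site in enumerate(spec.sites):
        for li in range(n_lip):
            p_on[li, si] = site.p_on_for(species_arr[li])
    k_off_site = np.array([s.k_off for s in spec.sites])

    pos = rng.uniform(0.0, 1.0, size=(n_lip, 2)) * box_xy
    state = np.full(n_lip, -1, dtype=int)  # -1 free, else site-copy index
    bound_since = np.full(n_lip, -1, dtype=int)

    pinned_mol = None
    pinned_li = None
    if spec.pin_first_lipid and n_copies > 0:
        outer = np.nonzero(leaflet_arr > 0)[0]
        pinned_li = int(outer[0])
        state[pinned_li] = 0
        bound_since[pinned_li] = 0
        pos[pinned_li] = centers[0]

    head_xy = np.empty((spec.n_frames, n_lip, 2))
    completed: dict[str, list[int]] = {sp: [] for sp in spec.n_lipids_per_species}
    bound_frames = np.zeros(n_lip, dtype=int)
    site_species_frames = {
        s.site_id: {sp: 0 for sp in spec.n_lipids_per_species} for s in spec.sites
    }
    outer_mask = leaflet_arr > 0

    for f in range(spec.n_frames):
        # releases (pinned lipid never releases)
        bound = np.nonzero(state >= 0)[0]
        if bound.size:
            koff = k_off_site[copy_site[state[bound]]]
            rel = rng.random(bound.size) < koff
            if pinned_li is not None:
                rel[bound == pinned_li] = False
            for li in bound[rel]:
                completed[species_arr[li]].append(f - bound_since[li])
            state[bound[rel]] = -1
            bound_since[bound[rel]] = -1

        # diffusion of free lipids
        free = state < 0
        if free.any():
            pos[free] = np.mod(
                pos[free] + rng.normal(0.0, spec.diffusion_sigma, size=(free.sum(), 2)),
                box_xy,
            )

        # capture attempts (outer-leaflet free lipids only)
        cand = np.nonzero(free & outer_mask)[0]
        if cand.size and n_copies:
            d = pos[cand, None, :] - centers[None, :, :]
            d -= box_xy * np.round(d / box_xy)
            dist = np.sqrt((d * d).sum(axis=2))
            radii = np.array([spec.sites[si].capture_radius for si in copy_site])
            occupied = np.zeros(n_copies, dtype=bool)
            if spec.exclusive_sites:
                for s in state[state >= 0]:
                    occupied[s] = True
            for ci, li in enumerate(cand):
                in_range = np.nonzero(dist[ci] <= radii)[0]
                if in_range.size == 0:
                    continue
                copy = int(in_range[np.argmin(dist[ci, in_range])])
                if occupied[copy]:
                    continue
                if rng.random() < p_on[li, copy_site[copy]]:
                    state[li] = copy
                    bound_since[li] = f
                    pos[li] = centers[copy]
                    if spec.exclusive_sites:
                        occupied[copy] = True

        head_xy[f] = pos
        nb = state >= 0
        bound_frames[nb] += 1
        for li in np.nonzero(nb)[0]:
            site_id = spec.sites[copy_site[state[li]]].site_id
            site_species_frames[site_id][species_arr[li]] += 1

    # assemble topology: protein beads then head/tail beads per lipid
    atoms = list(prot_top.atoms)
    next_index = len(atoms)
    for li in range(n_lip):
        mol = spec.n_subunits + li
        for name, role in (("HD", Role.lipid_head), ("TL", Role.lipid_tail)):
            atoms.append(
                AtomRecord(
                    atom_index=next_index,
                    atom_name=name,
                    residue_index=li + 1,
                    residue_name=species_arr[li],
                    subunit_id="L",
                    molecule_id=mol,
                    species=species_arr[li],
                    role=role,
                    element_class=ElementClass.bead,
                )
            )
            next_index += 1
    top = Topology(atoms=atoms, subunit_map=dict(prot_top.subunit_map))
    if pinned_li is not None:
        pinned_mol = spec.n_subunits + pinned_li

    n_atoms = len(atoms)
    coords = np.empty((spec.n_frames, n_atoms, 3))
    coords[:, : prot_top.n_atoms, :] = prot_frame.coordinates
    head_cols = prot_top.n_atoms + 2 * np.arange(n_lip)
    coords[:, head_cols, :2] = head_xy
    coords[:, head_cols, 2] = z_lip
    coords[:, head_cols + 1, :2] = head_xy
    coords[:, head_cols + 1, 2] = z_tail

    traj = Trajectory(
        topology=top,
        coords=coords,
        boxes=np.tile(np.array(spec.box), (spec.n_frames, 1)),
        times=np.arange(spec.n_frames) * spec.dt,
        dt=spec.dt,
    )

    per_species_frames = {
        sp: float(bound_frames[species_arr == sp].sum())
        / (spec.n_frames * max((species_arr == sp).sum(), 1))
        for sp in spec.n_lipids_per_species
    }
    k_off_by_species = {
        sp: min(s.k_off for s in spec.sites) if spec.sites else math.nan
        for sp in spec.n_lipids_per_species
    }
    truth = GroundTruth(
        planted_site_residues=planted_site_residues(spec),
        mean_dwell_frames={
            sp: (1.0 / k if k > 0 else math.inf) for sp, k in k_off_by_species.items()
        },
        bound_fraction=per_species_frames,
        completed_dwells=completed,
        pinned_molecule_id=pinned_mol,
        site_centers={
            s.site_id: centers[copy_site == si] for si, s in enumerate(spec.sites)
        },
        leaflet_by_molecule={
            spec.n_subunits + li: ("outer" if leaflet_arr[li] > 0 else "inner")
            for li in range(n_lip)
        },
        bound_species_frames=site_species_frames,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# Electrophysiology forward models
# ---------------------------------------------------------------------------

@dataclass
class BoltzmannCurveSpec:
    gmin: float = 0.0
    gmax: float = 1.0
    v50: float = -20.0  # mV
    s: float = 0.1  # mV^-1
    noise_sd: float = 0.0
    voltages: np.ndarray = field(
        default_factory=lambda: np.arange(-80.0, 61.0, 10.0)
    )  # the standard -80..+60 mV activation protocol
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ArgumentError("noise_sd must be >= 0")


@dataclass
class HillCurveSpec:
    effect_max: float = -25.0  # e.g. a saturating V50 shift in mV
    l50: float = 20.0  # µM
    hill: float = 1.0  # |H|
    noise_sd: float = 0.0
    concentrations: np.ndarray = field(
        default_factory=lambda: np.array([2.0, 7.0, 20.0, 40.0, 70.0])
    )  # µM, capped at 70 µM by fatty-acid solubility
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ArgumentError("noise_sd must be >= 0")


@dataclass
class ExpCurveSpec:
    amplitude: float = 1.0
    tau: float = 0.3  # s
    offset: float = 0.0
    noise_sd: float = 0.0
    times: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 1.0, 201))
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ArgumentError("tau must be > 0")
        if self.noise_sd < 0:
            raise ArgumentError("noise_sd must be >= 0")


def boltzmann(v, gmin, gmax, v50, s):
    """G(V) = Gmin + (Gmax−Gmin) / (1 + exp[(V50−V)·s])."""
    return gmin + (gmax - gmin) / (1.0 + np.exp((v50 - np.asarray(v, float)) * s))


def hill(conc, effect_max, l50, h):
    """ΔEffect([L]) = ΔEffect_max / (1 + (L50/[L])^|H|)."""
    conc = np.asarray(conc, dtype=float)
    return effect_max / (1.0 + (l50 / conc) ** abs(h))


def generate_gv_data(spec: BoltzmannCurveSpec) -> pd.DataFrame:
    """Noisy conductance–voltage table from the Boltzmann forward model."""
    v = np.asarray(spec.voltages, dtype=float)
    if v.size == 0:
        raise ArgumentError("voltage grid is empty")
    g = boltzmann(v, spec.gmin, spec.gmax, spec.v50, spec.s)
    if spec.noise_sd > 0:
        g = g + np.random.default_rng(spec.seed).normal(0.0, spec.noise_sd, v.shape)
    return pd.DataFrame({"voltage_mV": v, "conductance": g})


def generate_dose_response(spec: HillCurveSpec) -> pd.DataFrame:
    """Noisy concentration–effect table from the Hill forward model."""
    c = np.asarray(spec.concentrations, dtype=float)
    if np.any(c <= 0):
        raise ArgumentError("concentrations must be positive")
    e = hill(c, spec.effect_max, spec.l50, spec.hill)
    if spec.noise_sd > 0:
        e = e + np.random.default_rng(spec.seed).normal(0.0, spec.noise_sd, c.shape)
    return pd.DataFrame({"concentration_uM": c, "effect": e})


def generate_exponential_trace(spec: ExpCurveSpec) -> pd.DataFrame:
    """Noisy relaxation trace I(t) = A·exp(−t/τ) + C."""
    t = np.asarray(spec.times, dtype=float)
    i = spec.amplitude * np.exp(-t / spec.tau) + spec.offset
    if spec.noise_sd > 0:
        i = i + np.random.default_rng(spec.seed).normal(0.0, spec.noise_sd, t.shape)
    return pd.DataFrame({"time_s": t, "current": i})
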