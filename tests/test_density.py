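import numpy as np
import pytest

from pufasite.core import Selection
from pufasite.density import (
    SlabProfile,
    fold_enrichment,
    lateral_rdf,
    layered_occupancy_maps,
    occupancy_grid,
    slab_contact_profile,
    threshold_contour,
    write_opendx,
)
from pufasite.errors import ArgumentError
from util import build_system, lipid_bead


def single_atom_traj(xyz, n_frames=1, box=(10, 10, 10)):
    return build_system(lipids=[lipid_bead("LIN", xyz)], n_frames=n_frames, box=box)


class TestOccupancyGrid:
    def test_stationary_atom(self):
        traj = single_atom_traj((2.5, 3.5, 4.5), n_frames=100)
        grid = occupancy_grid(traj, Selection("a", [0]), resolution=1.0)
        assert grid.occupancy[2, 3, 4] == 1.0
        assert grid.counts.sum() == 100

    def test_three_percent_occupancy(self):
        xyz = np.tile([8.5, 8.5, 8.5], (100, 1))
        xyz[:3] = [2.5, 2.5, 2.5]  # inside the target voxel in 3 of 100 frames
        traj = single_atom_traj(xyz, n_frames=100)
        grid = occupancy_grid(traj, Selection("a", [0]), resolution=1.0)
        assert grid.occupancy[2, 2, 2] == pytest.approx(0.03)

    def test_binary_per_frame_vs_weighted(self):
        # two atoms in the same voxel every frame: binary counts 1/frame
        traj = build_system(
            lipids=[lipid_bead("LIN", (2.2, 2.2, 2.2)), lipid_bead("LIN", (2.7, 2.7, 2.7))],
            n_frames=10,
        )
        sel = Selection("both", [0, 1])
        binary = occupancy_grid(traj, sel, resolution=5.0)
        weighted = occupancy_grid(traj, sel, resolution=5.0, weighted=True)
        assert binary.counts[0, 0, 0] == 10
        assert weighted.counts[0, 0, 0] == 20

    def test_matches_bruteforce_voxelization(self, rng):
        n_frames, n_atoms = 40, 6
        walks = rng.uniform(-5, 15, (n_frames, n_atoms, 3)).cumsum(axis=0) * 0.1 + 5
        lipids = [
            {"species": "LIN", "atoms": [("HD", *_role_bead(), walks[:, i, :])]}
            for i in range(n_atoms)
        ]
        traj = build_system(lipids=lipids, n_frames=n_frames, box=(10, 10, 10))
        sel = Selection("all", list(range(n_atoms)))
        grid = occupancy_grid(traj, sel, resolution=1.0)
        brute = np.zeros_like(grid.counts)
        for f in range(n_frames):
            seen = set()
            for i in range(n_atoms):
                v = tuple(
                    np.minimum(
                        (np.mod(traj.coords[f, i], 10.0) / 1.0).astype(int), 9
                    )
                )
                seen.add(v)
            for v in seen:
                brute[v] += 1
        assert np.array_equal(grid.counts, brute)

    def test_translation_invariance(self, rng):
        xyz = rng.uniform(2, 8, (20, 3))
        t1 = single_atom_traj(xyz, n_frames=20)
        shift = np.array([10.0, 20.0, 30.0])
        t2 = build_system(
            lipids=[lipid_bead("LIN", xyz + shift)], n_frames=20, box=(40, 40, 40)
        )
        g1 = occupancy_grid(t1, Selection("a", [0]), 1.0)
        g2 = occupancy_grid(t2, Selection("a", [0]), 1.0)
        # same voxel pattern, offset by the (co-translated) origin shift
        assert g1.counts.sum() == g2.counts.sum()
        assert sorted(g1.counts[g1.counts > 0].tolist()) == sorted(
            g2.counts[g2.counts > 0].tolist()
        )

    def test_bad_resolution_rejected(self):
        traj = single_atom_traj((1, 1, 1))
        with pytest.raises(ArgumentError):
            occupancy_grid(traj, Selection("a", [0]), resolution=0.0)


class TestThresholdContour:
    def test_mask_values(self):
        traj = single_atom_traj((2.5, 2.5, 2.5), n_frames=100)
        grid = occupancy_grid(traj, Selection("a", [0]), 1.0)
        grid.counts[0, 0, 0] = 16
        grid.counts[1, 1, 1] = 10
        m = threshold_contour(grid, 0.15)
        assert m[2, 2, 2] and m[0, 0, 0] and not m[1, 1, 1]

    def test_nesting_monotone(self, fixture_system):
        _, traj, _ = fixture_system
        from pufasite.io import headgroup_selection

        grid = occupancy_grid(traj, headgroup_selection(traj, "LIN"), 2.0)
        prev = None
        for thr in (0.10, 0.15, 0.20, 0.30):
            mask = threshold_contour(grid, thr)
            if prev is not None:
                assert not (mask & ~prev).any()
            prev = mask

    def test_invalid_threshold(self):
        traj = single_atom_traj((1, 1, 1))
        grid = occupancy_grid(traj, Selection("a", [0]), 1.0)
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ArgumentError):
                threshold_contour(grid, bad)


class TestLayeredMaps:
    def test_layers_partition_the_grid(self, rng):
        xyz = rng.uniform(0, 10, (30, 3))
        traj = single_atom_traj(xyz, n_frames=30)
        sel = Selection("a", [0])
        full = occupancy_grid(traj, sel, resolution=1.0)
        layers = [(float(z), float(z + 1)) for z in range(10)]
        maps = layered_occupancy_maps(traj, sel, layers, resolution=1.0)
        for k, m in enumerate(maps):
            assert np.array_equal(m.counts[:, :, 0], full.counts[:, :, k])

    def test_confined_heads_leave_other_layers_empty(self):
        traj = single_atom_traj((5, 5, 2.5), n_frames=5)
        maps = layered_occupancy_maps(
            traj, Selection("a", [0]), [(0.0, 5.0), (5.0, 10.0)]
        )
        assert maps[0].counts.sum() == 5
        assert maps[1].counts.sum() == 0

    def test_empty_layer_list_rejected(self):
        traj = single_atom_traj((1, 1, 1))
        with pytest.raises(ArgumentError):
            layered_occupancy_maps(traj, Selection("a", [0]), [])


class TestSlabProfile:
    def test_fixed_contact_in_one_bin(self):
        traj = build_system(
            protein=[{"sub": "A", "resid": 1, "xyz": (5, 5, 5.1)}],
            lipids=[lipid_bead("LIN", (5, 7, 5.1))],  # 2.0 A from reference
            n_frames=100,
            box=(10, 10, 10),
        )
        prof = slab_contact_profile(
            traj, Selection("h", [1]), [("A", 1)], shell_cutoff=3.0, slab=0.5
        )[0]
        k = int(5.1 / 0.5)
        assert prof.counts[k] == 100
        assert prof.counts.sum() == 100

    def test_outside_shell_counts_nothing(self):
        traj = build_system(
            protein=[{"sub": "A", "resid": 1, "xyz": (5, 5, 5)}],
            lipids=[lipid_bead("LIN", (5, 8.2, 5))],
            n_frames=10,
            box=(10, 10, 10),
        )
        prof = slab_contact_profile(
            traj, Selection("h", [1]), [("A", 1)], shell_cutoff=3.0
        )[0]
        assert prof.counts.sum() == 0

    def test_total_equals_unbinned_event_count(self, rng):
        from pufasite.core import minimum_image_distance

        n_frames = 25
        heads = rng.uniform(0, 20, (n_frames, 3, 3))
        lipids = [
            {"species": "LIN", "atoms": [("HD", *_role_bead(), heads[:, i, :])]}
            for i in range(3)
        ]
        traj = build_system(
            protein=[{"sub": "A", "resid": 1, "xyz": (10, 10, 10)}],
            lipids=lipids,
            n_frames=n_frames,
            box=(20, 20, 20),
        )
        sel = Selection("h", [1, 2, 3])
        prof = slab_contact_profile(traj, sel, [("A", 1)], shell_cutoff=5.0)[0]
        brute = 0
        for f in range(n_frames):
            for i in (1, 2, 3):
                d = minimum_image_distance(traj.coords[f, i], traj.coords[f, 0], traj.boxes[f])
                brute += d <= 5.0
        assert prof.counts.sum() == brute

    def test_interval_splitting(self):
        traj = build_system(
            protein=[{"sub": "A", "resid": 1, "xyz": (5, 5, 5)}],
            lipids=[lipid_bead("LIN", (5, 6, 5))],
            n_frames=10,
            dt=1.0,
            box=(10, 10, 10),
        )
        profs = slab_contact_profile(
            traj, Selection("h", [1]), [("A", 1)], shell_cutoff=3.0, interval=5.0
        )
        assert len(profs) == 2
        assert all(p.counts.sum() == 5 for p in profs)


class TestFoldEnrichment:
    def _prof(self, counts):
        edges = np.arange(0, len(counts) * 0.5 + 0.25, 0.5)
        return SlabProfile(edges=edges, counts=np.array(counts), interval_label="t")

    def test_simple_ratio(self):
        fc = fold_enrichment(self._prof([10, 20]), self._prof([5, 10]))
        assert fc.ratio.tolist() == [2.0, 2.0]

    def test_numerator_only_flagged(self):
        fc = fold_enrichment(self._prof([4]), self._prof([0]))
        assert np.isnan(fc.ratio[0])
        assert fc.numerator_only[0]

    def test_identity(self):
        fc = fold_enrichment(self._prof([3, 0, 7]), self._prof([3, 0, 7]))
        assert fc.ratio[0] == 1.0 and fc.ratio[2] == 1.0
        assert fc.empty[1]

    def test_binning_mismatch_rejected(self):
        with pytest.raises(ArgumentError):
            fold_enrichment(self._prof([1, 2]), self._prof([1, 2, 3]))


class TestLateralRDF:
    def test_uniform_points_give_unity(self):
        # 10^6 (frame, atom) samples drawn uniformly in the box
        rng = np.random.default_rng(0)
        n_frames, n_atoms = 2000, 500
        xyz = rng.uniform(0, 60, (n_frames, n_atoms, 3))
        lipids = [
            {"species": "LIN", "atoms": [("HD", *_role_bead(), xyz[:, i, :])]}
            for i in range(n_atoms)
        ]
        traj = build_system(
            protein=[{"sub": "A", "resid": 1, "xyz": (30, 30, 30)}],
            lipids=lipids,
            n_frames=n_frames,
            box=(60, 60, 60),
        )
        sel = Selection("h", list(range(1, n_atoms + 1)))
        # equal-area annuli: every bin collects >60k of the 10^6 samples
        edges = np.sqrt(np.linspace(10.0**2, 26.0**2, 9))
        rdf = lateral_rdf(traj, sel, Selection("p", [0]), edges)
        assert np.all(np.abs(rdf.g - 1.0) <= 0.02)

    def test_ring_gives_single_peak(self):
        theta = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        xyz = np.stack([30 + 15.5 * np.cos(theta), 30 + 15.5 * np.sin(theta), np.full(40, 30.0)], axis=1)
        lipids = [{"species": "LIN", "atoms": [("HD", *_role_bead(), xyz[i])]} for i in range(40)]
        traj = build_system(
            protein=[{"sub": "A", "resid": 1, "xyz": (30, 30, 30)}],
            lipids=lipids,
            box=(60, 60, 60),
        )
        sel = Selection("h", list(range(1, 41)))
        rdf = lateral_rdf(traj, sel, Selection("p", [0]), np.arange(0.0, 26.0, 1.0))
        assert rdf.counts[15] == 40
        assert rdf.counts.sum() == 40

    def test_intensive_under_particle_doubling(self):
        rng = np.random.default_rng(1)
        gs = []
        for n_atoms in (400, 800):
            xyz = rng.uniform(0, 60, (500, n_atoms, 3))
            lipids = [
                {"species": "LIN", "atoms": [("HD", *_role_bead(), xyz[:, i, :])]}
                for i in range(n_atoms)
            ]
            traj = build_system(
                protein=[{"sub": "A", "resid": 1, "xyz": (30, 30, 30)}],
                lipids=lipids,
                n_frames=500,
                box=(60, 60, 60),
            )
            sel = Selection("h", list(range(1, n_atoms + 1)))
            gs.append(lateral_rdf(traj, sel, Selection("p", [0]), np.arange(5.0, 26.0, 2.0)).g)
        assert np.allclose(gs[0], gs[1], atol=0.05)

    def test_overlong_bins_truncated_with_warning(self):
        traj = single_atom_traj((5, 5, 5), box=(20, 20, 20))
        with pytest.warns(UserWarning, match="truncated"):
            lateral_rdf(
                traj, Selection("h", [0]), Selection("p", [0]), np.arange(0, 50.0, 1.0)
            )


class TestOpenDX:
    def test_roundtrippable_header(self, tmp_path):
        traj = single_atom_traj((2.5, 2.5, 2.5), n_frames=4)
        grid = occupancy_grid(traj, Selection("a", [0]), 1.0)
        path = tmp_path / "grid.dx"
        write_opendx(grid, path)
        text = path.read_text()
        assert "gridpositions counts 10 10 10" in text
        assert "1.000000 0 0" in text
        values = []
        for line in text.splitlines():
            if line and line[0].isdigit() or line.startswith("0"):
                try:
                    values.extend(float(v) for v in line.split())
                except ValueError:
                    pass
        assert pytest.approx(sum(values)) == grid.occupancy.sum()


def _role_bead():
    from pufasite.core import ElementClass, Role

    return (Role.lipid_head, ElementClass.bead)
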