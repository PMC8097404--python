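import numpy as np
import pytest

from pufasite.contacts import (
    ContactTensor,
    classify_contact_residues,
    compute_contact_tensor,
    count_lipids_near_protein,
    longest_run_lengths,
    residue_longest_lifetime,
    residue_stats,
    residue_total_interaction_time,
    symmetry_average,
)
from pufasite.core import Role, minimum_image_distance
from pufasite.errors import ArgumentError, InsufficientDataError, StructureError
from util import build_system, lipid_bead


def make_tensor(presence, dt=1.0, mode="whole_lipid", cutoff=6.0):
    presence = np.asarray(presence, dtype=bool)
    F, L, R = presence.shape
    return ContactTensor(
        presence=presence,
        lipid_ids=list(range(100, 100 + L)),
        residue_keys=[("A", i + 1) for i in range(R)],
        dt=dt,
        mode=mode,
        cutoff=cutoff,
    )


def brute_quantile(values, q):
    """Sort-based linear-interpolation quantile, written independently."""
    v = sorted(values)
    pos = q * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return v[lo] + (pos - lo) * (v[hi] - v[lo])


class TestContactTensor:
    @pytest.mark.parametrize("d,expected", [(5.9, True), (6.1, False)])
    def test_cutoff_boundary(self, d, expected):
        traj = build_system(
            protein=[{"sub": "A", "resid": 1, "xyz": (10, 10, 10)}],
            lipids=[lipid_bead("LIN", (10 + d, 10, 10))],
            n_frames=2,
        )
        tensor = compute_contact_tensor(traj, "LIN", cutoff=6.0)
        assert bool(tensor.presence[0, 0, 0]) is expected

    def test_periodic_image_contact(self):
        traj = build_system(
            protein=[{"sub": "A", "resid": 1, "xyz": (1, 10, 10)}],
            lipids=[lipid_bead("LIN", (48, 10, 10))],
            box=(50, 50, 50),
            n_frames=2,
        )
        tensor = compute_contact_tensor(traj, "LIN", cutoff=6.0)
        assert tensor.presence.all()

    def test_unknown_species_rejected(self):
        traj = build_system(
            protein=[{"sub": "A", "resid": 1, "xyz": (0, 0, 0)}],
            lipids=[lipid_bead("LIN", (1, 1, 1))],
        )
        with pytest.raises(ArgumentError, match="POPC"):
            compute_contact_tensor(traj, "POPC")

    def test_matches_bruteforce_on_random_frames(self, rng):
        # multi-atom lipids and residues, random coordinates, PBC wrap
        n_frames = 60
        prot = [
            {"sub": "A", "resid": r + 1, "xyz": rng.uniform(0, 30, (n_frames, 3))}
            for r in range(4)
        ]
        lipids = []
        for _ in range(3):
            lipids.append(
                {
                    "species": "LIN",
                    "atoms": [
                        ("HD", Role.lipid_head, None, rng.uniform(-10, 40, (n_frames, 3))),
                        ("TL", Role.lipid_tail, None, rng.uniform(-10, 40, (n_frames, 3))),
                    ],
                }
            )
        from pufasite.core import ElementClass

        lipids = [
            {
                "species": l["species"],
                "atoms": [(n, r, ElementClass.bead, x) for (n, r, _, x) in l["atoms"]],
            }
            for l in lipids
        ]
        traj = build_system(protein=prot, lipids=lipids, box=(30, 30, 30), n_frames=n_frames)
        for mode in ("whole_lipid", "headgroup_only"):
            tensor = compute_contact_tensor(traj, "LIN", cutoff=6.0, mode=mode)
            top = traj.topology
            for f in range(n_frames):
                for li, mol in enumerate(tensor.lipid_ids):
                    latoms = top.molecule_atoms(mol, head_only=(mode == "headgroup_only"))
                    for ri, key in enumerate(tensor.residue_keys):
                        ratoms = top.residue_atom_indices(key)
                        d = min(
                            minimum_image_distance(
                                traj.coords[f, i], traj.coords[f, j], traj.boxes[f]
                            )
                            for i in latoms
                            for j in ratoms
                        )
                        assert tensor.presence[f, li, ri] == (d <= 6.0), (f, li, ri, d)

    def test_headgroup_mode_implies_whole_lipid_mode(self, fixture_system):
        _, traj, _ = fixture_system
        whole = compute_contact_tensor(traj, "LIN", cutoff=6.0, mode="whole_lipid")
        head = compute_contact_tensor(traj, "LIN", cutoff=6.0, mode="headgroup_only")
        assert not (head.presence & ~whole.presence).any()


class TestRunLengthStatistics:
    def test_total_time_union_example(self):
        # lipid A [1,1,0,1], lipid B [0,1,1,0]: 4 frames with any contact
        presence = np.zeros((4, 2, 1), dtype=bool)
        presence[:, 0, 0] = [1, 1, 0, 1]
        presence[:, 1, 0] = [0, 1, 1, 0]
        t = residue_total_interaction_time(make_tensor(presence, dt=0.5))
        assert t[0] == pytest.approx(2.0)

    def test_longest_lifetime_example(self):
        presence = np.zeros((4, 2, 1), dtype=bool)
        presence[:, 0, 0] = [1, 1, 0, 1]
        presence[:, 1, 0] = [0, 1, 1, 0]
        l = residue_longest_lifetime(make_tensor(presence, dt=0.5))
        assert l[0] == pytest.approx(1.0)

    def test_no_contacts(self):
        t = make_tensor(np.zeros((5, 2, 3), dtype=bool))
        assert residue_total_interaction_time(t).tolist() == [0, 0, 0]
        assert residue_longest_lifetime(t).tolist() == [0, 0, 0]

    def test_full_duration_contact(self):
        presence = np.ones((100, 1, 1), dtype=bool)
        t = make_tensor(presence, dt=0.5)
        assert residue_longest_lifetime(t)[0] == pytest.approx(t.duration)

    def test_sum_variant_counts_multiplicity(self):
        presence = np.ones((4, 2, 1), dtype=bool)
        t = make_tensor(presence)
        assert residue_total_interaction_time(t, union=True)[0] == 4
        assert residue_total_interaction_time(t, union=False)[0] == 8

    def test_matches_bruteforce_on_random_tensors(self, rng):
        def brute_longest(seq):
            best = cur = 0
            for v in seq:
                cur = cur + 1 if v else 0
                best = max(best, cur)
            return best

        for _ in range(50):
            presence = rng.random((50, 3, 4)) < rng.uniform(0.1, 0.9)
            t = make_tensor(presence, dt=0.25)
            total = residue_total_interaction_time(t)
            longest = residue_longest_lifetime(t)
            for ri in range(4):
                union = presence[:, :, ri].any(axis=1)
                assert total[ri] == pytest.approx(union.sum() * 0.25)
                expect = max(brute_longest(presence[:, li, ri]) for li in range(3))
                assert longest[ri] == pytest.approx(expect * 0.25)

    def test_invariant_longest_le_total_le_duration(self, rng):
        for _ in range(20):
            presence = rng.random((40, 4, 6)) < 0.4
            t = make_tensor(presence)
            s = residue_stats(t)
            assert (s.longest_lifetime <= s.total_time + 1e-12).all()
            assert (s.total_time <= s.duration + 1e-12).all()

    def test_union_subadditivity(self, rng):
        presence = rng.random((80, 5, 3)) < 0.3
        t = make_tensor(presence)
        union = residue_total_interaction_time(t, union=True)
        summed = residue_total_interaction_time(t, union=False)
        assert (union <= summed + 1e-12).all()

    def test_coarser_sampling_preserves_episode_times(self):
        # one 40-frame episode: halving the rate loses < 1 frame-equivalent
        presence = np.zeros((100, 1, 1), dtype=bool)
        presence[10:50, 0, 0] = True
        fine = make_tensor(presence, dt=1.0)
        coarse = make_tensor(presence[::2], dt=2.0)
        tf = residue_total_interaction_time(fine)[0]
        tc = residue_total_interaction_time(coarse)[0]
        assert abs(tf - tc) < 1.0 * 2  # one coarse frame-equivalent


class TestLipidCounting:
    def test_counts_distinct_molecules(self):
        lipids = [lipid_bead("LIN", (10 + d, 10, 10)) for d in (1, 3, 20, 22, 24)]
        traj = build_system(
            protein=[{"sub": "A", "resid": 1, "xyz": (10, 10, 10)}],
            lipids=lipids,
            n_frames=3,
        )
        out = count_lipids_near_protein(traj, "LIN", cutoff=6.0)
        assert (out["count"] == 2).all()

    def test_running_average_of_constant_is_constant(self):
        lipids = [lipid_bead("LIN", (12, 10, 10))]
        traj = build_system(
            protein=[{"sub": "A", "resid": 1, "xyz": (10, 10, 10)}],
            lipids=lipids,
            n_frames=20,
        )
        out = count_lipids_near_protein(traj, "LIN", cutoff=6.0, window=5.0)
        assert np.allclose(out["running_average"], 1.0)

    def test_window_below_dt_rejected(self):
        traj = build_system(
            protein=[{"sub": "A", "resid": 1, "xyz": (10, 10, 10)}],
            lipids=[lipid_bead("LIN", (12, 10, 10))],
            n_frames=5,
            dt=1.0,
        )
        with pytest.raises(ArgumentError):
            count_lipids_near_protein(traj, "LIN", window=0.5)

    def test_matches_per_frame_recount_on_fixture(self, fixture_system):
        _, traj, _ = fixture_system
        out = count_lipids_near_protein(traj, "LIN", cutoff=6.0)
        top = traj.topology
        prot = top.protein_atoms()
        for f in (0, 57, 123):
            n = 0
            for mol in top.lipid_molecules("LIN"):
                heads = top.molecule_atoms(mol, head_only=True)
                d = min(
                    minimum_image_distance(traj.coords[f, i], traj.coords[f, j], traj.boxes[f])
                    for i in heads
                    for j in prot
                )
                n += d <= 6.0
            assert out["count"].iloc[f] == n


class TestSymmetryAveraging:
    def _stats(self, per_subunit):
        keys, total = [], []
        for sub, vals in per_subunit.items():
            for i, v in enumerate(vals):
                keys.append((sub, i + 1))
                total.append(v)
        from pufasite.contacts import ResidueStats

        arr = np.array(total, dtype=float)
        return ResidueStats(
            residue_keys=keys, total_time=arr, longest_lifetime=arr / 2,
            dt=1.0, duration=100.0,
        )

    def test_identical_profiles_average_to_themselves(self):
        s = self._stats({k: [1.0, 2.0, 3.0] for k in "ABCD"})
        avg = symmetry_average(s, {k: [1, 2, 3] for k in "ABCD"})
        assert avg.total_time.tolist() == [1.0, 2.0, 3.0]
        assert avg.averaged

    def test_single_nonzero_subunit(self):
        s = self._stats({"A": [0.0], "B": [0.0], "C": [0.0], "D": [4.0]})
        avg = symmetry_average(s, {k: [1] for k in "ABCD"})
        assert avg.total_time[0] == pytest.approx(1.0)

    def test_subunit_order_irrelevant(self):
        s = self._stats({"A": [1.0, 5.0], "B": [3.0, 7.0]})
        m1 = {"A": [1, 2], "B": [1, 2]}
        m2 = {"B": [1, 2], "A": [1, 2]}
        a1 = symmetry_average(s, m1)
        a2 = symmetry_average(s, m2)
        assert np.allclose(a1.total_time, a2.total_time)

    def test_unequal_subunits_rejected(self):
        s = self._stats({"A": [1.0, 2.0], "B": [3.0]})
        with pytest.raises(StructureError):
            symmetry_average(s, {"A": [1, 2], "B": [1]})


class TestClassification:
    def _stats(self, values):
        from pufasite.contacts import ResidueStats

        arr = np.array(values, dtype=float)
        return ResidueStats(
            residue_keys=[("A", i + 1) for i in range(len(values))],
            total_time=arr, longest_lifetime=arr, dt=1.0, duration=1e6,
        )

    def test_single_outlier_with_zero_iqr(self):
        cls = classify_contact_residues(self._stats([2, 2, 2, 2, 2, 2, 2, 50]))
        assert cls.high_contact == {("A", 8)}
        assert cls.fence_values["total_time"]["Q3"] == pytest.approx(2.0)
        assert cls.fence_values["total_time"]["IQR"] == pytest.approx(0.0)

    def test_all_equal_gives_empty_set(self):
        cls = classify_contact_residues(self._stats([3.0] * 6))
        assert cls.high_contact == set()
        assert cls.stable_contact == set()

    def test_tie_at_fence_excluded(self):
        # fence = Q3 + 1.5*IQR; a value exactly at the fence must not be flagged
        vals = [0, 0, 0, 0]
        cls = classify_contact_residues(self._stats(vals))
        assert cls.high_contact == set()

    def test_too_few_residues_rejected(self):
        with pytest.raises(InsufficientDataError):
            classify_contact_residues(self._stats([1, 2, 3]))

    def test_matches_sort_based_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            vals = rng.exponential(10, n).round(3)
            cls = classify_contact_residues(self._stats(vals))
            q3 = brute_quantile(vals, 0.75)
            q1 = brute_quantile(vals, 0.25)
            fence = q3 + 1.5 * (q3 - q1)
            expect = {("A", i + 1) for i, v in enumerate(vals) if v > fence}
            assert cls.high_contact == expect
            assert cls.fence_values["total_time"]["fence"] == pytest.approx(fence)
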