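"""Trajectory statistics: RMSD, Rg, PCA, clustering, hydrogen bonds,
center distances, native contacts and contact maps."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import unbindkit as uk
from unbindkit import synthetic as syn

from oracles import bestfit_rmsd_scipy, brute_force_qb


def _random_rigid(seed):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.uniform(-10, 10, size=3)
    return rot, shift


def _line_trajectory(n_atoms=5, n_frames=4, seed=0, noise=0.5):
    rng = np.random.default_rng(seed)
    base = np.zeros((n_atoms, 3))
    base[:, 0] = 3.0 * np.arange(n_atoms)
    frames = base[None] + rng.normal(0, noise, size=(n_frames, n_atoms, 3))
    top = uk.Topology(
        atom_names=[f"C{i + 1}" for i in range(n_atoms)],
        elements=["C"] * n_atoms, res_ids=list(range(1, n_atoms + 1)),
        res_names=["BDS"] * n_atoms, chain_ids=["A"] * n_atoms,
        masses=[12.011] * n_atoms)
    return uk.Trajectory(top, frames)


class TestRMSD:
    def test_identical_frame_zero(self):
        traj = _line_trajectory()
        sel = traj.topology.select_all()
        assert uk.superpose_rmsd(traj, sel)[0] == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_removed_by_fit(self):
        traj = _line_trajectory()
        rot, shift = _random_rigid(1)
        moved = uk.Trajectory(traj.topology,
                              np.array([traj.coords[0] @ rot.T + shift]))
        sel = traj.topology.select_all()
        rmsd = uk.superpose_rmsd(moved, sel, reference=traj.coords[0])
        assert rmsd[0] < 1e-10

    def test_partial_fit_matches_independent_kabsch(self):
        """Fit on 3 atoms, measure all 4, compare with an independent
        rotational-alignment evaluation."""
        ref = np.array([[0.0, 0, 0], [2, 0, 0], [0, 2, 0], [1, 1, 2]])
        frame = ref.copy()
        frame[3] += [0.0, 0.0, 1.0]          # one atom displaced
        rot, shift = _random_rigid(2)
        frame = frame @ rot.T + shift
        top = _line_trajectory(4).topology
        traj = uk.Trajectory(top, frame[None])
        fit = uk.Selection(top, [0, 1, 2])
        measure = top.select_all()
        ours = uk.superpose_rmsd(traj, fit, measure, reference=ref)[0]
        # oracle: align the fit atoms with scipy, apply to all, measure
        a, b = frame[:3], ref[:3]
        r, _ = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        fitted = r.apply(frame - a.mean(0)) + b.mean(0)
        oracle = np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1)))
        assert np.isclose(ours, oracle, atol=1e-10)

    def test_pairwise_bestfit_matches_scipy(self):
        traj = _line_trajectory(n_atoms=6, n_frames=5, seed=3)
        mat = uk.pairwise_bestfit_rmsd(traj.coords)
        for i, j in itertools.combinations(range(5), 2):
            oracle = bestfit_rmsd_scipy(traj.coords[i], traj.coords[j])
            assert np.isclose(mat[i, j], oracle, atol=1e-8)

    def test_too_few_fit_atoms_rejected(self):
        traj = _line_trajectory()
        with pytest.raises(ValueError, match="3 atoms"):
            uk.superpose_rmsd(traj, uk.Selection(traj.topology, [0, 1]))


class TestRg:
    def test_coincident_atoms_zero(self):
        traj = _line_trajectory()
        traj.coords[:] = 1.0
        assert np.all(uk.radius_of_gyration(
            traj, traj.topology.select_all()) == 0.0)

    def test_two_equal_masses_two_angstroms_apart(self):
        top = _line_trajectory(2).topology
        coords = np.array([[[0.0, 0, 0], [2.0, 0, 0]]])
        traj = uk.Trajectory(top, coords)
        assert np.isclose(uk.radius_of_gyration(
            traj, top.select_all())[0], 1.0)

    def test_translation_invariant(self):
        traj = _line_trajectory(seed=5)
        sel = traj.topology.select_all()
        shifted = uk.Trajectory(traj.topology, traj.coords + 100.0)
        assert np.allclose(uk.radius_of_gyration(traj, sel),
                           uk.radius_of_gyration(shifted, sel))


class TestPCA:
    def test_identical_frames_all_zero(self):
        traj = _line_trajectory(noise=0.0)
        result = uk.pca(traj, traj.topology.select_all())
        assert np.all(result.eigenvalues == 0.0)

    def test_trace_conservation(self):
        traj = _line_trajectory(n_frames=40, seed=8)
        coords = traj.coords[:, :, :].reshape(40, -1)
        result = uk.pca(traj, traj.topology.select_all(), superpose=False)
        cov = np.cov(coords.T, ddof=1)
        assert np.isclose(result.eigenvalues.sum(), np.trace(cov),
                          rtol=1e-10)

    def test_known_covariance_recovered(self):
        cov = np.zeros((12, 12))
        cov[0, 0], cov[1, 1] = 4.0, 1.0
        traj = syn.generate_gaussian_trajectory(4, cov, 5000, seed=13)
        result = uk.pca(traj, traj.topology.select_all(), superpose=False)
        for target, value in zip((4.0, 1.0), result.eigenvalues[:2]):
            se = target * np.sqrt(2.0 / 5000)
            assert abs(value - target) < 3 * se

    def test_single_frame_rejected(self):
        traj = _line_trajectory(n_frames=1)
        with pytest.raises(ValueError, match="2 frames"):
            uk.pca(traj, traj.topology.select_all())


class TestClustering:
    def test_planted_conformers_recovered_exactly(self):
        traj, labels = syn.generate_conformer_trajectory(8, 3, 90, seed=17)
        result = uk.cluster_frames(traj, traj.topology.select_all(),
                                   n_clusters=3, sieve=1)
        best = max(
            np.mean(np.array([p[x] for x in result.labels]) == labels)
            for p in itertools.permutations(range(3)))
        assert best == 1.0
        assert np.isclose(result.populations.sum(), 1.0)

    def test_sieve_agrees_with_full_clustering(self):
        traj, _ = syn.generate_conformer_trajectory(8, 3, 200, seed=19)
        sel = traj.topology.select_all()
        full = uk.cluster_frames(traj, sel, n_clusters=3, sieve=1)
        sieved = uk.cluster_frames(traj, sel, n_clusters=3, sieve=10)
        agreement = max(
            np.mean(np.array([p[x] for x in sieved.labels]) == full.labels)
            for p in itertools.permutations(range(3)))
        assert agreement >= 0.95

    def test_sieve_counts(self):
        traj, _ = syn.generate_conformer_trajectory(4, 2, 4000, seed=23)
        result = uk.cluster_frames(traj, traj.topology.select_all(),
                                   n_clusters=2, sieve=10)
        assert len(result.sieved_frames) == 400

    def test_identical_frames_single_cluster(self):
        traj = _line_trajectory(n_frames=6, noise=0.0)
        result = uk.cluster_frames(traj, traj.topology.select_all(),
                                   distance_threshold=0.5, sieve=1)
        assert result.n_clusters == 1
        assert result.populations[0] == 1.0

    def test_too_many_clusters_rejected(self):
        traj = _line_trajectory(n_frames=6)
        with pytest.raises(ValueError, match="sieved"):
            uk.cluster_frames(traj, traj.topology.select_all(),
                              n_clusters=4, sieve=2)


class TestHBonds:
    def test_ideal_geometry_full_occupancy(self):
        traj = syn.generate_hbond_trajectory([True] * 5, distance_on=2.8)
        table, _ = uk.hbond_occupancy(
            traj, traj.topology.select(chain="A"),
            traj.topology.select(chain="B"))
        assert table["occupancy"].tolist() == [1.0]

    def test_long_distance_zero_occupancy(self):
        traj = syn.generate_hbond_trajectory([True] * 5, distance_on=3.6)
        table, _ = uk.hbond_occupancy(
            traj, traj.topology.select(chain="A"),
            traj.topology.select(chain="B"))
        assert table["occupancy"].tolist() == [0.0]

    def test_seven_of_ten_frames(self):
        traj = syn.generate_hbond_trajectory([True] * 7 + [False] * 3)
        table, timeline = uk.hbond_occupancy(
            traj, traj.topology.select(chain="A"),
            traj.topology.select(chain="B"))
        assert table["occupancy"].tolist() == [0.7]
        assert timeline[0].tolist() == [True] * 7 + [False] * 3

    def test_boundary_distance_is_strict(self):
        """An acceptor at exactly the 3.5 Å cutoff does not count."""
        top = syn.generate_hbond_trajectory([True]).topology
        frame = np.array([[0.0, 0.0, 0.0],       # donor N
                          [1.0, 0.0, 0.0],       # its hydrogen
                          [3.5, 0.0, 0.0]])      # acceptor, linear geometry
        traj = uk.Trajectory(top, frame[None])
        table, _ = uk.hbond_occupancy(traj, top.select(chain="A"),
                                      top.select(chain="B"))
        assert table["occupancy"].tolist() == [0.0]
        # one ulp inside the cutoff counts
        frame[2, 0] = np.nextafter(3.5, 0.0)
        table, _ = uk.hbond_occupancy(uk.Trajectory(top, frame[None]),
                                      top.select(chain="A"),
                                      top.select(chain="B"))
        assert table["occupancy"].tolist() == [1.0]

    def test_boundary_angle_is_strict(self):
        """An angle exactly at the cutoff does not count; strictly above
        does."""
        traj = syn.generate_hbond_trajectory([True], distance_on=2.9,
                                             angle_on=120.0)
        coords = traj.coords[0]
        v1 = coords[2] - coords[1]
        v2 = coords[0] - coords[1]
        realized = float(np.degrees(np.arccos(
            np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))))
        groups = (traj.topology.select(chain="A"),
                  traj.topology.select(chain="B"))
        at_boundary = uk.HBondSpec(angle_cutoff=realized)
        below = uk.HBondSpec(angle_cutoff=np.nextafter(realized, 0.0))
        assert uk.hbond_occupancy(traj, *groups, at_boundary)[0][
            "occupancy"].tolist() == [0.0]
        assert uk.hbond_occupancy(traj, *groups, below)[0][
            "occupancy"].tolist() == [1.0]

    def test_donor_without_hydrogen_warned_and_skipped(self):
        top = uk.Topology(
            atom_names=["N", "O"], elements=["N", "O"], res_ids=[1, 1],
            res_names=["DON", "ACC"], chain_ids=["A", "B"],
            masses=[14.0, 16.0])
        traj = uk.Trajectory(top, np.zeros((1, 2, 3)))
        with pytest.warns(UserWarning, match="no bonded hydrogen"):
            table, _ = uk.hbond_occupancy(traj, top.select(chain="A"),
                                          top.select(chain="B"))
        assert len(table) == 0

    def test_conjunction_bounded_by_individual_criteria(self):
        """Occupancy of (distance AND angle) never exceeds either criterion
        alone."""
        rng = np.random.default_rng(29)
        formed = rng.random(20) < 0.5
        traj = syn.generate_hbond_trajectory(formed.tolist())
        loose_d = uk.HBondSpec(distance_cutoff=100.0)
        loose_a = uk.HBondSpec(angle_cutoff=1.0)
        strict = uk.HBondSpec()
        groups = (traj.topology.select(chain="A"),
                  traj.topology.select(chain="B"))
        occ = {name: uk.hbond_occupancy(traj, *groups, spec)[0]
               ["occupancy"].iloc[0]
               for name, spec in (("strict", strict), ("d_only", loose_a),
                                  ("a_only", loose_d))}
        assert occ["strict"] <= min(occ["d_only"], occ["a_only"])
        assert 0.0 <= occ["strict"] <= 1.0


class TestCenterDistance:
    def test_identical_groups_zero(self):
        traj = _line_trajectory()
        sel = traj.topology.select_all()
        assert np.all(uk.group_center_distance(traj, sel, sel) == 0.0)

    def test_constructed_centroid_distance(self):
        top = _line_trajectory(4).topology
        coords = np.array([[[0.0, 0, 0], [2, 0, 0],
                            [0, 3.86, 0], [2, 3.86, 0]]])
        traj = uk.Trajectory(top, coords)
        a = uk.Selection(top, [0, 1])
        b = uk.Selection(top, [2, 3])
        assert np.isclose(uk.group_center_distance(traj, a, b)[0], 3.86)

    def test_rotation_invariant(self):
        traj = _line_trajectory(6, seed=31)
        top = traj.topology
        a, b = uk.Selection(top, [0, 1, 2]), uk.Selection(top, [3, 4, 5])
        rot, shift = _random_rigid(7)
        moved = uk.Trajectory(top, traj.coords @ rot.T + shift)
        assert np.allclose(uk.group_center_distance(traj, a, b),
                           uk.group_center_distance(moved, a, b))


class TestNativeContacts:
    def test_reference_frame_full_qb(self):
        toy = syn.generate_toy_complex(8, 8, 8, seed=37, n_frames=10,
                                       broken_per_frame=[0] * 10)
        top = toy.topology
        result = uk.native_contacts(toy.trajectory, top.select(chain="A"),
                                    top.select(chain="B"))
        assert np.all(result.qb == 1.0)

    def test_planted_schedule_and_brute_force_oracle(self):
        toy = syn.generate_toy_complex(10, 10, 10, seed=41, n_frames=30)
        top = toy.topology
        result = uk.native_contacts(toy.trajectory, top.select(chain="A"),
                                    top.select(chain="B"))
        assert np.allclose(result.qb, toy.expected_qb)
        # frame-by-frame brute-force all-pairs scan over the native pairs
        ridx = top.residue_index()
        keys = top.residue_keys
        key_to_atoms = {k: np.flatnonzero(ridx == i)
                        for i, k in enumerate(keys)}
        res_a = [key_to_atoms[a] for a, _ in result.native_pairs]
        res_b = [key_to_atoms[b] for _, b in result.native_pairs]
        for f in range(toy.trajectory.n_frames):
            oracle = np.array([
                brute_force_qb(toy.trajectory.coords[f], [ia], [ib])[0]
                for ia, ib in zip(res_a, res_b)])
            assert np.array_equal(result.timelines[:, f], oracle)

    def test_all_scaled_beyond_cutoff_zero(self):
        toy = syn.generate_toy_complex(5, 5, 5, seed=43, n_frames=3,
                                       broken_per_frame=[0, 0, 0])
        coords = toy.trajectory.coords.copy()
        coords[2, 5:] += [0.0, 50.0, 0.0]
        traj = uk.Trajectory(toy.topology, coords)
        result = uk.native_contacts(traj, toy.topology.select(chain="A"),
                                    toy.topology.select(chain="B"))
        assert result.qb[2] == 0.0

    def test_qb_monotone_under_radial_scaling(self):
        """Uniformly scaling the inter-group separation never creates
        contacts: Qb is non-increasing in the scale factor."""
        toy = syn.generate_toy_complex(6, 6, 6, seed=47, n_frames=1,
                                       broken_per_frame=[0], jitter=0.0)
        top = toy.topology
        base = toy.trajectory.coords[0]
        values = []
        for scale in (1.0, 1.2, 1.5, 2.0, 4.0):
            coords = base.copy()
            coords[6:, 1] *= scale       # move ligand radially off the interface
            traj = uk.Trajectory(top, np.stack([base, coords]))
            result = uk.native_contacts(traj, top.select(chain="A"),
                                        top.select(chain="B"))
            values.append(result.qb[1])
        assert all(x >= y for x, y in zip(values, values[1:]))

    def test_no_native_contacts_rejected(self):
        toy = syn.generate_toy_complex(3, 3, 3, seed=53, n_frames=2,
                                       broken_per_frame=[3, 3])
        with pytest.raises(ValueError, match="undefined"):
            uk.native_contacts(toy.trajectory,
                               toy.topology.select(chain="A"),
                               toy.topology.select(chain="B"))


class TestContactMap:
    def test_single_frame_intersection_is_itself(self):
        toy = syn.generate_toy_complex(5, 5, 5, seed=59, n_frames=2)
        maps, inter, keys = uk.contact_map(toy.trajectory, [0])
        assert np.array_equal(maps[0], inter)
        assert len(keys) == 10

    def test_disjoint_maps_empty_intersection(self):
        toy = syn.generate_toy_complex(4, 4, 4, seed=61, n_frames=10)
        # first frame: all contacts; last frame: all broken
        maps, inter, _ = uk.contact_map(
            toy.trajectory, [0, toy.trajectory.n_frames - 1])
        cross = inter[:4, 4:]
        assert not cross.any()

    def test_matches_brute_force_scan(self):
        top, coords = syn.generate_random_complex(4, 4, seed=67, box=8.0)
        traj = uk.Trajectory(top, coords[None])
        maps, _, keys = uk.contact_map(traj, [0], cutoff=6.0)
        ridx = top.residue_index()
        atom_groups = [np.flatnonzero(ridx == i) for i in range(len(keys))]
        for i in range(len(keys)):
            for j in range(len(keys)):
                if i == j:
                    continue
                diff = coords[atom_groups[i]][:, None] - coords[atom_groups[j]]
                expected = np.sqrt((diff ** 2).sum(-1)).min() < 6.0
                assert maps[0, i, j] == expected


@pytest.mark.parametrize("statistic", ["rmsd", "rg", "pca_eigs", "qb"])
def test_statistics_invariant_under_global_rigid_motion(statistic):
    """Applying one rigid transform to every frame leaves each statistic
    unchanged."""
    toy = syn.generate_toy_complex(6, 6, 6, seed=71, n_frames=8)
    traj = toy.trajectory
    top = toy.topology
    rot, shift = _random_rigid(11)
    moved = uk.Trajectory(top, traj.coords @ rot.T + shift)
    sel = top.select_all()
    a, b = top.select(chain="A"), top.select(chain="B")
    if statistic == "rmsd":
        f = lambda t: uk.superpose_rmsd(t, sel)
    elif statistic == "rg":
        f = lambda t: uk.radius_of_gyration(t, sel)
    elif statistic == "pca_eigs":
        f = lambda t: uk.pca(t, sel).eigenvalues
    else:
        f = lambda t: uk.native_contacts(t, a, b).qb
    assert np.allclose(f(traj), f(moved), atol=1e-8)
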