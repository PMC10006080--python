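"""Ensemble analysis: windows, Rg, contacts, f_S, clustering, fractions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_components, partition
from mef2dyn.ensemble import (ContactCriteria, ContactTrajectory, Trajectory,
                              classify_compactness, cluster_contact_map,
                              cluster_snapshots, contact_similarity,
                              contact_trajectory, domain_contact_fraction,
                              extract_contacts, radius_of_gyration,
                              read_contact_table, rg_series, rmsd_to_mean,
                              select_equilibrated_window, similarity_matrix,
                              write_contact_table)
from mef2dyn.profiles import DomainWindow
from mef2dyn.simulate import gen_conformers, gen_contact_trajectory


def chain_trajectory(n_frames=3, n_atoms=10, timestep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    return Trajectory(xyz=rng.normal(size=(n_frames, n_atoms, 3)),
                      masses=np.full(n_atoms, 12.0),
                      residue_index=np.arange(1, n_atoms + 1),
                      timestep_ps=timestep)


class TestWindowSelection:
    def test_snapshot_accounting_single_replica(self):
        traj = chain_trajectory(n_frames=10000)  # 100 ns at 10 ps saves
        idx = select_equilibrated_window(traj, (70, 100))
        assert idx.size == 3000

    def test_three_replicas_pool_to_9000(self):
        total = sum(select_equilibrated_window(
            chain_trajectory(n_frames=10000, seed=s), (70, 100)).size
            for s in range(3))
        assert total == 9000

    def test_full_window_returns_all_frames(self):
        traj = chain_trajectory(n_frames=50)
        idx = select_equilibrated_window(traj, (0, 0.5 + 1e-9))
        assert idx.size == 50

    def test_empty_window(self):
        traj = chain_trajectory(n_frames=50)
        assert select_equilibrated_window(traj, (0, 0)).size == 0

    def test_window_beyond_trajectory_raises(self):
        with pytest.raises(IndexError):
            select_equilibrated_window(chain_trajectory(n_frames=10),
                                       (70, 100))


class TestRadiusOfGyration:
    def test_coincident_atoms(self):
        xyz = np.zeros((5, 3))
        assert radius_of_gyration(xyz, np.ones(5)) == 0.0

    def test_two_point_closed_form(self):
        xyz = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        assert radius_of_gyration(xyz, np.ones(2)) == pytest.approx(0.5)

    def test_matches_double_loop_oracle(self, rng):
        traj = gen_conformers(seed=11, n_frames=3, chain_length=20,
                              collapse_bias=0.4)
        for f in range(traj.n_frames):
            xyz, m = traj.xyz[f], traj.masses
            com = (m[:, None] * xyz).sum(0) / m.sum()
            acc = sum(m[i] * ((xyz[i] - com) ** 2).sum()
                      for i in range(len(m)))
            assert radius_of_gyration(xyz, m) == pytest.approx(
                np.sqrt(acc / m.sum()))

    def test_zero_mass_raises(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.ones((3, 3)), np.zeros(3))

    def test_scaling_doubles_median(self):
        traj = gen_conformers(seed=4, n_frames=5, chain_length=15)
        doubled = Trajectory(xyz=2 * traj.xyz, masses=traj.masses,
                             residue_index=traj.residue_index)
        assert np.median(rg_series(doubled)) == pytest.approx(
            2 * np.median(rg_series(traj)))


class TestContacts:
    def test_two_close_residues_detected(self):
        xyz = np.zeros((1, 5, 3))
        xyz[0, :, 0] = [0.0, 1.0, 2.0, 3.0, 0.3]   # residue 5 near residue 1
        traj = Trajectory(xyz=xyz, masses=np.ones(5),
                          residue_index=np.arange(1, 6))
        contacts = extract_contacts(traj, 0, ContactCriteria(cutoff_nm=0.45))
        assert (1, 5) in contacts

    def test_extended_chain_has_no_distal_contacts(self):
        xyz = np.zeros((1, 10, 3))
        xyz[0, :, 0] = np.arange(10)  # 1 nm spacing
        traj = Trajectory(xyz=xyz, masses=np.ones(10),
                          residue_index=np.arange(1, 11))
        assert extract_contacts(traj, 0) == frozenset()

    def test_hydrogens_excluded(self):
        xyz = np.zeros((1, 3, 3))
        xyz[0] = [[0, 0, 0], [0.3, 0, 0], [5.0, 0, 0]]
        traj = Trajectory(xyz=xyz, masses=np.ones(3),
                          residue_index=np.array([1, 5, 9]),
                          elements=np.array(["C", "H", "C"]))
        # the only close pair involves a hydrogen on residue 5
        assert extract_contacts(traj, 0) == frozenset()

    def test_matches_exhaustive_oracle(self):
        traj = gen_conformers(seed=7, n_frames=4, chain_length=30,
                              collapse_bias=0.8)
        crit = ContactCriteria(cutoff_nm=0.45, min_separation=3)
        for f in range(traj.n_frames):
            oracle = set()
            for i in range(30):
                for j in range(i + 1, 30):
                    d = np.linalg.norm(traj.xyz[f, i] - traj.xyz[f, j])
                    if d <= 0.45 and (j + 1) - (i + 1) >= 3:
                        oracle.add((i + 1, j + 1))
            assert extract_contacts(traj, f, crit) == oracle

    def test_bad_cutoff_raises(self):
        with pytest.raises(ValueError):
            ContactCriteria(cutoff_nm=0.0)


class TestContactSimilarity:
    def test_formula_arithmetic(self):
        a = {(1, 4), (2, 5), (3, 6)}
        b = {(1, 4), (2, 5), (7, 10)}
        assert contact_similarity(a, b) == pytest.approx(2 / 2)

    def test_disjoint_sets(self):
        assert contact_similarity({(1, 4)}, {(2, 5)}) == 0.0

    def test_identical_and_empty_sets_are_inf(self):
        assert contact_similarity({(1, 4)}, {(1, 4)}) == np.inf
        assert contact_similarity(set(), set()) == np.inf

    def test_empty_vs_nonempty_is_zero(self):
        assert contact_similarity(set(), {(1, 4)}) == 0.0

    @given(seed=st.integers(0, 300))
    @settings(max_examples=40, deadline=None)
    def test_symmetry_and_jaccard_relation(self, seed):
        rng = np.random.default_rng(seed)
        universe = [(i, j) for i in range(1, 10) for j in range(i + 3, 10)]
        a = frozenset(p for p in universe if rng.random() < 0.4)
        b = frozenset(p for p in universe if rng.random() < 0.4)
        fs = contact_similarity(a, b)
        assert fs == contact_similarity(b, a)
        union = len(a | b)
        if union and fs != np.inf:
            j = len(a & b) / union
            assert fs == pytest.approx(j / (1 - j))
            assert (fs > 0.5) == (j > 1 / 3)


class TestClustering:
    def test_all_identical_snapshots_one_cluster(self):
        s = frozenset({(1, 5), (2, 7)})
        res = cluster_snapshots(ContactTrajectory(snapshots=[s] * 8))
        assert res.n_clusters == 1 and res.clusters[0].population == 8

    def test_planted_disjoint_motifs_recovered(self):
        ct = gen_contact_trajectory(seed=5, k=2, n_frames=40, noise_rate=0.0)
        res = cluster_snapshots(ct)
        assert partition(res.labels) == partition(ct.true_labels)

    def test_stage1_matches_brute_force_oracle(self):
        import warnings

        for seed in range(5):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # deliberately noisy regime
                ct = gen_contact_trajectory(seed=seed, k=3, n_frames=60,
                                            motif_size=6, noise_rate=0.01,
                                            dropout=0.1)
            res = cluster_snapshots(ct, join_clusters=False)
            assert partition(res.labels) == brute_force_components(
                ct.snapshots)

    def test_empty_trajectory(self):
        res = cluster_snapshots(ContactTrajectory(snapshots=[]))
        assert res.n_clusters == 0 and res.labels.size == 0

    def test_populations_sum_and_frequency_bound(self):
        ct = gen_contact_trajectory(seed=9, k=3, n_frames=50,
                                    noise_rate=0.005)
        res = cluster_snapshots(ct)
        assert res.populations().sum() == len(ct)
        for info in res.clusters:
            assert all(c <= info.population
                       for c in info.frequencies.values())

    def test_join_stage_merges_similar_motifs(self):
        # two stage-1 components sharing the same high-frequency motif:
        # frames of motif A, and frames of motif A plus heavy unique noise
        motif = frozenset({(1, 5), (2, 6), (3, 7), (4, 8)})
        far = [frozenset(motif | {(10 + i, 20 + i)} | {(11 + i, 25 + i)}
                         | {(12 + i, 30 + i)} | {(9 + i, 16 + i)})
               for i in range(4)]
        snaps = [motif] * 4 + far
        res1 = cluster_snapshots(ContactTrajectory(snapshots=snaps),
                                 join_clusters=False)
        res2 = cluster_snapshots(ContactTrajectory(snapshots=snaps),
                                 join_clusters=True)
        assert res2.n_clusters <= res1.n_clusters

    def test_deterministic_given_input(self):
        ct = gen_contact_trajectory(seed=13, k=4, n_frames=80,
                                    noise_rate=0.003)
        a = cluster_snapshots(ct)
        b = cluster_snapshots(ct)
        assert np.array_equal(a.labels, b.labels)


class TestContactMapsAndFractions:
    def test_single_snapshot_cluster_map_is_indicator(self):
        s = frozenset({(1, 5), (2, 8)})
        res = cluster_snapshots(ContactTrajectory(snapshots=[s],
                                                  n_residues=8))
        mat = cluster_contact_map(res, 0)
        assert mat[0, 4] == 1 and mat[4, 0] == 1 and mat.sum() == 4

    def test_pair_in_all_members_counts_population(self):
        s = frozenset({(1, 5)})
        res = cluster_snapshots(ContactTrajectory(snapshots=[s] * 6,
                                                  n_residues=5))
        assert cluster_contact_map(res, 0)[0, 4] == 6

    def test_counts_match_tally_oracle(self):
        ct = gen_contact_trajectory(seed=3, k=2, n_frames=30,
                                    noise_rate=0.004)
        res = cluster_snapshots(ct)
        info = res.clusters[0]
        mat = cluster_contact_map(res, 0)
        for (i, j), c in info.frequencies.items():
            tally = sum((i, j) in ct.snapshots[m] for m in info.members)
            assert mat[i - 1, j - 1] == c == tally

    def test_domain_fraction_extremes(self):
        win = DomainWindow(1, 10)
        inside = ContactTrajectory(snapshots=[frozenset({(1, 5), (2, 8)})] * 3)
        res = cluster_snapshots(inside)
        assert domain_contact_fraction(res, win, "both_in") == 1.0
        assert domain_contact_fraction(res, win, "any_in") == 1.0
        outside = DomainWindow(20, 30)
        assert domain_contact_fraction(res, outside, "both_in") == 0.0
        assert domain_contact_fraction(res, outside, "any_in") == 0.0

    def test_any_in_at_least_both_in(self):
        ct = gen_contact_trajectory(seed=21, k=2, n_frames=30)
        res = cluster_snapshots(ct)
        win = DomainWindow(22, 28)
        assert domain_contact_fraction(res, win, "any_in") >= \
            domain_contact_fraction(res, win, "both_in")


class TestCompactness:
    def test_reference_is_mixed(self):
        assert classify_compactness(np.full(10, 1.0), 1.0) == "mixed"

    def test_generator_ground_truth(self):
        compact = gen_conformers(seed=2, n_frames=12, collapse_bias=1.0)
        extended = gen_conformers(seed=2, n_frames=12, collapse_bias=0.0)
        ref = 0.5 * (np.median(rg_series(compact))
                     + np.median(rg_series(extended)))
        assert classify_compactness(rg_series(compact), ref) == "compact"
        assert classify_compactness(rg_series(extended), ref) == "extended"

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            classify_compactness(np.array([]), 1.0)


class TestPipelineAndIO:
    def test_contact_trajectory_pools_replicas(self):
        reps = [gen_conformers(seed=s, n_frames=20, chain_length=15,
                               timestep_ps=10.0, replica=f"r{s}")
                for s in range(2)]
        ct = contact_trajectory(reps, window_ns=(0.1, 0.2))
        assert len(ct) == 20  # 10 frames per replica in [100, 200) ps

    def test_contact_table_round_trip(self, tmp_path):
        ct = gen_contact_trajectory(seed=6, k=2, n_frames=15,
                                    noise_rate=0.003)
        path = tmp_path / "contacts.tsv"
        write_contact_table(ct, path)
        back = read_contact_table(path, n_frames=len(ct))
        assert back.snapshots == ct.snapshots

    def test_rmsd_to_mean_nonnegative_and_zero_for_static(self):
        traj = chain_trajectory(n_frames=4)
        assert np.all(rmsd_to_mean(traj) >= 0)
        static = Trajectory(xyz=np.repeat(traj.xyz[:1], 4, axis=0),
                            masses=traj.masses,
                            residue_index=traj.residue_index)
        assert np.allclose(rmsd_to_mean(static), 0.0, atol=1e-10)

    def test_similarity_matrix_matches_pairwise(self):
        ct = gen_contact_trajectory(seed=8, k=2, n_frames=12,
                                    noise_rate=0.01)
        fs = similarity_matrix(ct)
        for i in range(len(ct)):
            for j in range(len(ct)):
                assert fs[i, j] == pytest.approx(
                    contact_similarity(ct.snapshots[i], ct.snapshots[j]))
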