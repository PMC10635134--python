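"""Pose selection: symmetry RMSD, leader clustering, ranking, filtering."""

import numpy as np
import pytest

from noedock.docking import Pose
from noedock.selection import (LigandSymmetry, PoseMetric, SelectionConfig,
                               cluster_poses, pose_rmsd, rank_clusters,
                               select_final_poses)
from noedock.structure import RigidTransform


@pytest.fixture(scope="module")
def metric(toy):
    return PoseMetric([toy.receptor], toy.ligand, toy.symmetry)


def _shifted(base: RigidTransform, dx, dy=0.0, dz=0.0, score=0.0) -> Pose:
    shift = RigidTransform(np.eye(3), np.array([dx, dy, dz]))
    return Pose(transform=shift.compose(base), score=score)


def brute_force_leader(poses, metric, cutoff):
    """Independent greedy-leader reimplementation for small instances."""
    unassigned = list(range(len(poses)))
    clusters = []
    while unassigned:
        leader = unassigned[0]  # poses pre-sorted by score
        members = [i for i in unassigned
                   if metric.rmsd(poses[leader], poses[i]) <= cutoff]
        clusters.append(frozenset(members))
        unassigned = [i for i in unassigned if i not in members]
    return clusters


class TestPoseRmsd:
    def test_identical_poses_zero(self, toy, metric):
        p = Pose(transform=toy.true_pose)
        assert metric.rmsd(p, p) == 0.0

    def test_pure_translation(self, toy, metric):
        p = Pose(transform=toy.true_pose)
        q = _shifted(toy.true_pose, 2.0)
        assert metric.rmsd(p, q) == pytest.approx(2.0, abs=1e-9)

    def test_c2_flip_invariant_on_axis_subset(self, toy):
        """The 180° flip about the ligand symmetry axis moves the off-axis
        atoms but leaves the axis-atom RMSD at zero."""
        flip = RigidTransform(np.diag([1.0, -1.0, -1.0]), np.zeros(3))
        p = Pose(transform=toy.true_pose)
        q = Pose(transform=toy.true_pose.compose(flip))
        axis_metric = PoseMetric([toy.receptor], toy.ligand, toy.symmetry)
        all_metric = PoseMetric([toy.receptor], toy.ligand,
                                LigandSymmetry.all_heavy(toy.ligand))
        assert axis_metric.rmsd(p, q) < 1e-6
        assert all_metric.rmsd(p, q) > 1.0

    def test_missing_symmetry_atoms_rejected(self, toy):
        with pytest.raises(ValueError, match="missing"):
            PoseMetric([toy.receptor], toy.ligand, LigandSymmetry(("XX",)))

    def test_functional_wrapper(self, toy):
        p = Pose(transform=toy.true_pose)
        q = _shifted(toy.true_pose, 1.0)
        got = pose_rmsd(p, q, toy.symmetry, [toy.receptor], toy.ligand)
        assert got == pytest.approx(1.0, abs=1e-9)

    def test_cross_receptor_alignment(self, toy):
        """Rigidly moving a receptor conformation (and its pose with it)
        changes nothing after Cα alignment."""
        t = RigidTransform.from_rotvec([0.2, 0.1, -0.4], [3.0, -1.0, 2.0])
        moved_receptor = toy.receptor.with_coords(t.apply(toy.receptor.coords))
        metric = PoseMetric([toy.receptor, moved_receptor], toy.ligand, toy.symmetry)
        p = Pose(transform=toy.true_pose, receptor_index=0)
        q = Pose(transform=t.compose(toy.true_pose), receptor_index=1)
        assert metric.rmsd(p, q) < 1e-6


class TestClusterPoses:
    def test_all_within_cutoff_single_cluster(self, toy, metric):
        poses = [_shifted(toy.true_pose, 0.1 * i, score=float(i)) for i in range(5)]
        res = cluster_poses(poses, metric, SelectionConfig(cluster_cutoff=1.5))
        assert res.n_clusters == 1

    def test_all_far_singletons(self, toy, metric):
        poses = [_shifted(toy.true_pose, 4.0 * i, score=float(i)) for i in range(4)]
        res = cluster_poses(poses, metric, SelectionConfig(cluster_cutoff=1.5))
        assert res.n_clusters == 4

    def test_matches_brute_force_oracle(self, toy, metric):
        rng = np.random.default_rng(12)
        poses = []
        for i in range(20):
            blob = rng.integers(3)
            offset = np.array([0.0, 6.0, 12.0])[blob]
            dx, dy = 0.4 * rng.standard_normal(2)
            poses.append(_shifted(toy.true_pose, offset + dx, dy, score=float(i)))
        cfg = SelectionConfig(cluster_cutoff=1.5)
        res = cluster_poses(poses, metric, cfg)
        expected = brute_force_leader(poses, metric, 1.5)
        got = [frozenset(res.members(c)) for c in range(res.n_clusters)]
        assert got == expected

    def test_leader_separation_invariant(self, toy, metric):
        rng = np.random.default_rng(5)
        poses = [_shifted(toy.true_pose, 3.0 * rng.standard_normal(),
                          score=float(i)) for i in range(15)]
        res = cluster_poses(poses, metric, SelectionConfig(cluster_cutoff=1.0))
        for a in res.seeds:
            for b in res.seeds:
                if a < b:
                    assert metric.rmsd(poses[a], poses[b]) > 1.0
        for cid, leader in enumerate(res.seeds):
            for i in res.members(cid):
                assert metric.rmsd(poses[leader], poses[i]) <= 1.0

    def test_unsorted_rejected(self, toy, metric):
        poses = [_shifted(toy.true_pose, 0, score=1.0), _shifted(toy.true_pose, 0, score=0.0)]
        with pytest.raises(ValueError, match="sorted"):
            cluster_poses(poses, metric)


class TestRankClusters:
    def _clusters_of(self, sizes_scores, toy, metric):
        poses, x = [], 0.0
        for scores in sizes_scores:
            for s in sorted(scores):
                poses.append(_shifted(toy.true_pose, x, score=s))
            x += 10.0
        poses.sort(key=lambda p: p.score)
        return poses, cluster_poses(poses, metric, SelectionConfig(cluster_cutoff=1.5))

    def test_top_four_average(self, toy, metric):
        poses, clusters = self._clusters_of([[-10, -9, -8, -7, -6]], toy, metric)
        order = rank_clusters(clusters, poses, SelectionConfig(rank_top_k=4))
        assert order == [0]
        members = clusters.members(0)
        best4 = sorted(poses[i].score for i in members)[:4]
        assert np.mean(best4) == pytest.approx(-8.5)

    def test_small_cluster_averages_all_members(self, toy, metric):
        poses, clusters = self._clusters_of([[-4, -2]], toy, metric)
        order = rank_clusters(clusters, poses, SelectionConfig(rank_top_k=4))
        assert order == [0]  # rank key is the mean of both members (−3)

    def test_better_average_ranks_first(self, toy, metric):
        poses, clusters = self._clusters_of(
            [[-9, -9, -8, -8], [-10, -8, -7, -7]], toy, metric)
        # keys: −8.5 vs −8.0 → the first cluster wins
        order = rank_clusters(clusters, poses, SelectionConfig(rank_top_k=4))
        key = lambda cid: np.mean(sorted(poses[i].score for i in clusters.members(cid))[:4])
        assert key(order[0]) <= key(order[1])
        assert key(order[0]) == pytest.approx(-8.5)


class TestSelectFinalPoses:
    def test_violation_free_representatives_survive(self, toy, toy_restraints, metric):
        poses = [_shifted(toy.true_pose, 0.0, score=-5.0),
                 _shifted(toy.true_pose, 0.3, score=-4.0)]
        clusters = cluster_poses(poses, metric)
        order = rank_clusters(clusters, poses)
        report = select_final_poses(order, clusters, poses, toy_restraints,
                                    [toy.receptor], toy.ligand)
        assert len(report.final_poses) == clusters.n_clusters
        assert report.n_restraints_satisfied == len(toy_restraints)

    def test_violating_representative_dropped(self, toy, toy_restraints, metric):
        # 60 Å away: every restraint is grossly violated
        poses = [_shifted(toy.true_pose, 60.0, score=-5.0)]
        clusters = cluster_poses(poses, metric)
        report = select_final_poses([0], clusters, poses, toy_restraints,
                                    [toy.receptor], toy.ligand)
        assert report.final_poses == []
        assert report.n_dropped_by_violation == 1
        assert "no poses passed" in report.summary()

    def test_filter_monotone_in_tolerance(self, toy, toy_restraints, metric):
        rng = np.random.default_rng(8)
        poses = sorted((_shifted(toy.true_pose, 2.5 * rng.standard_normal(),
                                 0.5 * rng.standard_normal(), score=float(i))
                        for i in range(12)), key=lambda p: p.score)
        clusters = cluster_poses(poses, metric)
        order = rank_clusters(clusters, poses)
        kept = []
        for tol in (0.0, 0.3, 1.0, 5.0):
            cfg = SelectionConfig(violation_tolerance=tol)
            rep = select_final_poses(order, clusters, poses, toy_restraints,
                                     [toy.receptor], toy.ligand, cfg)
            kept.append({id(p.transform) for p in rep.final_poses})
        for a, b in zip(kept, kept[1:]):
            assert a <= b

    def test_output_never_exceeds_cluster_count(self, toy, toy_restraints, metric):
        rng = np.random.default_rng(3)
        poses = sorted((_shifted(toy.true_pose, 2.0 * rng.standard_normal(),
                                 score=float(i)) for i in range(10)),
                       key=lambda p: p.score)
        clusters = cluster_poses(poses, metric)
        order = rank_clusters(clusters, poses)
        rep = select_final_poses(order, clusters, poses, toy_restraints,
                                 [toy.receptor], toy.ligand)
        assert len(rep.final_poses) <= clusters.n_clusters
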