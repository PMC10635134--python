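"""Rigid-body docking: sampling, scoring, minimisation, ensemble runs."""

import numpy as np
import pytest

from noedock.docking import (DockingConfig, build_context, dock_ensemble,
                             minimize_pose, sample_pose, score_pose)
from noedock.restraints import derive_active_residues
from noedock.structure import Atom, Structure, rmsd_no_fit
from noedock.synthetic import (ToyComplexSpec, fabricated_restraints,
                               make_receptor_variants, make_toy_complex)


@pytest.fixture(scope="module")
def docking_setup(toy, toy_restraints):
    active = derive_active_residues(toy.noe_peaks, toy.proton_groups, toy.site_labels)
    ctx = build_context(toy.receptor, toy.ligand, active, toy_restraints)
    config = DockingConfig(sampling_center=tuple(toy.true_ligand.centroid()),
                           sampling_radius=2.0, max_minimizer_evals=80, seed=0)
    return ctx, config, active


class TestSamplePose:
    def test_zero_radius_centers_exactly(self, toy, rng):
        cfg = DockingConfig(sampling_center=(1.0, 2.0, 3.0), sampling_radius=0.0)
        pose = sample_pose(toy.ligand, cfg, rng)
        centroid = pose.transform.apply(toy.ligand.coords).mean(axis=0)
        np.testing.assert_allclose(centroid, [1.0, 2.0, 3.0], atol=1e-12)

    def test_centroid_distribution_matches_uniform_ball(self, toy):
        # mean of a uniform ball is its centre; per-axis variance R²/5
        R = 2.0
        cfg = DockingConfig(sampling_center=(0.0, 0.0, 0.0), sampling_radius=R)
        rng = np.random.default_rng(42)
        centroids = np.array([
            sample_pose(toy.ligand, cfg, rng).transform.apply(toy.ligand.coords).mean(axis=0)
            for _ in range(4000)])
        sigma_mean = np.sqrt(R ** 2 / 5 / len(centroids))
        assert np.abs(centroids.mean(axis=0)).max() < 3 * sigma_mean
        assert np.allclose(centroids.var(axis=0), R ** 2 / 5, rtol=0.15)

    def test_deterministic_sequence(self, toy):
        cfg = DockingConfig(sampling_center=(0.0, 0.0, 0.0), sampling_radius=2.0)
        a = [sample_pose(toy.ligand, cfg, np.random.default_rng(7)).transform.translation
             for _ in range(1)]
        b = [sample_pose(toy.ligand, cfg, np.random.default_rng(7)).transform.translation
             for _ in range(1)]
        np.testing.assert_array_equal(a, b)

    def test_rotations_are_proper(self, toy, rng):
        cfg = DockingConfig()
        for _ in range(20):
            R = sample_pose(toy.ligand, cfg, rng).transform.rotation
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


class TestScorePose:
    def test_true_pose_scores_zero(self, toy, docking_setup):
        ctx, config, _ = docking_setup
        from noedock.docking import Pose

        pose = Pose(transform=toy.true_pose)
        scored = score_pose(pose, ctx, config)
        assert scored.e_air == pytest.approx(0.0, abs=1e-12)
        assert scored.e_steric == pytest.approx(0.0, abs=1e-12)
        assert scored.score == pytest.approx(0.0, abs=1e-12)

    def test_single_air_violation_arithmetic(self):
        # one restraint with d_eff = upper + 0.5 and no steric partner
        from noedock.docking import ScoringContext
        from noedock.restraints import AtomGroup, DistanceRestraint

        rec = Structure([Atom(1, "CG", "C", "PRB", 1, "A", [0.0, 0.0, 0.0])])
        lig = Structure([Atom(1, "C1", "C", "LIG", 1, "L", [8.5, 0.0, 0.0])])
        ctx = ScoringContext(receptor=rec, ligand=lig)
        ctx.add_distance_restraints([DistanceRestraint(
            "t", AtomGroup("ligand", ("C1",)), AtomGroup("receptor", ("CG",), 1),
            lower=1.8, upper=8.0)])
        e_air, e_steric = ctx.energies(lig.coords)
        assert e_air == pytest.approx(0.25)
        # single C–C pair at 8.5 Å is nowhere near the soft contact
        assert e_steric == pytest.approx(0.0)

    def test_steric_penalty_matches_hand_computation(self):
        # three C–C contacts at fixed distances; softness 0.8·(1.7+1.7)=2.72
        rec = Structure([Atom(1, "C", "C", "WAL", 900, "A", [0.0, 0.0, 0.0])])
        lig = Structure([
            Atom(1, "C1", "C", "LIG", 1, "L", [2.0, 0.0, 0.0]),
            Atom(2, "C2", "C", "LIG", 1, "L", [0.0, 2.5, 0.0]),
            Atom(3, "C3", "C", "LIG", 1, "L", [0.0, 0.0, 4.0]),
        ])
        ctx = build_context(rec, lig)
        _, e_steric = ctx.energies(lig.coords)
        expected = (2.72 - 2.0) ** 2 + (2.72 - 2.5) ** 2  # third pair clash-free
        assert e_steric == pytest.approx(expected)

    def test_score_decomposition_exact(self, toy, docking_setup, rng):
        ctx, _, _ = docking_setup
        config = DockingConfig(w_air=2.0, w_steric=0.5,
                               sampling_center=tuple(toy.true_ligand.centroid()))
        for _ in range(10):
            pose = score_pose(sample_pose(toy.ligand, config, rng), ctx, config)
            assert pose.score == pytest.approx(2.0 * pose.e_air + 0.5 * pose.e_steric)
            assert pose.e_air >= 0 and pose.e_steric >= 0


class TestMinimizePose:
    def test_zero_score_pose_stays_optimal(self, toy, docking_setup):
        ctx, config, _ = docking_setup
        from noedock.docking import Pose

        pose = score_pose(Pose(transform=toy.true_pose), ctx, config)
        out = minimize_pose(pose, ctx, config)
        assert out.score <= pose.score + 1e-12
        assert out.score == pytest.approx(0.0, abs=1e-9)

    def test_displaced_pose_recovers_funnel_minimum(self, toy, docking_setup):
        ctx, config, _ = docking_setup
        from noedock.docking import Pose
        from noedock.structure import RigidTransform

        shift = RigidTransform(np.eye(3), np.array([2.0, 0.0, 0.0]))
        displaced = score_pose(Pose(transform=shift.compose(toy.true_pose)), ctx, config)
        assert displaced.score > 0.1
        out = minimize_pose(displaced, ctx,
                            DockingConfig(max_minimizer_evals=600,
                                          sampling_center=config.sampling_center))
        assert out.score < 1e-3

    def test_rigidity_preserved(self, toy, docking_setup, rng):
        ctx, config, _ = docking_setup
        pose = score_pose(sample_pose(toy.ligand, config, rng), ctx, config)
        out = minimize_pose(pose, ctx, config)
        d_in = np.linalg.norm(pose.ligand_coords(toy.ligand)[:, None]
                              - pose.ligand_coords(toy.ligand)[None], axis=-1)
        d_out = np.linalg.norm(out.ligand_coords(toy.ligand)[:, None]
                               - out.ligand_coords(toy.ligand)[None], axis=-1)
        assert np.abs(d_in - d_out).max() < 1e-9

    def test_monotone_never_worse(self, toy, docking_setup, rng):
        ctx, config, _ = docking_setup
        for _ in range(5):
            pose = score_pose(sample_pose(toy.ligand, config, rng), ctx, config)
            out = minimize_pose(pose, ctx, config)
            assert out.score <= pose.score + 1e-12


class TestDockEnsemble:
    def test_bookkeeping_counts(self, toy, docking_setup):
        _, config, active = docking_setup
        receptors = make_receptor_variants(toy, 3, seed=1)
        cfg = DockingConfig(n_poses_per_conformation=4, max_minimizer_evals=10,
                            sampling_center=config.sampling_center, seed=2)
        poses = dock_ensemble(receptors, toy.ligand, active, cfg)
        assert len(poses) == 12
        scores = [p.score for p in poses]
        assert scores == sorted(scores)

    def test_single_receptor_single_pose(self, toy, docking_setup):
        _, config, active = docking_setup
        cfg = DockingConfig(n_poses_per_conformation=1, max_minimizer_evals=10,
                            sampling_center=config.sampling_center, seed=2)
        assert len(dock_ensemble([toy.receptor], toy.ligand, active, cfg)) == 1

    def test_deterministic_under_seed(self, toy, docking_setup, toy_restraints):
        _, config, active = docking_setup
        cfg = DockingConfig(n_poses_per_conformation=5, max_minimizer_evals=30,
                            sampling_center=config.sampling_center, seed=9)
        a = dock_ensemble([toy.receptor], toy.ligand, active, cfg, toy_restraints)
        b = dock_ensemble([toy.receptor], toy.ligand, active, cfg, toy_restraints)
        for pa, pb in zip(a, b):
            assert pa.score == pb.score
            np.testing.assert_array_equal(pa.transform.translation, pb.transform.translation)

    def test_ground_truth_recovery_across_seeds(self):
        """Best-scoring pose lands within 1.5 Å symmetry-RMSD of the true
        pose for ≥95% of seeds (2 receptors × 200 poses each)."""
        recovered = 0
        n_seeds = 20
        for seed in range(n_seeds):
            c = make_toy_complex(ToyComplexSpec(seed=seed))
            restraints = fabricated_restraints(c)
            active = derive_active_residues(c.noe_peaks, c.proton_groups, c.site_labels)
            receptors = make_receptor_variants(c, 2, seed=seed + 100)
            cfg = DockingConfig(n_poses_per_conformation=200,
                                sampling_center=tuple(c.true_ligand.centroid()),
                                sampling_radius=2.0, max_minimizer_evals=80, seed=seed)
            poses = dock_ensemble(receptors, c.ligand, active, cfg, restraints=restraints)
            names = set(c.symmetry.rmsd_atom_names)
            idx = [i for i, a in enumerate(c.ligand.atoms) if a.name in names]
            truth = c.true_pose.apply(c.ligand.coords)[idx]
            best = poses[0].transform.apply(c.ligand.coords)[idx]
            recovered += rmsd_no_fit(best, truth) <= 1.5
        assert recovered >= 0.95 * n_seeds
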