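"""Post-docking pose selection funnel.

Docked poses are compared by a symmetry-aware ligand RMSD (computed after
aligning receptor Cα atoms, and restricted for a C2-symmetric ligand to the
heavy atoms on its symmetry axis so the two flip-related placements are not
double-counted), clustered by score-ordered leader clustering at a fixed
cutoff, ranked by the mean score of each cluster's best four poses, and
reduced to one best pose per cluster; poses violating any NOE restraint by
more than the tolerance are discarded.  The surviving ensemble is summarised
by any-pose restraint satisfaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .docking import Pose
from .ensemble import ClusterResult
from .restraints import DistanceRestraint, evaluate_violations
from .structure import RigidTransform, Structure, rmsd_no_fit, select_atoms, superpose

__all__ = ["LigandSymmetry", "SelectionConfig", "PoseMetric", "pose_rmsd",
           "cluster_poses", "rank_clusters", "select_final_poses", "SelectionReport"]


@dataclass(frozen=True)
class LigandSymmetry:
    """Ligand heavy atoms used for pose RMSD.

    For a two-fold symmetric ligand these are the atoms on the symmetry axis
    (invariant under the flip); for an asymmetric ligand, all heavy atoms.
    """

    rmsd_atom_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rmsd_atom_names:
            raise ValueError("symmetry atom list must be nonempty")

    @classmethod
    def all_heavy(cls, ligand: Structure) -> "LigandSymmetry":
        return cls(tuple(a.name for a in ligand.atoms if not a.is_hydrogen))


@dataclass(frozen=True)
class SelectionConfig:
    cluster_cutoff: float = 1.5
    violation_tolerance: float = 0.3
    rank_top_k: int = 4
    alignment_atom_name: str = "CA"

    def __post_init__(self) -> None:
        if self.cluster_cutoff <= 0:
            raise ValueError("cluster cutoff must be > 0")
        if self.violation_tolerance < 0:
            raise ValueError("violation tolerance must be >= 0")
        if self.rank_top_k < 1:
            raise ValueError("rank_top_k must be >= 1")


class PoseMetric:
    """Symmetry-aware pose RMSD with cached receptor Cα alignments."""

    def __init__(self, receptors: Sequence[Structure], ligand: Structure,
                 symmetry: LigandSymmetry, alignment_atom_name: str = "CA"):
        self.receptors = list(receptors)
        self.ligand = ligand
        self.symmetry = symmetry
        names = set(symmetry.rmsd_atom_names)
        self._sym_idx = [i for i, a in enumerate(ligand.atoms) if a.name in names]
        if len(self._sym_idx) != len(symmetry.rmsd_atom_names):
            found = {ligand.atoms[i].name for i in self._sym_idx}
            missing = sorted(names - found)
            raise ValueError(f"symmetry atoms missing from ligand: {missing}")
        self._sym_template = ligand.coords[self._sym_idx]
        self._ca = [select_atoms(r, atom_names=[alignment_atom_name]).coords
                    for r in self.receptors]
        self._align_cache: dict[tuple[int, int], RigidTransform] = {}

    def _alignment(self, src: int, dst: int) -> RigidTransform:
        """Transform mapping receptor ``src`` frame onto receptor ``dst``."""
        key = (src, dst)
        if key not in self._align_cache:
            if src == dst:
                self._align_cache[key] = RigidTransform.identity()
            else:
                if self._ca[src].shape != self._ca[dst].shape:
                    raise ValueError("receptor conformations have mismatched Cα sets")
                transform, _ = superpose(self._ca[src], self._ca[dst])
                self._align_cache[key] = transform
        return self._align_cache[key]

    def symmetry_coords(self, pose: Pose, frame_of: int | None = None) -> np.ndarray:
        """Pose's symmetry-atom coordinates, optionally mapped to another
        receptor's frame via Cα alignment."""
        xyz = pose.transform.apply(self._sym_template)
        if frame_of is not None and frame_of != pose.receptor_index:
            xyz = self._alignment(pose.receptor_index, frame_of).apply(xyz)
        return xyz

    def rmsd(self, pose_a: Pose, pose_b: Pose) -> float:
        a = self.symmetry_coords(pose_a)
        b = self.symmetry_coords(pose_b, frame_of=pose_a.receptor_index)
        return rmsd_no_fit(a, b)


def pose_rmsd(pose_a: Pose, pose_b: Pose, symmetry: LigandSymmetry,
              receptors: Sequence[Structure], ligand: Structure,
              alignment_atom_name: str = "CA") -> float:
    """Ligand RMSD between two poses after receptor Cα alignment.

    Computed over ``symmetry.rmsd_atom_names`` only, without re-fitting the
    ligand itself.
    """
    metric = PoseMetric(receptors, ligand, symmetry, alignment_atom_name)
    return metric.rmsd(pose_a, pose_b)


def cluster_poses(poses: Sequence[Pose], metric: PoseMetric,
                  config: SelectionConfig | None = None) -> ClusterResult:
    """Score-ordered leader clustering of docked poses.

    The best-ranked unassigned pose seeds a cluster; every unassigned pose
    within the cutoff of that leader joins it.  Poses must arrive sorted
    ascending by score.  Deterministic.
    """
    if not poses:
        raise ValueError("no poses to cluster")
    config = config or SelectionConfig()
    scores = [p.score for p in poses]
    if any(scores[i] > scores[i + 1] for i in range(len(scores) - 1)):
        raise ValueError("poses must be sorted ascending by score")
    n = len(poses)
    # leader coords cached in the leader's own receptor frame per comparison
    assignments = np.full(n, -1, dtype=int)
    seeds: list[int] = []
    for i in range(n):
        if assignments[i] != -1:
            continue
        cid = len(seeds)
        seeds.append(i)
        assignments[i] = cid
        for j in range(i + 1, n):
            if assignments[j] == -1 and metric.rmsd(poses[i], poses[j]) <= config.cluster_cutoff:
                assignments[j] = cid
    # the leader is both seed and representative (best score in its cluster)
    return ClusterResult(assignments=assignments, seeds=seeds,
                         representatives=list(seeds), radius=config.cluster_cutoff)


def rank_clusters(clusters: ClusterResult, poses: Sequence[Pose],
                  config: SelectionConfig | None = None) -> list[int]:
    """Cluster ids sorted by the mean score of each cluster's best poses.

    The average runs over the best min(top_k, size) members; ties prefer the
    larger cluster, then the lower cluster id.
    """
    config = config or SelectionConfig()
    keys = []
    for cid in range(clusters.n_clusters):
        members = clusters.members(cid)
        member_scores = sorted(poses[i].score for i in members)
        k = min(config.rank_top_k, len(member_scores))
        keys.append((float(np.mean(member_scores[:k])), -len(members), cid))
    return [cid for _, _, cid in sorted(zip([k[0] for k in keys],
                                            [k[1] for k in keys],
                                            [k[2] for k in keys]))]


@dataclass
class SelectionReport:
    final_poses: list[Pose]
    cluster_order: list[int]
    n_clusters: int
    n_dropped_by_violation: int
    n_restraints: int
    n_restraints_satisfied: int
    residues_satisfied: dict[int, bool] = field(default_factory=dict)
    restraints_satisfied: dict[str, bool] = field(default_factory=dict)
    note: str = ""

    @property
    def n_residues(self) -> int:
        return len(self.residues_satisfied)

    @property
    def n_residues_satisfied(self) -> int:
        return sum(self.residues_satisfied.values())

    def summary(self) -> str:
        if not self.final_poses:
            return (f"no poses passed the {self.note or 'violation'} filter; "
                    f"0 final poses from {self.n_clusters} clusters")
        return (f"{len(self.final_poses)} final poses from {self.n_clusters} clusters; "
                f"satisfied {self.n_restraints_satisfied} of {self.n_restraints} restraints; "
                f"{self.n_residues_satisfied} of {self.n_residues} receptor residues")


def select_final_poses(ranked_cluster_ids: Sequence[int], clusters: ClusterResult,
                       poses: Sequence[Pose], restraints: Sequence[DistanceRestraint],
                       receptors: Sequence[Structure], ligand: Structure,
                       config: SelectionConfig | None = None) -> SelectionReport:
    """Best pose per cluster in rank order, NOE-violation filtered.

    A cluster representative whose worst restraint violation exceeds the
    tolerance is discarded.  An empty survivor set is a valid outcome and is
    reported, not raised.
    """
    config = config or SelectionConfig()
    if not ranked_cluster_ids:
        raise ValueError("no ranked clusters")
    final: list[Pose] = []
    dropped = 0
    for cid in ranked_cluster_ids:
        members = clusters.members(cid)
        best_idx = min(members, key=lambda i: (poses[i].score, i))
        pose = poses[best_idx]
        lig = pose.realize(ligand)
        report = evaluate_violations(restraints, receptors[pose.receptor_index], lig,
                                     tolerance=config.violation_tolerance)
        if report.max_violation > config.violation_tolerance:
            dropped += 1
            continue
        final.append(replace(pose, violations=report))
    if final:
        pose_ligands = [p.realize(ligand) for p in final]
        # evaluate each pose against its own receptor conformation
        per_restraint: dict[str, bool] = {r.id: False for r in restraints}
        for p, lig in zip(final, pose_ligands):
            rep = evaluate_violations(restraints, receptors[p.receptor_index], lig,
                                      tolerance=config.violation_tolerance)
            for rec in rep:
                per_restraint[rec.restraint_id] = per_restraint[rec.restraint_id] or rec.satisfied
        per_residue: dict[int, bool] = {}
        for r in restraints:
            if r.receptor_residue is None:
                continue
            per_residue[r.receptor_residue] = (per_residue.get(r.receptor_residue, False)
                                               or per_restraint[r.id])
        n_sat = sum(per_restraint.values())
    else:
        per_restraint = {r.id: False for r in restraints}
        per_residue = {r.receptor_residue: False for r in restraints
                       if r.receptor_residue is not None}
        n_sat = 0
    return SelectionReport(
        final_poses=final,
        cluster_order=list(ranked_cluster_ids),
        n_clusters=clusters.n_clusters,
        n_dropped_by_violation=dropped,
        n_restraints=len(restraints),
        n_restraints_satisfied=n_sat,
        residues_satisfied=per_residue,
        restraints_satisfied=per_restraint,
        note=f"{config.violation_tolerance} Å violation",
    )
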