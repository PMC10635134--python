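"""Quality-threshold clustering of conformational trajectories.

A continuous trajectory is reduced to a small ensemble of docking receptors:
pairwise superposed RMSD over a heavy-atom selection, greedy quality-threshold
clustering at a fixed radius, and per-cluster medoid representatives (the
member closest to the centroid in RMSD space).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure import Structure, superpose

__all__ = ["FrameSet", "ClusterResult", "pairwise_rmsd_matrix", "qt_cluster",
           "representative_frames", "reference_rmsd_profile"]


@dataclass
class FrameSet:
    """An ordered, atom-aligned list of conformations of the same molecule."""

    frames: list[Structure]
    labels: list | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty frame set")
        n0 = len(self.frames[0])
        names0 = [a.name for a in self.frames[0].atoms]
        for i, f in enumerate(self.frames[1:], start=1):
            if len(f) != n0 or [a.name for a in f.atoms] != names0:
                raise ValueError(f"frame {i} is not atom-aligned with frame 0")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class ClusterResult:
    """Frame→cluster assignment with seed and representative frames."""

    assignments: np.ndarray  # cluster id per frame
    seeds: list[int]  # seed frame per cluster id
    representatives: list[int]  # medoid frame per cluster id
    radius: float

    @property
    def n_clusters(self) -> int:
        return len(self.seeds)

    def members(self, cluster_id: int) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.assignments == cluster_id)]


def _selection_indices(frames: Sequence[Structure], selection) -> list[int]:
    first = frames[0]
    if selection is None:
        idx = [i for i, a in enumerate(first.atoms) if not a.is_hydrogen]
    elif callable(selection):
        idx = [i for i, a in enumerate(first.atoms) if selection(a)]
    else:
        names = set(selection)
        idx = [i for i, a in enumerate(first.atoms) if a.name in names]
    if not idx:
        raise ValueError("empty atom selection for RMSD")
    return idx


def pairwise_rmsd_matrix(frames: Sequence[Structure], selection=None) -> np.ndarray:
    """Symmetric matrix of superposed RMSDs over an atom selection.

    ``selection`` may be None (heavy atoms), a set of atom names, or a
    predicate on Atom.  Frames must be atom-aligned.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    idx = _selection_indices(frames, selection)
    coords = [f.coords[idx] for f in frames]
    n = len(frames)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, rmsd = superpose(coords[j], coords[i])
            m[i, j] = m[j, i] = rmsd
    return m


def reference_rmsd_profile(frames: Sequence[Structure], reference: Structure,
                           selection=None) -> np.ndarray:
    """Superposed RMSD of each frame from one reference conformation (1-D mode)."""
    idx = _selection_indices(list(frames) + [reference], selection)
    ref = reference.coords[idx]
    return np.array([superpose(f.coords[idx], ref)[1] for f in frames])


def qt_cluster(matrix: np.ndarray, radius: float) -> ClusterResult:
    """Greedy quality-threshold clustering on a distance matrix.

    Repeatedly, every unassigned frame proposes the cluster of all unassigned
    frames within ``radius`` of it; the largest candidate is committed (ties
    broken toward the lowest seed index).  Every member ends within ``radius``
    of its cluster's seed.  Deterministic.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(m, m.T, atol=1e-9) or np.any(m < 0):
        raise ValueError("distance matrix must be symmetric and non-negative")
    if radius <= 0:
        raise ValueError("quality threshold radius must be > 0")
    n = m.shape[0]
    assignments = np.full(n, -1, dtype=int)
    seeds: list[int] = []
    members_by_cluster: list[list[int]] = []
    while np.any(assignments == -1):
        unassigned = np.flatnonzero(assignments == -1)
        best_seed, best_members = -1, []
        for s in unassigned:
            cand = [int(i) for i in unassigned if m[s, i] <= radius]
            if len(cand) > len(best_members):
                best_seed, best_members = int(s), cand
        cid = len(seeds)
        seeds.append(best_seed)
        members_by_cluster.append(best_members)
        assignments[best_members] = cid

    representatives = [_medoid(members, m) for members in members_by_cluster]
    return ClusterResult(assignments=assignments, seeds=seeds,
                         representatives=representatives, radius=float(radius))


def _medoid(members: list[int], m: np.ndarray) -> int:
    """Member minimising mean squared distance to the others; ties → lowest index."""
    if len(members) == 1:
        return members[0]
    sub = m[np.ix_(members, members)]
    cost = (sub ** 2).mean(axis=1)
    order = sorted(range(len(members)), key=lambda k: (cost[k], members[k]))
    return members[order[0]]


def representative_frames(frames: Sequence[Structure], result: ClusterResult) -> list[Structure]:
    """The medoid conformation of each cluster, in cluster-id order."""
    if result.n_clusters == 0:
        raise ValueError("no clusters to represent")
    return [frames[i] for i in result.representatives]
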