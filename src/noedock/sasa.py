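"""Shrake–Rupley solvent-accessible surface area and cavity openness.

The cavity-openness progress coordinate is the summed SASA of the residues
lining the receptor's internal cavity (default: the 17 ARNT PAS-B cavity
residues), computed in the context of the whole structure.  The sphere
lattice is a deterministic golden-spiral placement, so results carry no RNG
dependence; per-atom SASA is the unoccluded fraction of lattice points on
the expanded sphere of radius r_atom + probe, scaled by that sphere's area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure

__all__ = ["CavityDefinition", "SasaResult", "sphere_lattice", "shrake_rupley", "cavity_openness"]

#: Cavity-lining residues of ARNT PAS-B used for the openness coordinate.
ARNT_CAVITY_RESIDUES = (363, 365, 373, 396, 409, 411, 412, 415, 425,
                        427, 429, 439, 441, 443, 457, 459, 461)


@dataclass(frozen=True)
class CavityDefinition:
    residues: tuple[int, ...] = ARNT_CAVITY_RESIDUES
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    include_hydrogens: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("cavity definition needs at least one residue")
        if self.probe_radius <= 0:
            raise ValueError("probe radius must be > 0")
        if self.n_sphere_points < 60:
            raise ValueError("need at least 60 sphere points")


@dataclass
class SasaResult:
    per_atom: np.ndarray  # Å², aligned with the atom subset used
    atom_indices: list[int]  # indices into the input structure
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_atom = np.asarray(self.per_atom, dtype=float)
        self.total = float(self.per_atom.sum())


def sphere_lattice(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(structure: Structure,
                  probe_radius: float = 1.4,
                  n_sphere_points: int = 960,
                  include_hydrogens: bool = False) -> SasaResult:
    """Per-atom solvent-accessible surface area (Å²).

    Heavy atoms only by default (crystal structures usually lack hydrogens);
    set ``include_hydrogens`` when SASA of protonated models is wanted.
    """
    idx = [i for i, a in enumerate(structure.atoms)
           if include_hydrogens or not a.is_hydrogen]
    if not idx:
        raise ValueError("no atoms to compute SASA for")
    xyz = np.array([structure.atoms[i].xyz for i in idx])
    radii = np.array([structure.atoms[i].vdw_radius for i in idx]) + probe_radius
    unit = sphere_lattice(n_sphere_points)

    tree = cKDTree(xyz)
    rmax = radii.max()
    per_atom = np.empty(len(idx))
    point_area = 4.0 * np.pi / n_sphere_points
    for k in range(len(idx)):
        pts = xyz[k] + radii[k] * unit
        neighbors = tree.query_ball_point(xyz[k], r=radii[k] + rmax)
        neighbors = [j for j in neighbors if j != k]
        if neighbors:
            d = np.linalg.norm(pts[:, None, :] - xyz[neighbors][None, :, :], axis=-1)
            buried = np.any(d < radii[neighbors][None, :], axis=1)
            n_free = int(np.count_nonzero(~buried))
        else:
            n_free = n_sphere_points
        per_atom[k] = n_free * point_area * radii[k] ** 2
    return SasaResult(per_atom=per_atom, atom_indices=idx)


def cavity_openness(structure: Structure, cavity: CavityDefinition | None = None) -> float:
    """Summed SASA (Å²) of the cavity-lining residues, in whole-structure context."""
    cavity = cavity or CavityDefinition()
    present = set(structure.residue_numbers())
    missing = [r for r in cavity.residues if r not in present]
    if missing:
        raise ValueError(f"cavity residue(s) missing from structure: {missing}")
    result = shrake_rupley(structure,
                           probe_radius=cavity.probe_radius,
                           n_sphere_points=cavity.n_sphere_points,
                           include_hydrogens=cavity.include_hydrogens)
    wanted = set(cavity.residues)
    mask = np.array([structure.atoms[i].res_seq in wanted for i in result.atom_indices])
    return float(result.per_atom[mask].sum())
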