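"""Ground-truth synthetic systems for every pipeline stage.

The central fixture is a toy receptor–ligand complex with a known true pose:
a concave pocket whose wall is lined with methyl "probe" pseudo-residues
(playing the role of cavity-lining methyl-bearing residues such as Ile/Leu/
Val side chains), one surface probe and one distant outlier probe, and a
small rigid ligand — optionally with an exact two-fold symmetry axis, the
situation that motivates symmetry-aware pose RMSD.  NOE peak tables are
fabricated from the true interproton distances with the same thresholds the
calibration uses, so the generated restraints are self-consistent: the true
pose violates none of them at zero noise.

Also provided: decoy poses, Gaussian-blob toy trajectories for clustering,
and a pocket-opening structure series for the cavity-openness coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .docking import Pose, random_rotation
from .restraints import (CalibrationTable, NoePeak, ProtonGroup,
                         calibrate_peaks, effective_distance)
from .selection import LigandSymmetry
from .structure import Atom, RigidTransform, Structure, rmsd_no_fit, vdw_radius_for

__all__ = ["ToyComplexSpec", "ToyComplex", "make_toy_complex", "fabricate_noe_peaks",
           "make_decoy_poses", "make_toy_trajectory", "make_receptor_variants",
           "make_opening_series", "c2_symmetric_ligand", "asymmetric_ligand",
           "fabricated_restraints"]

_TET = math.radians(70.5)  # C–C–H cone half-angle for methyl proton placement


def _atom(serial: int, name: str, element: str, res_name: str, res_seq: int,
          chain: str, xyz, hetatm: bool = False) -> Atom:
    return Atom(serial=serial, name=name, element=element, res_name=res_name,
                res_seq=res_seq, chain=chain, xyz=np.asarray(xyz, float),
                vdw_radius=vdw_radius_for(element), hetatm=hetatm)


# ---------------------------------------------------------------------------
# ligand templates
# ---------------------------------------------------------------------------


def _ring_positions(radius: float = 1.4) -> np.ndarray:
    ang = np.deg2rad(np.arange(6) * 60.0)
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)])


def c2_symmetric_ligand() -> tuple[Structure, dict[str, ProtonGroup], LigandSymmetry]:
    """Planar six-ring with a hydroxyl on the C1–C4 axis: exact C2 symmetry.

    The symmetry axis is the x axis through C1, C4 and O; the flip maps
    C2↔C6, C3↔C5 (and their protons), leaving the axis atoms fixed.  Proton
    groups: the two degenerate aromatic pairs (each with two distinct bonded
    carbons) and the hydroxyl proton.
    """
    ring = _ring_positions()
    atoms: list[Atom] = []
    serial = 1
    for i, xyz in enumerate(ring, start=1):
        atoms.append(_atom(serial, f"C{i}", "C", "LIG", 1, "L", xyz, hetatm=True))
        serial += 1
    o_xyz = ring[0] + np.array([1.36, 0.0, 0.0])
    atoms.append(_atom(serial, "O1", "O", "LIG", 1, "L", o_xyz, hetatm=True)); serial += 1
    # ring protons on C2, C3, C5, C6 (C1 carries O, C4 is bare on the axis)
    for i in (2, 3, 5, 6):
        direction = ring[i - 1] / np.linalg.norm(ring[i - 1])
        atoms.append(_atom(serial, f"H{i}", "H", "LIG", 1, "L",
                           ring[i - 1] + 1.09 * direction, hetatm=True))
        serial += 1
    atoms.append(_atom(serial, "HO1", "H", "LIG", 1, "L",
                       o_xyz + np.array([0.97, 0.0, 0.0]), hetatm=True))
    ligand = Structure(atoms=atoms, label="toy-ligand-c2")
    groups = {
        "L_H26": ProtonGroup("L_H26", ("H2", "H6"), ("C2", "C6"), "ligand"),
        "L_H35": ProtonGroup("L_H35", ("H3", "H5"), ("C3", "C5"), "ligand"),
        "L_HO1": ProtonGroup("L_HO1", ("HO1",), ("O1",), "ligand"),
    }
    symmetry = LigandSymmetry(("C1", "C4", "O1"))
    return ligand, groups, symmetry


def asymmetric_ligand() -> tuple[Structure, dict[str, ProtonGroup], LigandSymmetry]:
    """Six-ring with hydroxyl on C1 and a methyl on C3: no symmetry axis."""
    ring = _ring_positions()
    atoms: list[Atom] = []
    serial = 1
    for i, xyz in enumerate(ring, start=1):
        atoms.append(_atom(serial, f"C{i}", "C", "LIG", 1, "L", xyz, hetatm=True))
        serial += 1
    o_xyz = ring[0] + np.array([1.36, 0.0, 0.0])
    atoms.append(_atom(serial, "O1", "O", "LIG", 1, "L", o_xyz, hetatm=True)); serial += 1
    c3_dir = ring[2] / np.linalg.norm(ring[2])
    c7 = ring[2] + 1.50 * c3_dir
    atoms.append(_atom(serial, "C7", "C", "LIG", 1, "L", c7, hetatm=True)); serial += 1
    for i in (2, 5, 6):
        direction = ring[i - 1] / np.linalg.norm(ring[i - 1])
        atoms.append(_atom(serial, f"H{i}", "H", "LIG", 1, "L",
                           ring[i - 1] + 1.09 * direction, hetatm=True))
        serial += 1
    # methyl protons on C7 around the C3→C7 direction
    u, v = _orthobasis(c3_dir)
    for k in range(3):
        ang = 2.0 * math.pi * k / 3.0
        direction = (math.cos(_TET) * c3_dir
                     + math.sin(_TET) * (math.cos(ang) * u + math.sin(ang) * v))
        atoms.append(_atom(serial, f"H7{k + 1}", "H", "LIG", 1, "L",
                           c7 + 1.09 * direction, hetatm=True))
        serial += 1
    atoms.append(_atom(serial, "HO1", "H", "LIG", 1, "L",
                       o_xyz + np.array([0.97, 0.0, 0.0]), hetatm=True))
    ligand = Structure(atoms=atoms, label="toy-ligand-asym")
    groups = {
        "L_H2": ProtonGroup("L_H2", ("H2",), ("C2",), "ligand"),
        "L_H56": ProtonGroup("L_H56", ("H5", "H6"), ("C5", "C6"), "ligand"),
        "L_ME7": ProtonGroup("L_ME7", ("H71", "H72", "H73"), ("C7", "C7", "C7"), "ligand"),
        "L_HO1": ProtonGroup("L_HO1", ("HO1",), ("O1",), "ligand"),
    }
    symmetry = LigandSymmetry.all_heavy(ligand)
    return ligand, groups, symmetry


def _orthobasis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    helper = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    return u, np.cross(d, u)


# ---------------------------------------------------------------------------
# toy complex
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyComplexSpec:
    n_pocket_probes: int = 8
    pocket_radius: float = 6.0
    ligand_template: str = "c2_symmetric"
    peak_noise_rate: float = 0.0
    n_wall_atoms: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pocket_probes < 4:
            raise ValueError("need at least 4 pocket probes")
        if not (0.0 <= self.peak_noise_rate <= 0.5):
            raise ValueError("peak noise rate must be in [0, 0.5]")
        if self.ligand_template not in ("c2_symmetric", "asymmetric"):
            raise ValueError("ligand_template must be c2_symmetric|asymmetric")


@dataclass
class ToyComplex:
    receptor: Structure
    ligand: Structure  # template, at the origin in canonical orientation
    true_pose: RigidTransform
    noe_peaks: list[NoePeak]
    site_labels: dict[int, str]
    proton_groups: dict[str, ProtonGroup] = field(default_factory=dict)
    symmetry: LigandSymmetry | None = None
    spec: ToyComplexSpec | None = None

    @property
    def true_ligand(self) -> Structure:
        return self.ligand.with_coords(self.true_pose.apply(self.ligand.coords))

    @property
    def probe_residues(self) -> list[int]:
        return sorted(r for r, s in self.site_labels.items() if s == "cavity")


def _cap_directions(n: int, z_max: float = 0.25) -> np.ndarray:
    """Quasi-uniform directions on the spherical cap z <= z_max (golden spiral)."""
    from .sasa import sphere_lattice

    # oversample the full sphere, keep the cap, then thin to n
    m = max(4 * n, 64)
    pts = sphere_lattice(m)
    cap = pts[pts[:, 2] <= z_max]
    stride = max(1, len(cap) // n)
    chosen = cap[::stride][:n]
    if len(chosen) < n:  # pad from remaining cap points
        extra = [p for p in cap if not any(np.allclose(p, c) for c in chosen)]
        chosen = np.vstack([chosen, extra[: n - len(chosen)]])
    return chosen[:n]


def _probe_residue(res_seq: int, direction: np.ndarray, radius: float,
                   serial0: int, res_name: str = "PRB") -> list[Atom]:
    """A methyl-bearing pseudo-residue: CA anchor, CB, methyl CG + 3 protons."""
    d = direction / np.linalg.norm(direction)
    cg = radius * d
    cb = (radius + 1.5) * d
    ca = (radius + 3.0) * d
    atoms = [
        _atom(serial0, "CA", "C", res_name, res_seq, "A", ca),
        _atom(serial0 + 1, "CB", "C", res_name, res_seq, "A", cb),
        _atom(serial0 + 2, "CG", "C", res_name, res_seq, "A", cg),
    ]
    u, v = _orthobasis(-d)  # methyl protons fan toward the pocket centre
    for k in range(3):
        ang = 2.0 * math.pi * k / 3.0
        hdir = (math.cos(_TET) * (-d)
                + math.sin(_TET) * (math.cos(ang) * u + math.sin(ang) * v))
        atoms.append(_atom(serial0 + 3 + k, f"HG{k + 1}", "H", res_name, res_seq,
                           "A", cg + 1.09 * hdir))
    return atoms


def make_toy_complex(spec: ToyComplexSpec | None = None) -> ToyComplex:
    """Build a deterministic toy pocket complex with fabricated NOE peaks.

    Probes sit on a spherical cap of the pocket wall around the true ligand
    placement; a surface probe near the pocket mouth and a far outlier probe
    carry matching site labels.  Peaks are fabricated from the true pose, so
    at zero noise the derived restraints are exactly satisfied by it.
    """
    spec = spec or ToyComplexSpec()
    rng = np.random.default_rng(spec.seed)

    if spec.ligand_template == "c2_symmetric":
        ligand, lig_groups, symmetry = c2_symmetric_ligand()
    else:
        ligand, lig_groups, symmetry = asymmetric_ligand()

    lig_extent = float(np.max(np.linalg.norm(ligand.heavy().coords, axis=1)))
    if lig_extent + 0.8 * (1.7 + 1.7) >= spec.pocket_radius:
        raise ValueError(
            f"ligand (extent {lig_extent:.1f} Å) does not fit a pocket of radius "
            f"{spec.pocket_radius:.1f} Å with van der Waals clearance")

    # true pose: seeded orientation, small off-centre shift within the pocket
    R0 = random_rotation(rng)
    t0 = 0.4 * rng.standard_normal(3)
    t0 *= min(1.0, 0.6 / max(np.linalg.norm(t0), 1e-9))
    true_pose = RigidTransform(R0, t0)

    atoms: list[Atom] = []
    serial = 1
    groups = dict(lig_groups)
    site_labels: dict[int, str] = {}

    probe_dirs = _cap_directions(spec.n_pocket_probes)
    for i, d in enumerate(probe_dirs):
        res_seq = i + 1
        res_atoms = _probe_residue(res_seq, d, spec.pocket_radius, serial)
        atoms.extend(res_atoms)
        serial += len(res_atoms)
        site_labels[res_seq] = "cavity"
        groups[f"R_M{res_seq}"] = ProtonGroup(
            f"R_M{res_seq}", ("HG1", "HG2", "HG3"), ("CG", "CG", "CG"),
            "receptor", residue=res_seq)

    # surface probe near the pocket mouth (+z), close enough to see the ligand
    surf_seq = spec.n_pocket_probes + 1
    surf_dir = np.array([0.25, 0.0, 1.0])
    res_atoms = _probe_residue(surf_seq, surf_dir, spec.pocket_radius * 0.92,
                               serial, res_name="SRF")
    atoms.extend(res_atoms)
    serial += len(res_atoms)
    site_labels[surf_seq] = "surface"
    groups[f"R_M{surf_seq}"] = ProtonGroup(
        f"R_M{surf_seq}", ("HG1", "HG2", "HG3"), ("CG", "CG", "CG"),
        "receptor", residue=surf_seq)

    # distant outlier probe: labelled, but too far for any NOE
    out_seq = spec.n_pocket_probes + 2
    res_atoms = _probe_residue(out_seq, np.array([0.0, 1.0, 0.6]),
                               spec.pocket_radius * 2.5, serial, res_name="OUT")
    atoms.extend(res_atoms)
    serial += len(res_atoms)
    site_labels[out_seq] = "outlier"
    groups[f"R_M{out_seq}"] = ProtonGroup(
        f"R_M{out_seq}", ("HG1", "HG2", "HG3"), ("CG", "CG", "CG"),
        "receptor", residue=out_seq)

    # inert wall atoms densify the cap between probes
    wall_dirs = _cap_directions(spec.n_wall_atoms * 2, z_max=0.35)
    probe_cg = spec.pocket_radius * probe_dirs
    n_wall = 0
    for d in wall_dirs:
        if n_wall >= spec.n_wall_atoms:
            break
        pos = spec.pocket_radius * d
        if np.min(np.linalg.norm(probe_cg - pos, axis=1)) < 2.0:
            continue
        n_wall += 1
        res_seq = 900 + n_wall
        atoms.append(_atom(serial, "C", "C", "WAL", res_seq, "A", pos))
        serial += 1
        site_labels.setdefault(res_seq, "surface")

    receptor = Structure(atoms=atoms, label="toy-receptor")
    complex_ = ToyComplex(receptor=receptor, ligand=ligand, true_pose=true_pose,
                          noe_peaks=[], site_labels=site_labels,
                          proton_groups=groups, symmetry=symmetry, spec=spec)
    complex_.noe_peaks = fabricate_noe_peaks(complex_, CalibrationTable(),
                                             noise_rate=spec.peak_noise_rate,
                                             rng=rng)
    return complex_


def fabricate_noe_peaks(complex_: ToyComplex, table: CalibrationTable | None = None,
                        noise_rate: float = 0.0,
                        rng: np.random.Generator | None = None) -> list[NoePeak]:
    """Classify every (ligand group, receptor methyl) effective distance.

    d ≤ strong-upper → strong; ≤ medium-upper → medium; ≤ weak-upper → weak;
    beyond that no peak.  Optional misclassification noise moves a peak's
    class by ±1 level at the given rate.
    """
    table = table or CalibrationTable()
    rng = rng or np.random.default_rng(0)
    true_lig = complex_.true_ligand
    classes = ["strong", "medium", "weak"]
    peaks: list[NoePeak] = []
    lig_groups = [g for g in complex_.proton_groups.values() if g.owner == "ligand"]
    rec_groups = [g for g in complex_.proton_groups.values() if g.owner == "receptor"]
    for lg in lig_groups:
        lx = np.array([true_lig.atom_by_name(n).xyz for n in lg.proton_atom_names])
        for rg in rec_groups:
            rx = np.array([complex_.receptor.atom_by_name(n, rg.residue).xyz
                           for n in rg.proton_atom_names])
            d = effective_distance(lx, rx)
            if d <= table.upper("strong"):
                cls = 0
            elif d <= table.upper("medium"):
                cls = 1
            elif d <= table.upper("weak"):
                cls = 2
            else:
                continue
            if noise_rate > 0 and rng.random() < noise_rate:
                cls = min(2, max(0, cls + (1 if rng.random() < 0.5 else -1)))
            peaks.append(NoePeak(lg.id, rg.id, classes[cls]))
    return peaks


def make_decoy_poses(complex_: ToyComplex, n: int, min_rmsd_from_truth: float,
                     rng: np.random.Generator, max_tries: int = 10000) -> list[Pose]:
    """Random rigid placements at least ``min_rmsd_from_truth`` (symmetry-aware
    RMSD over the symmetry atom subset) away from the true pose."""
    if n < 1:
        raise ValueError("need n >= 1 decoys")
    sym = complex_.symmetry or LigandSymmetry.all_heavy(complex_.ligand)
    names = set(sym.rmsd_atom_names)
    idx = [i for i, a in enumerate(complex_.ligand.atoms) if a.name in names]
    template = complex_.ligand.coords
    true_sym = complex_.true_pose.apply(template)[idx]
    center = complex_.true_pose.apply(template).mean(axis=0)
    decoys: list[Pose] = []
    tries = 0
    while len(decoys) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} decoys ≥ {min_rmsd_from_truth} Å from truth "
                f"within {max_tries} samples")
        R = random_rotation(rng)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        target = center + (2.5 * rng.random()) * direction
        t = target - R @ template.mean(axis=0)
        pose = Pose(transform=RigidTransform(R, t))
        if rmsd_no_fit(pose.transform.apply(template)[idx], true_sym) >= min_rmsd_from_truth:
            decoys.append(pose)
    return decoys


def make_receptor_variants(complex_: ToyComplex, n: int, sigma: float = 0.15,
                           seed: int = 0) -> list[Structure]:
    """The toy receptor plus n−1 jittered copies (a stand-in conformational
    ensemble).  Heavy-atom jitter is Gaussian with the given σ (Å)."""
    rng = np.random.default_rng(seed)
    variants = [complex_.receptor]
    for _ in range(n - 1):
        xyz = complex_.receptor.coords + sigma * rng.standard_normal((len(complex_.receptor), 3))
        variants.append(complex_.receptor.with_coords(xyz))
    return variants


def make_toy_trajectory(n_blobs: int, frames_per_blob: int, blob_sigma: float,
                        seed: int = 0, n_atoms: int = 20,
                        min_separation: float | None = None):
    """Frames drawn from well-separated Gaussian blobs around base conformations.

    Blob base conformations are pushed apart until every pairwise superposed
    RMSD exceeds the separation floor (at least 4·blob_sigma; default also
    ≥ 5 Å so a 2 Å quality threshold recovers the generating blobs exactly).
    Returns (FrameSet, labels).
    """
    from .ensemble import FrameSet
    from .structure import superpose

    if min_separation is None:
        min_separation = max(4.0 * blob_sigma, 5.0)
    min_separation = max(min_separation, 4.0 * blob_sigma)
    rng = np.random.default_rng(seed)
    base = 4.0 * rng.standard_normal((n_atoms, 3))
    scale = max(min_separation, 1.0)
    while True:
        bases = [base + scale * rng.standard_normal((n_atoms, 3)) for _ in range(n_blobs)]
        ok = True
        for i in range(n_blobs):
            for j in range(i + 1, n_blobs):
                if superpose(bases[i], bases[j])[1] <= min_separation:
                    ok = False
        if ok:
            break
        scale *= 1.5

    proto = Structure([
        _atom(i + 1, "CA", "C", "GLY", i + 1, "A", base[i]) for i in range(n_atoms)
    ], label="toy-traj")
    frames, labels = [], []
    for b in range(n_blobs):
        for _ in range(frames_per_blob):
            xyz = bases[b] + blob_sigma * rng.standard_normal((n_atoms, 3))
            frames.append(proto.with_coords(xyz))
            labels.append(b)
    return FrameSet(frames=frames, labels=labels), labels


def make_opening_series(n_frames: int = 10, seed: int = 0) -> list[Structure]:
    """A structure series along a pocket-opening pathway.

    A core of "cavity" residues is wrapped in a shell of blocker atoms; each
    successive frame removes more of the shell over the core, so the summed
    cavity SASA is non-decreasing along the series (removing occluders never
    lowers SASA).
    """
    from .sasa import sphere_lattice

    rng = np.random.default_rng(seed)
    core = 1.5 * rng.standard_normal((6, 3))
    shell = 5.0 * sphere_lattice(80)
    order = np.argsort(shell[:, 2])[::-1]  # open from the top down
    frames = []
    for k in range(n_frames):
        n_removed = int(round(k * len(shell) * 0.6 / max(1, n_frames - 1)))
        keep = np.ones(len(shell), dtype=bool)
        keep[order[:n_removed]] = False
        atoms = [_atom(i + 1, "CA", "C", "CAV", i + 1, "A", core[i])
                 for i in range(len(core))]
        serial = len(core) + 1
        for j, xyz in enumerate(shell[keep]):
            atoms.append(_atom(serial, "C", "C", "SHL", 500 + j, "A", xyz))
            serial += 1
        frames.append(Structure(atoms=atoms, label=f"opening-{k}"))
    return frames


def fabricated_restraints(complex_: ToyComplex,
                          table: CalibrationTable | None = None):
    """Calibrated interproton restraints of the complex's fabricated peaks."""
    return calibrate_peaks(complex_.noe_peaks, complex_.proton_groups,
                           table or CalibrationTable())
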