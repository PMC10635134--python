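"""Atoms, structures, PDB I/O and rigid-body geometry.

This module is the geometric substrate for the whole pipeline: a flat,
order-preserving atom container read from / written to fixed-width PDB
records, plus proper rigid transforms, Kabsch superposition and RMSD.

Structures here are deliberately simple — an ordered list of atoms with
author residue numbering taken verbatim from the file (ARNT PAS-B style
numbering such as 356–470 is kept as-is, no renumbering).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "RigidTransform",
    "BONDI_RADII",
    "read_pdb",
    "read_pdb_models",
    "write_pdb",
    "select_atoms",
    "superpose",
    "rmsd_no_fit",
]

#: Bondi van der Waals radii (Å) by element symbol; 1.7 Å fallback for
#: anything not listed.  Overridable wherever a radius table is accepted.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

DEFAULT_VDW_RADIUS = 1.70


def _element_from_name(name: str) -> str:
    """Infer the element symbol from a PDB atom name.

    Strips digits and primes; two-letter elements (CL, BR, ...) are only
    recognised when the stripped name matches one exactly, otherwise the
    first letter wins (so "CA" is carbon, "HG12" is hydrogen).
    """
    stripped = "".join(ch for ch in name.strip() if ch.isalpha()).upper()
    if not stripped:
        return ""
    if stripped in BONDI_RADII and len(stripped) == 2:
        return stripped
    return stripped[0]


def vdw_radius_for(element: str, table: dict[str, float] | None = None) -> float:
    table = BONDI_RADII if table is None else table
    return table.get(element.upper(), DEFAULT_VDW_RADIUS)


@dataclass
class Atom:
    """One atom of a structure, in Å.

    ``res_seq`` is the author residue number and may be any integer.
    ``hetatm`` records whether the source line was a HETATM record;
    parsing and selection treat both record types identically.
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    xyz: np.ndarray
    vdw_radius: float = DEFAULT_VDW_RADIUS
    hetatm: bool = False

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.serial} {self.name}: non-finite coordinates")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial} {self.name}: vdw radius must be > 0")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    def copy(self) -> "Atom":
        return replace(self, xyz=self.xyz.copy())


@dataclass
class Structure:
    """Ordered atom list; order is preserved across read/write round-trips."""

    atoms: list[Atom] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials within structure")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array (a copy)."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def with_coords(self, xyz: np.ndarray, label: str | None = None) -> "Structure":
        """Same atoms with replaced coordinates (used to realise poses)."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate array shape {xyz.shape} != ({len(self.atoms)}, 3)")
        atoms = [replace(a, xyz=xyz[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms=atoms, label=self.label if label is None else label)

    def copy(self) -> "Structure":
        return Structure(atoms=[a.copy() for a in self.atoms], label=self.label)

    def residue_numbers(self) -> list[int]:
        """Distinct residue numbers in first-appearance order."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.res_seq, None)
        return list(seen)

    def heavy(self) -> "Structure":
        return Structure([a for a in self.atoms if not a.is_hydrogen], label=self.label)

    def centroid(self) -> np.ndarray:
        if not self.atoms:
            raise ValueError("centroid of empty structure")
        return self.coords.mean(axis=0)

    def atom_by_name(self, name: str, res_seq: int | None = None) -> Atom:
        for a in self.atoms:
            if a.name == name and (res_seq is None or a.res_seq == res_seq):
                return a
        where = f" in residue {res_seq}" if res_seq is not None else ""
        raise KeyError(f"atom {name!r} not found{where} in structure {self.label!r}")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform x ↦ R x + t (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal (RᵀR ≠ I within 1e-9)")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-9):
            raise ValueError("improper rotation (det R ≠ +1): reflections are not allowed")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec: Sequence[float], translation: Sequence[float] = (0, 0, 0)) -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        return cls(Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(), np.asarray(translation, float))

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


class PDBParseError(ValueError):
    """Raised on malformed PDB records; message names the offending line."""


# ---------------------------------------------------------------------------
# PDB I/O.  Parsing goes through Biopython (strict mode reports line numbers);
# writing is a fixed-width wwPDB v3.3 formatter so round-trips are exact to
# the format's 3-decimal coordinate precision.
# ---------------------------------------------------------------------------


def _biopython_models(path: str | Path):
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure(Path(path).stem, str(path))
    except PDBConstructionException as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    return structure


def _model_to_structure(model, label: str) -> Structure:
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            hetflag, res_seq, icode = residue.id
            for atom in residue:
                if atom.is_disordered():
                    # keep only blank/'A' altLocs, drop the rest with a warning
                    kept = None
                    for alt in atom.disordered_get_list():
                        if alt.get_altloc() in (" ", "A"):
                            kept = alt
                            break
                    if kept is None:
                        warnings.warn(
                            f"dropping all altLocs of atom {atom.get_id()} in residue {res_seq}")
                        continue
                    warnings.warn(
                        f"keeping altLoc {kept.get_altloc()!r} of atom {atom.get_id()} in residue {res_seq}")
                    atom = kept
                elif atom.get_altloc() not in (" ", "A"):
                    warnings.warn(
                        f"dropping altLoc {atom.get_altloc()!r} atom {atom.get_id()} in residue {res_seq}")
                    continue
                name = atom.get_name()
                element = (atom.element or "").strip().upper() or _element_from_name(name)
                atoms.append(Atom(
                    serial=atom.get_serial_number(),
                    name=name,
                    element=element,
                    res_name=residue.get_resname().strip(),
                    res_seq=int(res_seq),
                    chain=str(chain.id)[:1] or " ",
                    xyz=np.asarray(atom.get_coord(), dtype=float),
                    vdw_radius=vdw_radius_for(element),
                    hetatm=(hetflag.strip() != ""),
                ))
    return Structure(atoms=atoms, label=label)


def read_pdb(path: str | Path) -> Structure:
    """Read ATOM/HETATM records of the first model of a PDB file.

    Raises :class:`PDBParseError` (naming the line) on malformed coordinate
    fields and ``ValueError`` on a structure containing no atoms.
    """
    models = read_pdb_models(path)
    return models[0]


def read_pdb_models(path: str | Path) -> list[Structure]:
    """Read every MODEL of a PDB file as a separate :class:`Structure`."""
    bio = _biopython_models(path)
    label = Path(path).stem
    models = [_model_to_structure(m, label=label if len(bio) == 1 else f"{label}:model{m.id}")
              for m in bio]
    models = [m for m in models if len(m) > 0]
    if not models:
        raise ValueError(f"{path}: no atoms found (empty structure)")
    return models


def _format_atom_name(name: str, element: str) -> str:
    # one-letter elements with short names are right-shifted by one column
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def pdb_atom_line(atom: Atom) -> str:
    record = "HETATM" if atom.hetatm else "ATOM  "
    name = _format_atom_name(atom.name, atom.element)
    return (
        f"{record}{atom.serial:5d} {name}"
        f" {atom.res_name:>3s} {atom.chain:1s}{atom.res_seq:4d}    "
        f"{atom.xyz[0]:8.3f}{atom.xyz[1]:8.3f}{atom.xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
    )


def write_pdb(structure: Structure | Iterable[Structure], path: str | Path) -> None:
    """Write one structure (or an iterable of models) as fixed-width PDB."""
    models = [structure] if isinstance(structure, Structure) else list(structure)
    buf = io.StringIO()
    multi = len(models) > 1
    for i, model in enumerate(models, start=1):
        if multi:
            buf.write(f"MODEL     {i:4d}\n")
        for atom in model.atoms:
            buf.write(pdb_atom_line(atom) + "\n")
        if multi:
            buf.write("ENDMDL\n")
    buf.write("END\n")
    Path(path).write_text(buf.getvalue())


def select_atoms(structure: Structure,
                 residue_numbers: Iterable[int] | None = None,
                 atom_names: Iterable[str] | None = None) -> Structure:
    """Order-preserving subset by residue number and/or atom name.

    An empty selection is valid and returns an empty structure.
    """
    resi = None if residue_numbers is None else set(residue_numbers)
    names = None if atom_names is None else set(atom_names)
    atoms = [a for a in structure.atoms
             if (resi is None or a.res_seq in resi)
             and (names is None or a.name in names)]
    return Structure(atoms=[a.copy() for a in atoms], label=structure.label)


def superpose(mobile_xyz: np.ndarray, reference_xyz: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares proper-rotation superposition (Kabsch).

    Returns the transform mapping the mobile point set onto the reference
    and the post-fit RMSD.  Reflections are excluded by the determinant
    correction, so a mirror image fits with a non-zero residual.
    """
    mob = np.asarray(mobile_xyz, dtype=float)
    ref = np.asarray(reference_xyz, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError(f"point sets must be matching (n, 3) arrays, got {mob.shape} vs {ref.shape}")
    n = mob.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    P, Q = mob - mc, ref - rc
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    transform = RigidTransform(R, t)
    fitted = transform.apply(mob)
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return transform, rmsd


def rmsd_no_fit(xyz_a: np.ndarray, xyz_b: np.ndarray) -> float:
    """Root-mean-square deviation without superposition."""
    a = np.atleast_2d(np.asarray(xyz_a, dtype=float))
    b = np.atleast_2d(np.asarray(xyz_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"coordinate arrays differ in shape: {a.shape} vs {b.shape}")
    if a.shape[0] < 1:
        raise ValueError("rmsd of empty point sets")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
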