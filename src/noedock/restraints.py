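"""NOE distance restraints: calibration, heavy-atom extension, evaluation.

Classified NOESY cross-peak intensities become interproton distance bounds
(strong/medium/weak → 2.8/3.5/5.0 Å upper limits, 1.8 Å van-der-Waals lower
limit).  Peaks on cavity-lining methyl residues define the docking "active"
residue set.  Interproton restraints are expanded to inter-heavy-atom
distances by adding 1 Å for the two C–H bonds, with chemically equivalent
(degenerate) protons enumerated as separate heavy-atom alternatives.
Evaluation uses the r⁻⁶-summed effective distance of ambiguous interaction
restraints, which reduces to the plain distance for singleton groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .structure import Structure, select_atoms

__all__ = [
    "ProtonGroup",
    "NoePeak",
    "CalibrationTable",
    "AtomGroup",
    "DistanceRestraint",
    "ActiveResidueSet",
    "Violation",
    "ViolationReport",
    "calibrate_peaks",
    "derive_active_residues",
    "extend_to_heavy_atoms",
    "effective_distance",
    "evaluate_violations",
    "ensemble_satisfaction",
    "read_peak_table",
    "read_proton_groups",
    "read_site_labels",
    "write_restraint_tsv",
    "cns_restraint_block",
]

INTENSITY_CLASSES = ("strong", "medium", "weak")


@dataclass(frozen=True)
class ProtonGroup:
    """A group of chemically equivalent protons and their bonded heavy atoms.

    ``proton_atom_names[i]`` is bonded to ``heavy_atom_names[i]``; a methyl
    group lists the same carbon three times, a degenerate aromatic pair lists
    two distinct carbons.
    """

    id: str
    proton_atom_names: tuple[str, ...]
    heavy_atom_names: tuple[str, ...]
    owner: str  # "ligand" | "receptor"
    residue: int | None = None

    def __post_init__(self) -> None:
        if not self.proton_atom_names:
            raise ValueError(f"proton group {self.id}: empty proton list")
        if len(self.proton_atom_names) != len(self.heavy_atom_names):
            raise ValueError(f"proton group {self.id}: proton/heavy lists differ in length")
        if self.owner not in ("ligand", "receptor"):
            raise ValueError(f"proton group {self.id}: owner must be ligand|receptor")

    @property
    def distinct_heavy_atoms(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for h in self.heavy_atom_names:
            seen.setdefault(h, None)
        return tuple(seen)


@dataclass(frozen=True)
class NoePeak:
    ligand_group: str
    receptor_group: str
    intensity_class: str

    def __post_init__(self) -> None:
        if self.intensity_class not in INTENSITY_CLASSES:
            raise ValueError(
                f"unknown intensity class {self.intensity_class!r}; expected one of {INTENSITY_CLASSES}")


@dataclass(frozen=True)
class CalibrationTable:
    """Upper distance limits per peak class and the common lower limit (Å)."""

    upper_by_class: Mapping[str, float] = field(
        default_factory=lambda: {"strong": 2.8, "medium": 3.5, "weak": 5.0})
    lower: float = 1.8

    def __post_init__(self) -> None:
        u = self.upper_by_class
        if not (u["strong"] < u["medium"] < u["weak"]):
            raise ValueError("calibration uppers must strictly increase strong < medium < weak")
        if not all(self.lower < u[c] for c in INTENSITY_CLASSES):
            raise ValueError("lower limit must be below every upper limit")

    def upper(self, intensity_class: str) -> float:
        try:
            return float(self.upper_by_class[intensity_class])
        except KeyError:
            raise ValueError(f"unknown intensity class {intensity_class!r}") from None


@dataclass(frozen=True)
class AtomGroup:
    """Named atom set on one side of a restraint (evaluation unit)."""

    owner: str
    atom_names: tuple[str, ...]
    residue: int | None = None

    def __post_init__(self) -> None:
        if not self.atom_names:
            raise ValueError("empty restraint atom group")


@dataclass(frozen=True)
class DistanceRestraint:
    """A lower/upper distance bound between two atom groups.

    ``level`` is "interproton" (groups are proton names) or "heavy"
    (groups are the bonded heavy atoms, bounds extended by 1 Å).
    ``source_peak`` and the proton groups are carried for bookkeeping.
    """

    id: str
    group_a: AtomGroup  # ligand side
    group_b: AtomGroup  # receptor side
    lower: float
    upper: float
    level: str = "interproton"
    ligand_pg: ProtonGroup | None = None
    receptor_pg: ProtonGroup | None = None
    source_peak: NoePeak | None = None

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise ValueError(f"restraint {self.id}: bounds must satisfy 0 < lower < upper")
        if self.level not in ("interproton", "heavy"):
            raise ValueError(f"restraint {self.id}: level must be interproton|heavy")

    @property
    def receptor_residue(self) -> int | None:
        return self.group_b.residue


@dataclass(frozen=True)
class ActiveResidueSet:
    """Receptor residues driving ambiguous interaction restraints in docking."""

    residues: frozenset[int]
    ligand_id: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def sorted(self) -> list[int]:
        return sorted(self.residues)


@dataclass(frozen=True)
class Violation:
    restraint_id: str
    effective_distance: float
    violation: float
    satisfied: bool
    receptor_residue: int | None = None


@dataclass
class ViolationReport:
    records: list[Violation]
    tolerance: float

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def max_violation(self) -> float:
        return max((r.violation for r in self.records), default=0.0)

    @property
    def n_satisfied(self) -> int:
        return sum(r.satisfied for r in self.records)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([{
            "restraint_id": r.restraint_id,
            "receptor_residue": r.receptor_residue,
            "effective_distance": r.effective_distance,
            "violation": r.violation,
            "satisfied": r.satisfied,
        } for r in self.records])


# ---------------------------------------------------------------------------
# calibration and active residues
# ---------------------------------------------------------------------------


def calibrate_peaks(peaks: Sequence[NoePeak],
                    groups: Mapping[str, ProtonGroup],
                    table: CalibrationTable | None = None) -> list[DistanceRestraint]:
    """One interproton restraint per classified peak.

    Upper bound by intensity class, lower bound the 1.8 Å contact distance.
    """
    table = table or CalibrationTable()
    restraints = []
    for i, peak in enumerate(peaks):
        try:
            lig = groups[peak.ligand_group]
            rec = groups[peak.receptor_group]
        except KeyError as exc:
            raise ValueError(f"peak {i}: unknown proton group id {exc.args[0]!r}") from None
        restraints.append(DistanceRestraint(
            id=f"{peak.ligand_group}--{peak.receptor_group}",
            group_a=AtomGroup("ligand", tuple(dict.fromkeys(lig.proton_atom_names)), lig.residue),
            group_b=AtomGroup("receptor", tuple(dict.fromkeys(rec.proton_atom_names)), rec.residue),
            lower=table.lower,
            upper=table.upper(peak.intensity_class),
            level="interproton",
            ligand_pg=lig,
            receptor_pg=rec,
            source_peak=peak,
        ))
    return restraints


def derive_active_residues(peaks: Sequence[NoePeak],
                           groups: Mapping[str, ProtonGroup],
                           site_labels: Mapping[int, str],
                           ligand_id: str = "") -> ActiveResidueSet:
    """Residues with ≥1 peak that line the cavity.

    Surface- and outlier-labelled residues are excluded even when they carry
    peaks (they cannot anchor a cavity binding mode).
    """
    residues: set[int] = set()
    for peak in peaks:
        rec = groups[peak.receptor_group]
        if rec.residue is None:
            raise ValueError(f"receptor group {rec.id} has no residue number")
        if rec.residue not in site_labels:
            raise ValueError(f"residue {rec.residue} has no cavity/surface/outlier site label")
        if site_labels[rec.residue] == "cavity":
            residues.add(rec.residue)
    if not residues and peaks:
        warnings.warn("no cavity-labelled residues among the peaks; active set is empty")
    return ActiveResidueSet(frozenset(residues), ligand_id=ligand_id)


def extend_to_heavy_atoms(restraints: Sequence[DistanceRestraint]) -> list[DistanceRestraint]:
    """Expand interproton restraints to inter-heavy-atom distances (+1 Å).

    Each distinct (ligand heavy atom, receptor heavy atom) pair implied by the
    equivalent protons becomes its own distance; methyl groups collapse to
    their single carbon, a degenerate aromatic pair contributes one distance
    per ring carbon.  Both bounds are shifted by +1.0 Å for the two C–H bonds.
    """
    out: list[DistanceRestraint] = []
    for r in restraints:
        if r.level != "interproton":
            raise ValueError(f"restraint {r.id}: can only extend interproton restraints")
        if r.ligand_pg is None or r.receptor_pg is None:
            raise ValueError(f"restraint {r.id}: missing proton→heavy atom mapping")
        for ha in r.ligand_pg.distinct_heavy_atoms:
            for hb in r.receptor_pg.distinct_heavy_atoms:
                out.append(DistanceRestraint(
                    id=f"{r.id}:{ha}-{hb}",
                    group_a=AtomGroup("ligand", (ha,), r.group_a.residue),
                    group_b=AtomGroup("receptor", (hb,), r.group_b.residue),
                    lower=r.lower + 1.0,
                    upper=r.upper + 1.0,
                    level="heavy",
                    ligand_pg=r.ligand_pg,
                    receptor_pg=r.receptor_pg,
                    source_peak=r.source_peak,
                ))
    return out


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def effective_distance(xyz_group_a: np.ndarray, xyz_group_b: np.ndarray) -> float:
    """r⁻⁶-summed effective distance between two atom groups (Å).

    d_eff = (Σ_ij d_ij⁻⁶)^(−1/6); always ≤ the minimum pairwise distance and
    equal to it for singleton groups.
    """
    a = np.atleast_2d(np.asarray(xyz_group_a, dtype=float))
    b = np.atleast_2d(np.asarray(xyz_group_b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("effective distance of empty atom group")
    diff = a[:, None, :] - b[None, :, :]
    d2 = np.sum(diff * diff, axis=-1)
    if np.any(d2 <= 0.0):
        raise ValueError("coincident atoms (zero distance) in effective-distance evaluation")
    return float(np.sum(d2 ** -3) ** (-1.0 / 6.0))


def _resolve_group(group: AtomGroup, receptor: Structure, ligand: Structure) -> np.ndarray:
    src = ligand if group.owner == "ligand" else receptor
    if group.residue is not None and group.owner == "receptor":
        src = select_atoms(src, residue_numbers=[group.residue])
    coords = []
    missing = []
    for name in group.atom_names:
        matched = [a for a in src.atoms if a.name == name]
        if not matched:
            missing.append(name)
        else:
            coords.extend(a.xyz for a in matched)
    if missing:
        where = f"residue {group.residue}" if group.residue is not None else group.owner
        raise ValueError(f"unresolvable atom name(s) {missing} in {where}")
    return np.array(coords)


def evaluate_violations(restraints: Sequence[DistanceRestraint],
                        receptor: Structure,
                        pose_ligand: Structure,
                        tolerance: float = 0.3) -> ViolationReport:
    """Per-restraint effective distances and bound violations for one pose.

    violation = max(0, d_eff − upper, lower − d_eff); satisfied ⇔ ≤ tolerance.
    """
    records = []
    for r in restraints:
        xa = _resolve_group(r.group_a, receptor, pose_ligand)
        xb = _resolve_group(r.group_b, receptor, pose_ligand)
        d_eff = effective_distance(xa, xb)
        viol = max(0.0, d_eff - r.upper, r.lower - d_eff)
        records.append(Violation(
            restraint_id=r.id,
            effective_distance=d_eff,
            violation=viol,
            satisfied=viol <= tolerance,
            receptor_residue=r.receptor_residue,
        ))
    return ViolationReport(records=records, tolerance=tolerance)


def ensemble_satisfaction(restraints: Sequence[DistanceRestraint],
                          receptor: Structure,
                          pose_ligands: Sequence[Structure],
                          tolerance: float = 0.3) -> tuple[int, dict[int, bool], dict[str, bool]]:
    """Restraint satisfaction over a pose ensemble under the any-pose rule.

    A restraint counts satisfied if at least one pose satisfies it; a ligand
    adopting multiple orientations in a cavity can jointly cover restraints no
    single pose can.  Returns (n_satisfied, per-residue map, per-restraint map).
    """
    if not pose_ligands:
        raise ValueError("ensemble satisfaction needs at least one pose")
    per_restraint: dict[str, bool] = {r.id: False for r in restraints}
    for lig in pose_ligands:
        report = evaluate_violations(restraints, receptor, lig, tolerance)
        for rec in report:
            if rec.satisfied:
                per_restraint[rec.restraint_id] = True
    per_residue: dict[int, bool] = {}
    for r in restraints:
        resi = r.receptor_residue
        if resi is None:
            continue
        per_residue[resi] = per_residue.get(resi, False) or per_restraint[r.id]
    return sum(per_restraint.values()), per_residue, per_restraint


# ---------------------------------------------------------------------------
# file dialects
# ---------------------------------------------------------------------------


def read_proton_groups(path: str | Path) -> dict[str, ProtonGroup]:
    """Read a proton-group TSV: id, owner, residue, protons, heavy_atoms.

    ``protons`` and ``heavy_atoms`` are comma-separated parallel lists;
    ``residue`` is empty for ligand groups.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    groups: dict[str, ProtonGroup] = {}
    for _, row in df.iterrows():
        residue = int(row["residue"]) if str(row["residue"]).strip() else None
        pg = ProtonGroup(
            id=row["id"].strip(),
            proton_atom_names=tuple(s.strip() for s in row["protons"].split(",")),
            heavy_atom_names=tuple(s.strip() for s in row["heavy_atoms"].split(",")),
            owner=row["owner"].strip(),
            residue=residue,
        )
        if pg.id in groups:
            raise ValueError(f"duplicate proton group id {pg.id!r}")
        groups[pg.id] = pg
    return groups


def read_peak_table(path: str | Path) -> list[NoePeak]:
    """Read a peak TSV with columns ligand_group, receptor_group, class."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return [NoePeak(row["ligand_group"].strip(), row["receptor_group"].strip(),
                    row["class"].strip())
            for _, row in df.iterrows()]


def read_site_labels(path: str | Path) -> dict[int, str]:
    """Read residue→{cavity,surface,outlier} labels from a two-column TSV."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    labels = {}
    for _, row in df.iterrows():
        label = row["site"].strip()
        if label not in ("cavity", "surface", "outlier"):
            raise ValueError(f"unknown site label {label!r}")
        labels[int(row["residue"])] = label
    return labels


def write_restraint_tsv(restraints: Sequence[DistanceRestraint], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame([{
        "id": r.id,
        "level": r.level,
        "ligand_atoms": ",".join(r.group_a.atom_names),
        "receptor_residue": r.receptor_residue,
        "receptor_atoms": ",".join(r.group_b.atom_names),
        "lower": r.lower,
        "upper": r.upper,
    } for r in restraints]).to_csv(path, sep="\t", index=False)


def cns_restraint_block(restraints: Sequence[DistanceRestraint]) -> str:
    """Render restraints as CNS-style ``assign (…) d dminus dplus`` lines."""
    lines = []
    for r in restraints:
        sel_a = " or ".join(f"name {n}" for n in r.group_a.atom_names)
        resi_b = f"resid {r.receptor_residue} and " if r.receptor_residue is not None else ""
        sel_b = " or ".join(f"name {n}" for n in r.group_b.atom_names)
        d = r.upper
        dminus = r.upper - r.lower
        lines.append(f"assign (segid LIG and ({sel_a})) ({resi_b}({sel_b})) {d:.1f} {dminus:.1f} 0.0")
    return "\n".join(lines) + ("\n" if lines else "")
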