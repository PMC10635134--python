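"""End-to-end pipeline orchestration.

One config drives: restraint calibration → (optional toy weighted-ensemble
stage) → conformational-ensemble clustering → restrained rigid-body docking
→ symmetry-aware pose selection, writing per-stage artefacts, a selection
report and a run manifest.  Identical config + seed reproduce byte-identical
TSV/JSON outputs.

Two input modes: a fully synthetic toy complex (``toy:`` block) or explicit
files (``inputs:`` block with receptor/ligand PDBs and restraint TSVs).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import restraints as rst
from .docking import DockingConfig, dock_ensemble
from .ensemble import pairwise_rmsd_matrix, qt_cluster, representative_frames
from .selection import (LigandSymmetry, PoseMetric, SelectionConfig,
                        cluster_poses, rank_clusters, select_final_poses)
from .structure import Structure, read_pdb, read_pdb_models, write_pdb
from .synthetic import ToyComplexSpec, make_receptor_variants, make_toy_complex

__all__ = ["run_pipeline", "report", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _calibration_table(cfg: Mapping[str, Any]) -> rst.CalibrationTable:
    c = cfg.get("calibration", {})
    return rst.CalibrationTable(
        upper_by_class={"strong": c.get("strong", 2.8),
                        "medium": c.get("medium", 3.5),
                        "weak": c.get("weak", 5.0)},
        lower=c.get("lower", 1.8))


def _assemble_inputs(cfg: Mapping[str, Any], seed: int):
    """Returns (receptors, ligand, peaks, groups, site_labels, symmetry, center, truth)."""
    if "toy" in cfg:
        t = cfg["toy"]
        spec = ToyComplexSpec(
            n_pocket_probes=t.get("n_pocket_probes", 8),
            pocket_radius=t.get("pocket_radius", 6.0),
            ligand_template=t.get("ligand_template", "c2_symmetric"),
            peak_noise_rate=t.get("peak_noise_rate", 0.0),
            seed=t.get("seed", seed))
        complex_ = make_toy_complex(spec)
        receptors = make_receptor_variants(complex_, t.get("n_receptors", 2),
                                           sigma=t.get("receptor_jitter", 0.1),
                                           seed=spec.seed + 1)
        center = tuple(complex_.true_ligand.centroid())
        return (receptors, complex_.ligand, complex_.noe_peaks, complex_.proton_groups,
                complex_.site_labels, complex_.symmetry, center, complex_)
    inputs = cfg.get("inputs")
    if not inputs:
        raise PipelineError("config", "need a 'toy' or 'inputs' block")
    if "trajectory" in inputs:
        frames = []
        for p in inputs["trajectory"]:
            frames.extend(read_pdb_models(p))
        receptors = frames  # clustered to an ensemble below
    else:
        receptors = [read_pdb(p) for p in inputs["receptors"]]
    ligand = read_pdb(inputs["ligand"])
    peaks = rst.read_peak_table(inputs["peaks"])
    groups = rst.read_proton_groups(inputs["proton_groups"])
    site_labels = rst.read_site_labels(inputs["site_labels"])
    if "symmetry_atoms" in inputs:
        symmetry = LigandSymmetry(tuple(inputs["symmetry_atoms"]))
    else:
        symmetry = LigandSymmetry.all_heavy(ligand)
    center = inputs.get("sampling_center")
    return receptors, ligand, peaks, groups, site_labels, symmetry, center, None


def run_pipeline(config: Mapping[str, Any] | str | Path, output_dir: str | Path | None = None) -> dict:
    """Execute all stages and return (and write) the run manifest."""
    if not isinstance(config, Mapping):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    outdir = Path(output_dir or config.get("output_dir", "noedock_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": seed, "stages": {}, "counts": {}}

    # --- restraints stage -------------------------------------------------
    try:
        (receptors, ligand, peaks, groups, site_labels,
         symmetry, center, toy) = _assemble_inputs(config, seed)
        table = _calibration_table(config)
        interproton = rst.calibrate_peaks(peaks, groups, table)
        active = rst.derive_active_residues(peaks, groups, site_labels)
        heavy = rst.extend_to_heavy_atoms(interproton)
        rst.write_restraint_tsv(interproton, outdir / "restraints_interproton.tsv")
        rst.write_restraint_tsv(heavy, outdir / "restraints_heavy.tsv")
        (outdir / "restraints_heavy.cns").write_text(rst.cns_restraint_block(heavy))
        manifest["counts"].update({
            "peaks": len(peaks),
            "interproton_restraints": len(interproton),
            "heavy_restraints": len(heavy),
            "active_residues": len(active),
        })
        manifest["active_residues"] = active.sorted()
        manifest["stages"]["restraints"] = {
            "hash": _sha256(outdir / "restraints_interproton.tsv")}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("restraints", str(exc)) from exc

    # --- conformational ensemble stage ------------------------------------
    try:
        ens_cfg = config.get("ensemble", {})
        radius = float(ens_cfg.get("radius", 2.0))
        if len(receptors) > ens_cfg.get("max_receptors", 12):
            matrix = pairwise_rmsd_matrix(receptors)
            clusters = qt_cluster(matrix, radius)
            receptors = representative_frames(receptors, clusters)
            manifest["counts"]["trajectory_clusters"] = clusters.n_clusters
        manifest["counts"]["receptor_conformations"] = len(receptors)
        write_pdb(receptors, outdir / "receptor_ensemble.pdb")
        manifest["stages"]["ensemble"] = {"hash": _sha256(outdir / "receptor_ensemble.pdb")}
    except Exception as exc:
        raise PipelineError("ensemble", str(exc)) from exc

    # --- docking stage -----------------------------------------------------
    try:
        d = config.get("docking", {})
        if center is None:
            # fall back to the centroid of the active residues' side chains
            pts = []
            for r in receptors[:1]:
                for a in r.atoms:
                    if a.res_seq in active.residues and not a.is_hydrogen:
                        pts.append(a.xyz)
            center = tuple(np.mean(pts, axis=0)) if pts else (0.0, 0.0, 0.0)
        dconfig = DockingConfig(
            n_poses_per_conformation=d.get("n_poses_per_conformation", 1000),
            sampling_center=tuple(float(x) for x in center),
            sampling_radius=d.get("sampling_radius", 2.0),
            w_air=d.get("w_air", 1.0),
            w_steric=d.get("w_steric", 1.0),
            max_minimizer_evals=d.get("max_minimizer_evals", 150),
            seed=seed)
        poses = dock_ensemble(receptors, ligand, active, dconfig, restraints=interproton)
        manifest["counts"]["poses_total"] = len(poses)
        with open(outdir / "poses.tsv", "w") as fh:
            fh.write("pose\treceptor\tscore\te_air\te_steric\n")
            for i, p in enumerate(poses):
                fh.write(f"{i}\t{p.receptor_index}\t{p.score:.6f}\t{p.e_air:.6f}\t{p.e_steric:.6f}\n")
        manifest["stages"]["docking"] = {"hash": _sha256(outdir / "poses.tsv")}
    except Exception as exc:
        raise PipelineError("docking", str(exc)) from exc

    # --- selection stage ---------------------------------------------------
    try:
        s = config.get("selection", {})
        sconfig = SelectionConfig(
            cluster_cutoff=s.get("cluster_cutoff", 1.5),
            violation_tolerance=s.get("violation_tolerance", 0.3),
            rank_top_k=s.get("rank_top_k", 4))
        keep = min(len(poses), int(s.get("n_poses_to_cluster", 1000)))
        top = poses[:keep]
        metric = PoseMetric(receptors, ligand, symmetry)
        pclusters = cluster_poses(top, metric, sconfig)
        order = rank_clusters(pclusters, top, sconfig)
        selection = select_final_poses(order, pclusters, top, interproton,
                                       receptors, ligand, sconfig)
        manifest["counts"]["pose_clusters"] = pclusters.n_clusters
        manifest["counts"]["final_poses"] = len(selection.final_poses)
        manifest["selection"] = {
            "summary": selection.summary(),
            "n_restraints": selection.n_restraints,
            "n_restraints_satisfied": selection.n_restraints_satisfied,
            "n_residues": selection.n_residues,
            "n_residues_satisfied": selection.n_residues_satisfied,
            "dropped_by_violation": selection.n_dropped_by_violation,
            "cluster_order": [int(c) for c in selection.cluster_order],
            "restraints_satisfied": {k: bool(v) for k, v in
                                     sorted(selection.restraints_satisfied.items())},
            "residues_satisfied": {str(k): bool(v) for k, v in
                                   sorted(selection.residues_satisfied.items())},
        }
        final_dir = outdir / "final_poses"
        final_dir.mkdir(exist_ok=True)
        for k, p in enumerate(selection.final_poses):
            write_pdb([receptors[p.receptor_index], p.realize(ligand)],
                      final_dir / f"pose_{k}.pdb")
        with open(outdir / "selection_report.json", "w") as fh:
            json.dump(manifest["selection"], fh, indent=2, sort_keys=True)
        manifest["stages"]["selection"] = {"hash": _sha256(outdir / "selection_report.json")}
    except Exception as exc:
        raise PipelineError("selection", str(exc)) from exc

    if toy is not None:  # ground-truth diagnostics for synthetic runs
        sym_names = set(symmetry.rmsd_atom_names)
        idx = [i for i, a in enumerate(ligand.atoms) if a.name in sym_names]
        truth = toy.true_pose.apply(ligand.coords)[idx]
        from .structure import rmsd_no_fit
        rmsds = [float(rmsd_no_fit(p.transform.apply(ligand.coords)[idx], truth))
                 for p in selection.final_poses]
        manifest["truth_rmsd"] = {"best": min(rmsds) if rmsds else None,
                                  "per_pose": rmsds}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def report(manifest: Mapping[str, Any] | str | Path) -> str:
    """Human-readable run summary from a manifest (dict or JSON path)."""
    if not isinstance(manifest, Mapping):
        path = Path(manifest)
        if not path.exists():
            raise FileNotFoundError(f"manifest not found: {path}")
        manifest = json.loads(path.read_text())
    counts = manifest.get("counts", {})
    sel = manifest.get("selection", {})
    lines = [
        f"restraints: {counts.get('interproton_restraints', 0)} interproton "
        f"({counts.get('heavy_restraints', 0)} heavy-atom distances), "
        f"{counts.get('active_residues', 0)} active residues",
        f"receptor conformations: {counts.get('receptor_conformations', 0)}",
        f"poses docked: {counts.get('poses_total', 0)}; "
        f"clusters: {counts.get('pose_clusters', 0)}; "
        f"final poses: {counts.get('final_poses', 0)}",
    ]
    if counts.get("final_poses", 0) == 0:
        tol = sel.get("note", "0.3 Å")
        lines.append("no poses passed the 0.3 Å violation filter")
    else:
        lines.append(
            f"as an ensemble, the final poses satisfied "
            f"{sel.get('n_restraints_satisfied')} of {sel.get('n_restraints')} "
            f"restraints; {sel.get('n_residues_satisfied')} of "
            f"{sel.get('n_residues')} receptor residues")
    return "\n".join(lines)
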