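# noedock

NOE-restraint-guided ensemble docking of small molecules into protein
internal cavities, at desk scale.

Solution NMR can reveal that a ligand binds inside a buried, hydrated cavity
— such as the internal cavity of the ARNT PAS-B domain — through
intermolecular NOE cross-peaks between ligand protons and cavity-lining
methyl groups. Turning those sparse, qualitative contacts into a structural
model takes a chain of computational steps, each simple, none standard in a
single package:

1. **Restraint calibration** — classified NOESY intensities become
   interproton distance bounds (strong/medium/weak → 2.8/3.5/5.0 Å upper
   limits, 1.8 Å van-der-Waals lower limit), heavy-atom equivalents (+1 Å
   for the two C–H bonds, degenerate protons enumerated), and a set of
   "active" cavity residues for ambiguous interaction restraints (AIRs).
2. **Cavity-openness sampling** — a weighted-ensemble (WE) resampler with
   minimal adaptive binning drives a pluggable propagator along a progress
   coordinate: the Shrake–Rupley solvent-accessible surface area of the
   cavity-lining residues.
3. **Ensemble reduction** — quality-threshold (QT) clustering of a
   trajectory at a 2 Å heavy-atom RMSD radius, keeping each cluster's
   medoid as a docking receptor.
4. **Restrained rigid-body docking** — uniformly random orientations,
   AIR-guided scoring with the r⁻⁶-summed effective distance
   d_eff = (Σᵢⱼ d_ij⁻⁶)^(−1/6), soft-sphere sterics, and derivative-free
   rigid-body minimisation.
5. **Pose selection** — symmetry-aware ligand RMSD (axis atoms only for a
   C2-symmetric ligand), leader clustering at 1.5 Å, ranking by the mean
   score of each cluster's best four poses, one best pose per cluster, and
   a 0.3 Å NOE-violation filter, with "any-pose" ensemble restraint
   satisfaction reporting.

A first-class synthetic-data module builds ground-truth systems for every
stage — toy pocket complexes with fabricated NOE tables that the true pose
satisfies exactly, decoy poses, clustered toy trajectories, and a 1-D
double-well system for the WE sampler — so the whole pipeline is testable
without any structure download.

## Worked example

```python
from noedock.pipeline import run_pipeline, report

config = {
    "seed": 11,
    "toy": {"seed": 11, "ligand_template": "c2_symmetric", "n_receptors": 2},
    "docking": {"n_poses_per_conformation": 150, "max_minimizer_evals": 80},
    "selection": {"cluster_cutoff": 1.5, "violation_tolerance": 0.3},
}
manifest = run_pipeline(config, output_dir="toy_run")
print(report(manifest))
print("best symmetry-RMSD to truth:", round(manifest["truth_rmsd"]["best"], 2), "Å")
```

prints

```
restraints: 20 interproton (37 heavy-atom distances), 8 active residues
receptor conformations: 2
poses docked: 300; clusters: 10; final poses: 8
as an ensemble, the final poses satisfied 20 of 20 restraints; 9 of 9 receptor residues
best symmetry-RMSD to truth: 0.7 Å
```

Reading: the toy complex fabricated 20 NOE peaks from its known true pose;
calibration produced 20 interproton restraints (37 heavy-atom distances
after degenerate-proton expansion) and 8 active cavity residues; docking
produced 300 minimised poses; leader clustering gave 10 pose clusters, 8 of
whose best poses passed the 0.3 Å violation filter; jointly those final
poses satisfy every restraint, and the best of them sits 0.7 Å (axis-atom
RMSD) from the true placement.

The same stages run from the shell:

```sh
noedock synth --seed 7 --ligand c2_symmetric --out toy/
noedock info toy/receptor.pdb
noedock cavity-openness --pdb toy/receptor.pdb --residues 1,2,3
noedock run --config run.yaml --out out/
noedock report --manifest out/manifest.json
```

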