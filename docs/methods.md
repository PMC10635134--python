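# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of the `noedock` pipeline. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Restraint model

Classified NOESY cross-peak intensities are mapped to interproton distance
bounds: upper limits of 2.8, 3.5 and 5.0 Å for strong, medium and weak
peaks, with a universal 1.8 Å lower limit (van-der-Waals contact). The
three-level calibration is deliberately coarse; it reflects what qualitative
peak-intensity analysis supports, and the pipeline never pretends to more
precision than the class bands carry.

**Effective distance.** Group-to-group distances use the r⁻⁶-summed
effective distance d_eff = (Σᵢⱼ d_ij⁻⁶)^(−1/6), the standard form for
ambiguous interaction restraints. It is bounded above by the minimum
pairwise distance, reduces to the plain distance for singleton groups, and
decreases monotonically as atoms join a group. It is exactly invariant
under a ligand symmetry operation that permutes equivalent protons, which
keeps restraint energies consistent with the symmetry-aware pose RMSD.

**Heavy-atom expansion.** Each interproton restraint becomes one
inter-heavy-atom distance per distinct (ligand heavy atom, receptor heavy
atom) pair implied by its equivalent protons; methyl groups collapse to
their single carbon. Both bounds are shifted by +1.0 Å to account for the
two C–H bonds. Applying the shift to the lower bound as well as the upper
is a deliberate reading of "extending the distance": a pure upper-bound
shift would leave a heavy-atom pair allowed to sit closer than the proton
contact limit permits. With this convention the packaged example tables
expand 12 → 19 (KG-655) and 28 → 31 (KG-279) distances.

**Active residues.** Residues carrying at least one peak and labelled
*cavity* form the active set driving AIRs; *surface* and *outlier* labelled
residues are excluded even when they show NOEs, since they cannot anchor a
cavity binding mode. The packaged site labels yield 7 active residues for
KG-655 and 6 for KG-279 (L418 drops out).

**Violations.** violation = max(0, d_eff − upper, lower − d_eff); a
restraint is satisfied when its violation is at or below the tolerance
(default 0.3 Å, configurable). Ensemble satisfaction uses the any-pose
rule: a restraint counts satisfied if at least one pose of the final set
satisfies it. This is the reading under which a ligand adopting multiple
orientations within a cavity can jointly satisfy restraints that no single
pose can.

## Cavity-openness coordinate

Solvent-accessible surface area is computed by the Shrake–Rupley method on
a deterministic golden-spiral sphere lattice (default 960 points, probe
1.4 Å), so results are free of RNG dependence; the isolated-atom value is
exact (4π(r+p)²) and doubling the lattice density changes totals by <1%.
The openness coordinate sums per-atom SASA over the cavity-lining residues
(default: the 17 ARNT PAS-B cavity residues 363–461) evaluated in
whole-structure context. Heavy atoms only by default, because crystal
structures typically lack hydrogens; hydrogens can be included via
configuration. Radii are Bondi by element, 1.7 Å fallback.

## Weighted-ensemble sampler

Resampling follows the standard statistically exact scheme: after each
propagation interval of τ steps, each occupied bin is brought to exactly
the target walker count (default 8) — the heaviest walker of an
under-populated bin splits into equal-weight copies in one shot; the two
lightest walkers of an over-populated bin merge iteratively, the survivor
drawn with probability proportional to weight (equal weights: lowest index
survives, for reproducibility). Total weight is conserved to 1e-12 and
asserted every iteration.

Binning is minimal-adaptive: one bin is reserved for the current minimum
(lagging) walker and one for the maximum (leading) walker; the remaining
n_bins − 2 bins tile [min, max] linearly and are rebuilt every iteration.
An all-equal ensemble gets a symmetric ε-width layout. Defaults are 15
bins and 8 walkers per bin.

The propagator is pluggable and must be deterministic given (state, seed);
seeds are spawned per iteration and per walker from the master seed, so
runs are bit-reproducible. The packaged propagator is overdamped Langevin
dynamics on the double well U(x) = h((x/w)² − 1)² (defaults h = 4 kT,
w = 1), a desk-scale stand-in for a molecular-dynamics engine. Sampler
validation starts all walkers in one well and compares the stationary
occupancy of the other well against quadrature of e^(−U/kT) (3 standard
errors over 8 replicates; the validation runs use dt = 0.01, τ = 30 steps,
300 iterations, averaging the final 100 — about 10⁶ aggregate steps), and
compares the WE-weighted coordinate distribution against a long brute-force
Brownian run at matched aggregate time (Kolmogorov–Smirnov distance
< 0.05). No rate or flux machinery is implemented: the sampler's job here
is conformational coverage, not kinetics.

## Conformational-ensemble reduction

Quality-threshold clustering on the pairwise superposed heavy-atom RMSD
matrix: every unassigned frame proposes the cluster of all unassigned
frames within the radius (default 2 Å) of itself; the largest candidate is
committed (ties → lowest seed index); repeat. Every member is within the
radius of its cluster seed, and the procedure is deterministic. "Closest
to the centroid" is implemented as the RMSD-space medoid (member
minimising mean squared distance to the rest), since a coordinate-space
centroid is not a physical conformation. A 1-D reference-RMSD profile mode
is also provided, but pairwise mode is the default: QT needs a pairwise
metric, and a one-dimensional projection would alias distinct
conformations.

## Rigid-body docking

The docking stage is a deliberate minimal stand-in for a full docking
engine: its purpose is a ranking signal plus restraint energies, not a
physical binding energy.

- **Sampling**: orientation uniform over proper rotations (normalised
  random quaternion); ligand centroid uniform in a sphere (default 2 Å)
  around the cavity centre.
- **Score**: score = w_air·e_air + w_steric·e_steric (defaults 1, 1).
  e_air sums squared violations of ambiguous restraints: one AIR per
  active residue (whole ligand to side-chain heavy atoms, upper 5.0 Å —
  the weak-NOE contact limit) plus the calibrated interproton group
  restraints evaluated on the posed ligand. Including the NOE group
  restraints in the docking score is this package's design choice: the
  per-residue AIRs alone are orientation-degenerate inside a small pocket,
  and the group terms are what make restraint-guided docking actually
  orient the ligand. Because the r⁻⁶ group distance is invariant under the
  ligand's C2 flip, the two flip-related placements score identically, as
  they should. e_steric is a soft-sphere penalty Σ max(0, 0.8(rᵢ+rⱼ) − d)²
  over receptor–ligand heavy-atom pairs.
- **Minimisation**: Powell search over the 6 rigid degrees of freedom with
  a fixed evaluation budget (default 150); the ligand is never deformed and
  the returned score never exceeds the input score. The minimised objective
  carries a small regulariser (weight 1e-3) pulling each NOE group distance
  toward the midpoint of its intensity-class distance band; inside the
  zero-violation region the score surface is flat, and the regulariser
  selects the least-squares point estimate under interval-censored
  distances instead of an arbitrary feasible point. The reported score is
  the pure violation + steric decomposition, always.

Exhaustive stages of a production docking protocol — semi-flexible
annealing, explicit-solvent refinement, force-field energies,
electrostatics — are out of scope by design.

## Pose selection

Poses (sorted by score) are compared by the ligand RMSD after aligning
receptor Cα atoms, computed without re-fitting the ligand, over the
symmetry atom subset: for a C2-symmetric ligand only the heavy atoms on the
symmetry axis, so the two flip-related placements are not double-counted;
for an asymmetric ligand all heavy atoms. All shared Cα atoms are used for
alignment. Leader clustering (cutoff 1.5 Å): the best-ranked unassigned
pose seeds a cluster and absorbs every unassigned pose within the cutoff.
Clusters are ranked by the mean score of their best min(4, size) poses
(ties: larger cluster, then lower id); the best pose of each cluster
survives unless its worst NOE violation exceeds the tolerance (0.3 Å). An
empty survivor set is a reported outcome, not an error. No manual
score-override of cluster representatives exists: the pipeline has no
electrostatics term on which such a veto could be based, a deliberate
divergence from protocols that include one.

## Synthetic systems

The toy complex places methyl-bearing probe pseudo-residues (CA–CB–CG plus
three methyl protons) on a spherical cap of a pocket wall (default 8 probes,
radius 6 Å) around a known true ligand placement, plus one surface probe
near the pocket mouth, one distant outlier probe, and inert wall atoms.
Ligand templates: a planar six-ring with an axial hydroxyl (exact C2
symmetry about the C1–C4–O axis, mirroring the situation that motivates
axis-subset RMSD) or an asymmetric variant with an extra methyl. NOE peaks
are fabricated from the true pose with exactly the calibration thresholds,
optionally with ±1-class misclassification noise (modelling spin-diffusion
artefacts); at zero noise the true pose satisfies every derived restraint
with zero violation, by construction. Blob trajectories for clustering
enforce an inter-blob separation of max(4σ, 5 Å) in superposed RMSD so a
2 Å quality threshold recovers the generating blobs exactly.

What the toy systems do **not** emulate: side-chain flexibility, realistic
chemistry and force fields, solvent, spin diffusion beyond class noise,
peak overlap or assignment ambiguity. Passing tests demonstrate the
correctness of the calibration/bookkeeping/sampling/clustering/selection
machinery, not the accuracy of docked poses for real receptors.

## Problem sizes and determinism

Validation workloads are sized for a single CPU: docking bookkeeping runs
10 toy receptors × 1000 poses at a reduced minimiser budget (15
evaluations); end-to-end recovery runs 20 seeds at 2 receptors × 150 poses
(budget 80); the WE validation uses ≤10⁶ aggregate propagator steps per
replicate set. Every random draw descends from a single seed via spawned
seed sequences; identical config + seed reproduce byte-identical TSV/JSON
outputs (PDB coordinates are written at the format's 3-decimal precision,
which bounds structure round-trip error at 5×10⁻⁴ Å).

## Known limitations

- The receptor is rigid everywhere; conformational variety enters only
  through the ensemble members.
- The docking score is a ranking signal; its absolute values mean nothing
  physically, and zero is attainable (and common) inside the restraint
  feasible set.
- Large-scale reference results that require cluster-scale molecular
  dynamics or a full docking energy function (e.g. microsecond WE runs on a
  real receptor, absolute SASA ranges of a specific protein ensemble,
  specific cluster counts of a published docking run) are outside what this
  desk-scale pipeline recomputes.
- QT clustering is O(n²)–O(n³) in frames; intended for trajectories of at
  most a few thousand frames.
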