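# Methods

This note documents the models and procedures `memprobe` implements, the
parameters that matter, what the synthetic generators emulate, and the
numerical choices made where the design was genuinely open.

## Conservation profiling

For each column of a gapped alignment where the designated reference row
carries a residue, two percentages are computed: **identity conservation**
(rows matching the most frequent residue of the column) and **class
conservation** (rows whose residue belongs to a configurable class, default
the hydrophobic set {M, A, V, I, L, C, Y, F, W}). Positions are numbered
1-based on the ungapped reference, so residue labels such as W300 or D670
carry over directly; reference-gap columns are skipped, never renumbered.

Open choices, and how they were settled:

- **Gap denominator.** Percentages can be taken against all rows
  (`all_rows`, the default — a gap counts against conservation, appropriate
  when the headline number is "x% of the N sequences") or against non-gap
  rows only (`nongap_rows`). Both are exposed because alignments of distant
  homologues are gap-heavy and the two conventions diverge there.
- **Ties** for the modal residue break alphabetically so reports are
  deterministic.
- **Nonstandard letters** (B, Z, X) stay in the denominator but never count
  as class or identity matches; a warning is emitted once per file.

## Consensus TM topology

Each predictor contributes a per-residue binary TM mark. The consensus
keeps residues whose vote fraction reaches a threshold (default 0.5,
ties count as TM), bridges qualifying runs separated by at most `max_gap`
non-qualifying residues (default 3, absorbing single-predictor dropouts
inside a helix), and discards merged runs shorter than `min_len` (default
15, roughly the minimum membrane-crossing span). All three are config
values. An expected segment count (e.g. 12 for an MFS fold) can be supplied
purely as a diagnostic: a mismatch warns and is never enforced. No rule for
reconciling predictor disagreement is standard; majority voting with gap
merging is this package's explicit, configurable convention.

## Superposition and RMSD

`kabsch_superpose` computes the least-squares optimal rigid transform via
SVD of the centered covariance matrix with the determinant sign correction,
so the returned rotation is always proper (no reflections). Collinear point
sets are solved but flagged with a warning, since the rotation about the
common axis is then arbitrary. RMSD series superpose each frame onto a
reference (frame 0 of the replica by default, or an external snapshot such
as the start of a different run) over the selected Cα atoms and evaluate
the RMSD over the same atoms. Plateau values are summarised as the mean
over the final window of each replica (default the last half), then
mean ± SD (n−1) across replicas — the way stabilised RMSDs of production
runs are conventionally quoted. Frames are assumed whole; there is no
periodic-image correction, and only orthorhombic boxes are carried.

## Secondary structure and helicity

Assignment follows the Kabsch–Sander electrostatic hydrogen-bond model with
partial charges 0.42 e / 0.20 e (prefactor 0.084·332 kcal·Å/mol) and the
−0.5 kcal/mol bond threshold. Amide hydrogens are reconstructed 1.0 Å from
N along the previous peptide's C−O direction; the first residue of a chain
has no H, and proline nitrogen never donates. Pair distances below 0.5 Å
are treated as clashes (bond assumed), mirroring the reference convention.
Chains split at C(i)–N(i+1) distances above 2.5 Å (a peptide bond is
~1.33 Å). Codes implemented: H, G, I (two consecutive 4-, 3-, 5-turns,
priority H > G > I), T (lone turn), '-'. β-strand bookkeeping is out of
scope.

Helicity conservation of a residue is the fraction of frames carrying a
helical code — default {H}, α only, since 3-10/π inclusion is a judgement
call; {H, G, I} is selectable. Replica SD uses the n−1 denominator (one
replica reports 0). The conservation criterion defaults to 0.60 on the
replica mean, with the boundary counting as conserved — a documented
resolution of wording that only specifies "greater than 60%" informally.

## Pocket statistics

- **Cavity volume** is a seeded flood fill on a cell-centered grid
  (default spacing 1.0 Å) inside an axis-aligned region: points farther
  than (vdW radius + probe radius, default probe 1.4 Å) from every atom are
  free, the cavity is the 6-connected free component containing the seed,
  and the volume is its point count × spacing³. vdW radii: C 1.7, N 1.55,
  O 1.52, S 1.8, P 1.8, H 1.2 Å. No published cavity-volume algorithm is
  implied; this definition is the package's own and absolute values are not
  comparable across methods.
- **Contact occupancy** counts, per residue, frames with at least one atom
  pair (residue atom, ligand atom) strictly within the cutoff (default
  6.0 Å), heavy atoms only unless requested otherwise. Replicas pool
  frame-weighted: total contact frames over total frames.
- **Salt-bridge traces** take the per-frame minimum over all donor–acceptor
  pairs; occupancy is the fraction of frames strictly below the threshold
  (default 3.5 Å), so frames at exactly the threshold are excluded. Mean
  and SD (n−1) of the distance accompany the occupancy.
- **Area per lipid** is (box_x·box_y − protein cross-section, default 0) /
  (lipids per leaflet), assuming two equal leaflets.

Strict inequality at every distance threshold is a single package-wide
convention.

## Dose-response fitting

The variable-slope 4PL is fitted by bounded least squares
(`scipy.optimize.curve_fit`, trust-region reflective). Initialisation: top
and bottom from the signal extrema, IC50 from the concentration nearest
half-maximal signal, Hill slope ±1 by response direction (negative for a
falling competition curve); three jittered starts with a fixed RNG stream
guard against poor basins, and the lowest-RSS solution wins. Bounds: Hill
slope in [−10, 10], log10 IC50 within two decades of the measured
concentration range; solutions at a bound are flagged. Data need at least
five distinct concentrations spanning two decades. Signals whose range is
below 5% of their magnitude are flagged `no_inhibition` (pIC50 undefined)
rather than fitted — the signature of a binding-dead mutant. Replicates are
fitted independently and summarised as mean ± SD of per-experiment pIC50
values, not pooled, matching how competition assays are tabulated. Fits are
unweighted, by default on %B0-normalised signal (pIC50 is scale-invariant,
so raw fits give the same potency).

## Synthetic study conditions

The generators define the default study conditions and carry their ground
truth in sidecar records:

- **Alignments**: 758 rows; each cell is a gap with its column's gap
  probability, otherwise a class residue with the column's class frequency
  (uniform within the class). The pipeline's labelled columns use the
  hydrophobic-conservation fractions of well-characterised binding-site
  residues (e.g. 0.939 for a conserved tryptophan); background columns use
  0.8. Rows are independent — no phylogenetic correlation — so tests
  validate counting, not evolutionary inference.
- **Backbones** are built from internal coordinates (N–CA 1.458, CA–C
  1.525, C–N 1.329, C=O 1.231 Å; angles 111.2°, 116.6°, 121.9°; ω = 180°)
  with exact requested dihedrals; the ideal helix uses φ = −57°, ψ = −47°.
  Unwound residues redraw φ ∈ [−180°, −120°], ψ ∈ [120°, 180°] (extended
  basin) in a Bernoulli-selected fraction of frames (exact counts
  optional). Because an i→i+4 turn's hydrogen-bond geometry spans only the
  dihedrals of residues i+1..i+3, the generator can replay the assignment
  rule combinatorially on the realised unwinding and report exact expected
  helical fractions — exact only at zero dihedral/coordinate noise, which
  is therefore the default; noise is opt-in and makes the truth
  approximate. No force field or dynamics is emulated: trajectories probe
  the analysis stack, not conformational physics.
- **Contact and distance traces** place atoms at prescribed distances in
  exact frame counts (contact at half the cutoff, non-contact at five
  cutoffs; salt-bridge frames at 3.0 / 5.0 Å around the 3.5 Å threshold),
  so occupancies are known by construction. Membrane frames encode a target
  area per lipid (default 65.58 Å², 200 lipids, 0.82 Å² jitter) in their
  box dimensions.
- **Dose-response curves** come from the same 4PL forward model the fitter
  assumes, with multiplicative Gaussian noise (default 1%) — parameter
  recovery tests therefore measure optimiser quality, not model adequacy.
  Default generator truths: wildtype pIC50 7.1, a weakened mutant 6.7, an
  unaffected mutant 7.1, and one flat (binding-abolished) curve.

Seeding: one global seed; each generator derives its stream by stable
hashing of (seed, component name), so adding a generator never perturbs
existing streams, and every output is bit-reproducible.

## Pipeline and determinism

`run_pipeline` executes the enabled stages from a single YAML/JSON config
holding every threshold (class set, vote threshold, helical codes, 60%
criterion, 6 Å cutoff, 3.5 Å threshold, grid settings) and writes per-stage
CSV/TSV plus a machine-readable `summary.json` (sorted keys, no
timestamps) that is byte-identical across reruns with the same seed. The
log records the package version, seed and a config hash. Stage failures
are reported with the stage name; other stages still run and partial
outputs are preserved. Disabling a stage never changes another stage's
numbers because stage seeds derive independently. The default trajectory
stage uses 3 replicas × 120 frames × 30 residues and the dedicated
helicity-recovery check uses 3 × 500 frames — sizes chosen so the full
bundle completes in seconds while leaving binomial recovery tolerances
comfortably tight.

## Known limitations

- The assigner covers helical classes and turns only; sheets, bridges and
  bends are not assigned.
- Cavity volumes depend on grid spacing, probe radius and region choice;
  only relative comparisons under fixed settings are meaningful.
- The synthetic trajectories have ideal bond geometry; real simulation
  frames with distorted backbones may shift hydrogen-bond energies near
  the −0.5 kcal/mol threshold.
- Multi-model PDB is the only trajectory format; compressed MD formats
  (XTC/DCD) are out of scope.
- TM predictors themselves are not run; topology consensus starts from
  their exported per-residue tracks.
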