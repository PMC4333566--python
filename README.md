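# memprobe

Desk-scale assessment toolkit for structural models of polytopic membrane
transporters — the situation where a protein of interest (an MFS-fold
transporter such as the synaptic vesicle protein SV2A) has no experimental
structure, models are built by remote homology, and every downstream claim
rests on sequence conservation, predicted topology, simulation stability and
binding data. `memprobe` implements the quantitative stages of that
assessment as a tested, reusable library:

- **Hydrophobic conservation** — per-column MSA statistics mapped to
  reference-residue numbering: identity conservation and the percentage of
  sequences carrying a residue in a class, by default the hydrophobic set
  {M, A, V, I, L, C, Y, F, W} whose conservation marks buried helix faces.
- **Consensus TM topology** — majority voting over per-residue binary tracks
  from multiple TM-prediction servers, with gap bridging and a minimum
  helix span, replacing the usual manual reconciliation.
- **Trajectory metrics** — Kabsch (SVD) least-squares superposition and
  selected-Cα RMSD time series; a from-scratch secondary-structure assigner
  using the Kabsch–Sander hydrogen-bond energy
  `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol (bond when
  `E < −0.5`), with α-helix from two consecutive i→i+4 turns; per-residue
  helicity-conservation profiles with replica mean ± SD against a 60%
  criterion.
- **Binding-pocket statistics** — seeded flood-fill probe-grid cavity
  volumes, per-residue ligand contact occupancy at a 6 Å cutoff,
  donor–acceptor minimum-distance traces with sub-threshold occupancy
  (3.5 Å, strict inequality), and area-per-lipid bookkeeping.
- **Competition-binding fits** — the variable-slope four-parameter logistic
  `Y = bottom + (top − bottom)/(1 + 10^((log10 IC50 − log10 X)·h))`,
  reporting pIC50 = −log10(IC50/M) with per-experiment fits aggregated as
  mean ± SD.
- **Synthetic data** — deterministic generators for every input (alignments
  with controlled column composition, helical backbones with controlled
  unwinding, contact/distance traces, predictor tracks, dose-response
  curves), each carrying its ground truth, so the whole pipeline runs and
  is testable at desk scale without external data.

## Worked example

`examples/trajectory_metrics.py` generates three replicas of a 30-residue
helix in which residue 8 unwinds in about half the frames and residue 20 in
a fifth, then measures what the analysis stack recovers:

```
RMSD over final half: 3.96 ± 0.37 Å (n = 3 replicas)
residues ≥60% helical: 27/30
  residue 8: helical fraction 0.50 ± 0.02 (truth 0.50)
  residue 20: helical fraction 0.80 ± 0.06 (truth 0.80)
```

The RMSD plateau (mean ± SD of per-replica means over the final half of
each run) stays modest because only two residues move; the helicity profile
pinpoints them, with residue 8 falling below the 60% conservation criterion
and residue 20 staying above. The other scripts in `examples/` cover
conservation profiling, topology consensus, pocket statistics and
dose-response fitting; each prints its numbers with a note on what they
mean. The same stages are available from a shell:

```sh
memprobe run-all --out out --seed 1
memprobe conserve alignment.fasta --reference SV2A_RAT --out profile.tsv
```

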