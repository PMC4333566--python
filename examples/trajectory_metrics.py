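"""RMSD and helicity conservation of a partially unwinding helix.

Generates three replicas of a 30-residue helix in which residue 8 unwinds
in about half the frames and residue 20 in a fifth, then measures Cα RMSD
against the first frame and the per-residue helical fraction.
"""
from memprobe import helicity_profile, rmsd_series
from memprobe.superpose import plateau_stats
from memprobe.synthetic import HelixSpec, gen_helix_trajectory

trajs, truth = gen_helix_trajectory(
    HelixSpec(n_residues=30, n_frames=100, n_replicas=3,
              unwind={8: 0.5, 20: 0.2}, seed=0)
)

series = [rmsd_series(t, selection=range(2, 30)) for t in trajs]
plateau = plateau_stats(series, window_fraction=0.5)
print(f"RMSD over final half: {plateau['mean_A']:.2f} ± "
      f"{plateau['sd_A']:.2f} Å (n = 3 replicas)")

prof = helicity_profile(trajs)
conserved = prof.conserved(0.60)
print(f"residues ≥60% helical: {int(conserved.sum())}/{conserved.size}")
for r in (8, 20):
    print(f"  residue {r}: helical fraction "
          f"{prof.mean[r - 1]:.2f} ± {prof.sd[r - 1]:.2f} "
          f"(truth {truth['mean_fraction'][r - 1]:.2f})")

# The RMSD stays small because only two residues move; the helicity profile
# pinpoints them: residue 8 falls below the 60% conservation criterion,
# residue 20 stays above it. Error bars are the SD over the 3 replicas.
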