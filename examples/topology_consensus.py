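"""Consensus TM segments from four noisy predictor tracks.

Emulates four TM-prediction servers disagreeing on a 12-helix transporter
and recovers the helix positions by majority vote with gap merging.
"""
from memprobe import consensus
from memprobe.synthetic import gen_topology_tracks

true_segments = [(s, s + 20) for s in range(6, 313, 26)][:12]
tracks, truth = gen_topology_tracks(true_segments, n_residues=313,
                                    n_predictors=4, flip_prob=0.03, seed=0)

topo = consensus(tracks, threshold=0.5, min_len=15, max_gap=3,
                 expected_count=12)
print(f"recovered {topo.n_segments} TM segments "
      f"(generator planted {len(true_segments)}):")
for k, (s, e) in enumerate(topo.segments, 1):
    print(f"  TM{k:<2d} {s:3d}-{e:3d}")

# Each segment is a run of residues where at least half the predictors
# vote TM, bridged across gaps of up to 3 residues and at least 15 long —
# the span of a membrane-crossing helix.
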