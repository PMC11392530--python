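"""Posterior expected coalescence time (TMRCA) along the genome.

Decodes one pair of simulated genomes with the fitted HMM, prints summary
statistics of the inferred TMRCA track and of the genealogy spans (distance
between inferred recombination events), and compares with the truth held by
the simulator.
"""

import numpy as np

from epismc import generate_fixture, genealogy_spans, posterior_tmrca
from epismc.simulate import true_tmrca_track
from epismc.smc import EmissionBlock, constant_model

data = generate_fixture("constant", seed=11, sequence_length=600_000)
blocks = [EmissionBlock("m1", "symmetric", (1e-8,), nbs=4),
          EmissionBlock("m2", "symmetric", (1e-4,), nbs=2)]
model = constant_model(10_000.0, 1e-8, blocks, n_states=16, window_size=100)

track = posterior_tmrca(data.encode_pair(0, 1), model)
breaks, truth = true_tmrca_track(data.tree_sequence, 0, 1)
pos = track.positions() + 50
true_at = truth[np.clip(np.searchsorted(breaks, pos, side="right") - 1, 0,
                        len(truth) - 1)]

corr = np.corrcoef(track.expected, true_at)[0, 1]
print(f"mean inferred TMRCA {track.expected.mean():.0f} generations "
      f"(truth {true_at.mean():.0f}); correlation {corr:.2f}")

spans = genealogy_spans(track)
print(f"genealogy spans: mean {spans.mean():.0f} bp, "
      f"median {np.median(spans):.0f} bp (right-skewed: mean > median)")
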