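"""How many endmembers? Scan candidate ranks with three diagnostics.

The cube is generated with k_true = 3.  The scan reports, per rank: the
best reconstruction error over seeded restarts, the consensus dispersion
(restart stability, 1 = perfectly stable), and the largest cosine between
fitted endmembers (near-duplicates signal an overshot rank).
"""

import warnings

import hsunmix as h

warnings.filterwarnings("ignore", message="gaussian noise clipped")

gt = h.default_ground_truth(seed=0)
dm = h.cube_to_matrix(h.make_cube(gt))

result = h.scan_k(dm, range(2, 6), n_restarts=5, seed=0)
print(result.to_frame().to_string(index=False))
print(f"\nchosen k = {result.chosen_k} (criterion: {result.criterion})")
if result.saturation_k is not None:
    print(f"component similarity saturates at k = {result.saturation_k}")
# expect the error curve to elbow at the true rank 3, dispersion to drop
# beyond it, and duplicated components to appear above it
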