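"""Partition an image pair into tolerance-sized regions and inspect the
global sampling rule.

Builds a small synthetic roughly paired image, splits it into four regions,
and prints each region's similarity/rarity score Q_i and selection
probability P_i.  Regions whose source and target pixels correlate well, or
whose intensity histogram is rare in the image, are sampled more often
during training.
"""

import numpy as np

from uframe import SyntheticSpec, compute_sampling_distribution, generate_dataset, partition_regions

spec = SyntheticSpec(
    image_size=256, cell_size=64, appearance="invert-gamma",
    misalign_mode="displace", misalign_d=0, jitter_shift=0, jitter_rotation=0,
    jitter_scale=0, noise_sigma=0.02, seed=0,
)
data = generate_dataset(spec)

grid = partition_regions(data.source.shape, tolerance=128, overlap=64, patch_size=64)
dist = compute_sampling_distribution(data.source, data.target, grid)

print(f"{grid.n_regions} regions of {grid.tolerance} px (overlap {grid.overlap} px)")
for i, rect in enumerate(grid.regions):
    print(
        f"region {i}: rows {rect.r0}-{rect.r1}, cols {rect.c0}-{rect.c1}  "
        f"Q = {dist.Q[i]:.4f}  P = {dist.P[i]:.4f}"
    )
print(f"sum P = {dist.P.sum():.6f} (a probability distribution over regions)")
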