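"""Single-pixel signal correlation (SPSC) as a co-deposition statistic.

Two proteoforms that deposit together produce correlated ion images; SPSC
is their pairwise Pearson correlation across pixels of a mask.  This script
plants a block covariance — one ADan-like group (r = 0.9 within), two
Abeta-like groups (r = 0.8 within), r = 0.1 across — on 500 masked pixels
and shows that the recovered matrix reproduces the block structure.
"""

import numpy as np

from vesselmap import msi as vmsi
from vesselmap import synthetic as syn

sizes = [4, 3, 3]
names = (
    [f"ADan_sp{i}" for i in range(4)]
    + [f"Abeta40_sp{i}" for i in range(3)]
    + [f"Abeta42_sp{i}" for i in range(3)]
)
R = syn.block_correlation_matrix(sizes, [0.9, 0.8, 0.8], 0.1)
data = syn.sample_correlated_images(R, 500, seed=3)
images = data.reshape(len(names), 20, 25)

M = vmsi.spsc_matrix(images, np.ones((20, 25), bool), species_names=names)
print(M.round(2).to_string())

bounds = np.cumsum([0] + sizes)
blocks = [range(bounds[k], bounds[k + 1]) for k in range(len(sizes))]
A = M.to_numpy()
within = [A[i, j] for b in blocks for i in b for j in b if i < j]
cross = [A[i, j] for bi in range(3) for bj in range(3) if bi < bj
         for i in blocks[bi] for j in blocks[bj]]
print(f"\nwithin-block r: min {min(within):.2f}; cross-block r: max {max(cross):.2f}")
print("all within-block correlations exceeding all cross-block ones recovers")
print("the planted co-deposition structure (same-group species co-localize).")
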