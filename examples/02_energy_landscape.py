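"""Build an energy landscape and its disconnectivity graph.

Constructs the landscape of a fitted model, lists its local minima and
branch lengths, prunes minor minima against a chance-level threshold derived
from random series of the same length, and prints the merge tree.
"""

import json

import numpy as np

from elatools import (
    EnergyLandscape,
    default_base_params,
    null_branch_stats,
    prune_minor_minima,
)
from elatools.landscape import merge_tree, merge_tree_dot

params = default_base_params(n_rois=6, coupling_scale=0.5, seed=11)
landscape = EnergyLandscape.from_params(params)

print(f"{landscape.n_minima} local minima")
for pattern, energy, branch in zip(
    landscape.minima_patterns(), landscape.energies[landscape.minima],
    landscape.branch_length,
):
    label = "".join("+" if s > 0 else "-" for s in pattern)
    print(f"  {label}  E = {energy:+.3f}  branch length = {branch:.3f}")

# prune minima whose branch is indistinguishable from chance at this length
stats = null_branch_stats(n_rois=6, t_max=500, length_multiplier=1, seed=3)
pruned = prune_minor_minima(landscape, stats)
print(f"\npruning threshold mu' + 2 sigma' = {stats.threshold:.3f}")
print(f"{pruned.n_minima} minima survive pruning")

print("\nmerge tree (JSON):")
print(json.dumps(merge_tree(pruned), indent=2))
print("\nGraphviz DOT of the disconnectivity graph:")
print(merge_tree_dot(pruned))
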