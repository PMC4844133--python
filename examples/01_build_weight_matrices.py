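"""Build the four autocorrelation weight matrices for a synthetic world.

Constructs a toy language phylogeny (with colonial offshoots), regional
country centroids and a border graph, then derives the matrices the
autoregression consumes: two distance-derived affinities (socio-linguistic,
spatial) and two row-normalized adjacencies (mutual intelligibility, shared
borders).
"""

import numpy as np

import culturenet as cn

world = cn.make_world(n_tips=24, n_colonies=8, seed=7)

print(f"world with {world.n} countries")
for label, w in world.networks.items():
    off = w.values[~np.eye(w.n, dtype=bool)]
    print(f"  {label:8s} kind={w.kind:26s} "
          f"median weight {np.median(off):.3f}  max {off.max():.3f}")

# The affinity transform maps the most divergent pair to 0 and self to 1;
# e.g. a pair split 25% of the way to the maximum divergence scores 0.75.
d = world.sol_distances
aff = cn.distance_to_affinity(d)
i, j = 0, 1
print(f"\npair ({d.nodes.ids[i]}, {d.nodes.ids[j]}): "
      f"distance {d.values[i, j]:.0f} years of max {d.values.max():.0f} "
      f"-> affinity {aff.values[i, j]:.3f}")
print("an affinity near 1 means the pair is expected to be strongly "
      "correlated in outcome; near 0, effectively independent.")
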