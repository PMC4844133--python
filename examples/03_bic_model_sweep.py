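"""Exhaustive BIC model selection across time bins.

Generates a panel whose bins carry signal planted on the spatial-adjacency
network, sweeps all 16 matrix subsets per bin, and reports the preferred
models, inclusion frequencies and median BIC gaps with their Bayes factors.
"""

import culturenet as cn
from culturenet.pipeline import sweep_panel
from culturenet.synthetic_data import make_correlated_panel

world = cn.make_world(n_tips=24, n_colonies=8, seed=1)
panel = make_correlated_panel(world, n_bins=10, rho={"S_adj": 0.6}, seed=2)

table, skipped = sweep_panel(panel, world.networks)
freqs = cn.inclusion_frequencies(table)["per_matrix"]
g12, g13 = cn.median_bic_gaps(table)

print("top-two inclusion frequencies over", len(table.bins), "bins:")
print(freqs)
print(f"\nmedian BIC gap preferred->2nd: {g12:.2f} "
      f"(Bayes factor {cn.bayes_factor(g12):.2f}, {cn.bayes_factor_band(cn.bayes_factor(g12))})")
print(f"median BIC gap preferred->3rd: {g13:.2f} "
      f"(Bayes factor {cn.bayes_factor(g13):.2f}, {cn.bayes_factor_band(cn.bayes_factor(g13))})")
print("\nthe generating matrix (S_adj) should top the overall column: "
      "BIC selection attributes the planted correlation to the right network.")
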