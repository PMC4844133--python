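"""Single-matrix significance census across time bins.

Fits each weight matrix alone to every bin of a polity-like panel and counts
the bins where its autocorrelation is significant at alpha = 0.05, then
summarizes the significant rho with a one-sample t-test.
"""

import numpy as np

import culturenet as cn

world = cn.make_world(n_tips=24, n_colonies=8, seed=3)
panel = cn.make_polity_like_panel(world, n_bins=20, change_prob=0.4,
                                  on="S_adj", rho=0.7, sigma2=9.0, seed=4)

for label, w in world.networks.items():
    triples = []
    for b in range(panel.n_bins):
        y, subs, _ = cn.align_bin(panel, b, [w])
        if np.ptp(y) > 0:
            triples.append((str(b), y, subs[0]))
    census = cn.significance_census(triples, alpha=0.05)
    s = cn.summarize_significant_rhos(census)
    line = f"  {label:8s} significant in {census.n_significant:2d} of {census.n_tested} bins"
    if not s.flagged:
        line += (f"; significant rho mean {s.mean:.2f} "
                 f"(95% CI {s.ci_low:.2f} to {s.ci_high:.2f}, "
                 f"t p = {s.t_pvalue:.3g}, df = {s.df})")
    print(line)

print("\nthe generating network (S_adj) should be significant far above the "
      "5% false-positive rate; a CI excluding 0 marks a consistent direction.")
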