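"""Scaled-down diffusion bias study.

Simulates one-step 20% trait diffusion on each of the four networks and runs
every simulated trait through the full 16-model BIC sweep, mirroring the
treatment of the empirical panels. The inclusion-count table shows which
networks the selection procedure attributes each condition's signal to —
off-diagonal mass is the selection bias the study quantifies.
"""

from culturenet import make_world
from culturenet.simulation import (
    bias_study_summary,
    inclusion_count_table,
    run_bias_study,
)

world = make_world(n_tips=24, n_colonies=8, seed=5)
batches = run_bias_study(world.networks, n_reps=10, seed=6)

print("top-two inclusion counts (rows = generating network, max 20):")
print(inclusion_count_table(batches))
print("\nmedian BIC gaps per condition:")
print(bias_study_summary(batches).round(2))
print("\nrows where the diagonal dominates are conditions the procedure "
      "attributes correctly; large off-diagonal entries (typically the dense "
      "spatial-proximity affinity) quantify its bias.")
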