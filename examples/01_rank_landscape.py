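"""Rank a small synthetic landscape under the richness and rarity objectives.

Builds a 40x40 landscape with 10 species, locks protected areas into the top
ranks, and prints how much of each feature's distribution the best 25% of the
landscape would retain under each objective.
"""

import numpy as np

from umbrascape import (
    PrioritizerConfig,
    SimConfig,
    build_removal_mask,
    coverage_at_fraction,
    rank_landscape,
    simulate_landscape,
)

cfg = SimConfig(n_rows=40, n_cols=40, n_species=10, n_seasonal_species=1,
                n_summer_only=2, seed=7)
res = simulate_landscape(cfg)
stack = res.stack
print(f"{len(stack.features)} features on {stack.analysis_mask.n_cells} habitat cells")

for objective in ("abf", "caz"):
    mask = build_removal_mask("prioritize_richness", stack.protected_mask,
                              stack.focal_mask, stack.grid)
    rank_map, table = rank_landscape(stack, PrioritizerConfig(objective), mask)
    retained = coverage_at_fraction(rank_map, 0.25, stack.features)
    print(f"\nobjective={objective}: mean proportion retained in top 25% "
          f"= {retained.mean():.3f}")
    worst = int(np.argmin(retained))
    print(f"  least-covered feature: {stack.features[worst].feature_id} "
          f"({retained[worst]:.3f} of its distribution)")

# The additive-benefit rule sums power-transformed losses over features, so
# it favors species-rich cells; the core-area rule ranks a cell by its single
# most-dependent feature, favoring range cores. The removal mask guarantees
# protected cells sit in the top ranks under either objective.
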