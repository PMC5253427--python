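"""Geographic, least-cost-path and barrier-crossing distances for the same
set of individuals."""

import numpy as np
from shapely.geometry import LineString

from landgenkit import (
    BarrierSet,
    SimulationConfig,
    barrier_count_matrix,
    euclidean_matrix,
    lcp_matrix,
    make_landscape,
    simulate_genotypes,
)

cfg = SimulationConfig(
    n_populations=4,
    n_individuals_per_pop=(8, 8, 8, 8),
    n_loci=6,
    n_generations=30,
    pop_sizes=40,
    landscape_wall=True,  # high-cost barrier with a single gap
    rng_seed=3,
)
surface, _ = make_landscape(cfg)
table, _ = simulate_genotypes(cfg, surface)

ibd = euclidean_matrix(table, log_transform=True)
lcp = lcp_matrix(table, surface, surface_id="RSF")
roads = BarrierSet(
    [LineString([(60_000.0, 0.0), (60_000.0, 120_000.0)])], "roads"
)
ibb = barrier_count_matrix(table, roads)

off = ~np.eye(table.n_individuals, dtype=bool)
print(f"log-Euclidean distance range: {ibd.values[off].min():.2f} .. {ibd.values[off].max():.2f}")
print(f"LCP cost range:               {np.nanmin(lcp.matrix.values[off]):.0f} .. {np.nanmax(lcp.matrix.values[off]):.0f}")
print(f"disconnected pairs:           {lcp.n_disconnected_pairs}")
print(f"road crossings per pair:      0 .. {int(ibb.values.max())}")
# Pairs on opposite sides of the wall accumulate much larger least-cost
# costs than their straight-line separation suggests, and cross the road
# feature exactly once.
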