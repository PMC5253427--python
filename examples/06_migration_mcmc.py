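"""Directional recent-migration rates between local populations from
multilocus genotypes, with credible intervals and qualitative classes."""

import numpy as np

from landgenkit import (
    MCMCConfig,
    SimulationConfig,
    net_emigration,
    run_bayesass,
    simulate_genotypes,
)

true_m = np.array(
    [
        [0.75, 0.20, 0.05],
        [0.05, 0.90, 0.05],
        [0.05, 0.05, 0.90],
    ]
)
cfg = SimulationConfig(
    n_populations=3,
    n_individuals_per_pop=(50, 50, 50),
    n_loci=14,
    n_generations=250,
    pop_sizes=60,
    true_migration_matrix=true_m,
    recent_migrant_ancestry=True,  # migration happens at sampling time only
    rng_seed=6,
)
table, truth = simulate_genotypes(cfg)

mcmc = MCMCConfig(n_iter=300_000, burn_in=100_000, thin=200, n_chains=1, delta_m=0.1, seed=0)
mig, trace = run_bayesass(table, mcmc)

print(f"{'into':6s} {'from':6s} {'truth':>6s} {'mean':>6s} {'95% CI':>16s} class")
for row in mig.to_table():
    i = mig.labels.index(row["into"])
    j = mig.labels.index(row["source"])
    ci = f"({row['ci_low']:.3f}-{row['ci_high']:.3f})"
    print(
        f"{row['into']:6s} {row['source']:6s} {true_m[i, j]:6.3f} "
        f"{row['mean']:6.3f} {ci:>16s} {row['class']}"
    )
for pop in mig.labels:
    print(f"net emigration of {pop}: {net_emigration(mig, pop):+.3f}")
# The posterior mean of the 0.20 rate lands near the truth with a credible
# interval reflecting the binomial sampling of migrant ancestry among the
# 50 sampled individuals; diagonal entries are the non-migrant fractions.
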