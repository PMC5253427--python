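"""Reproducible validation experiments for the analysis stack.

Each function runs one self-contained experiment — oracle comparison,
permutation-null calibration, closed-form population-genetics limit, or
parameter recovery — at a fixed desk-scale problem size, seeded explicitly.
They are used by the test suite and by ``scripts/acceptance.py``; problem
sizes are chosen so the full battery runs on one CPU in minutes.

Experiment conditions (population counts, locus counts, drift times, effect
sizes) are part of each experiment's definition: they are the regime in which
the method's property is expected to hold, documented in docs/methods.md.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_data import DistanceMatrix
from .distlm import PredictorSet, distlm_marginal
from .genetic_distance import allele_frequencies, pairwise_fst, rousset_ar
from .landscape_distance import euclidean_matrix, lcp_matrix
from .matrix_stats import mantel, partial_mantel, rcm
from .migration_mcmc import MAX_IMMIGRATION, MCMCConfig, run_bayesass
from .relatedness import (
    _genotype_pair_triples,
    _locus_freq_lookup,
    _lookup,
    fit_k_batch,
    relatedness_significance,
)
from .synthetic_data import (
    SimulationConfig,
    _centroid_distances,
    make_landscape,
    simulate_genotypes,
)

# ---------------------------------------------------------------------------
# Permutation-null calibrations
# ---------------------------------------------------------------------------


def _random_euclidean(n: int, rng: np.random.Generator) -> DistanceMatrix:
    pts = rng.normal(size=(n, 2))
    d = np.hypot(pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1])
    return DistanceMatrix(labels=[f"u{k}" for k in range(n)], values=d)


def mantel_null_pvalues(
    n_rep: int = 200, n: int = 20, n_perm: int = 999, seed: int = 0
) -> np.ndarray:
    """Simple-Mantel p-values when the two matrices are independent."""
    ss = np.random.SeedSequence(seed)
    out = np.empty(n_rep)
    for k, child in enumerate(ss.spawn(n_rep)):
        rng = np.random.default_rng(child)
        G = _random_euclidean(n, rng)
        X = DistanceMatrix(labels=G.labels, values=_random_euclidean(n, rng).values)
        out[k] = mantel(G, X, n_perm=n_perm, tail="greater",
                        seed=int(rng.integers(2**31))).p
    return out


def partial_mantel_null_pvalues(
    n_rep: int = 200, n: int = 20, n_perm: int = 999, seed: int = 1
) -> np.ndarray:
    """Partial-Mantel p-values when the tested matrix is independent of the
    response given the control."""
    ss = np.random.SeedSequence(seed)
    out = np.empty(n_rep)
    for k, child in enumerate(ss.spawn(n_rep)):
        rng = np.random.default_rng(child)
        C = _random_euclidean(n, rng)
        noise = rng.normal(scale=0.3, size=(n, n))
        noise = noise + noise.T
        gv = C.values + noise
        np.fill_diagonal(gv, 0.0)
        G = DistanceMatrix(labels=C.labels, values=gv)
        A = DistanceMatrix(labels=C.labels, values=_random_euclidean(n, rng).values)
        out[k] = partial_mantel(G, A, C, n_perm=n_perm, tail="greater",
                                seed=int(rng.integers(2**31))).p
    return out


def distlm_null_pvalues(
    n_rep: int = 200, n: int = 30, n_perm: int = 999, seed: int = 2
) -> np.ndarray:
    """Marginal DISTLM p-values for a predictor independent of the response."""
    import pandas as pd

    ss = np.random.SeedSequence(seed)
    out = np.empty(n_rep)
    for k, child in enumerate(ss.spawn(n_rep)):
        rng = np.random.default_rng(child)
        y = rng.normal(size=(n, 2))
        d = np.sqrt(((y[:, None, :] - y[None, :, :]) ** 2).sum(axis=2))
        D = DistanceMatrix(labels=[f"u{i}" for i in range(n)], values=d)
        preds = PredictorSet(
            data=pd.DataFrame({"x": rng.normal(size=n)}), unit_labels=D.labels
        )
        out[k] = distlm_marginal(D, preds, n_perm=n_perm,
                                 seed=int(rng.integers(2**31)))[0].p
    return out


def relatedness_null_pvalues(
    n_rep: int = 200, n_rand: int = 999, seed: int = 3
) -> np.ndarray:
    """Randomization p-values when the observed pair is itself drawn from the
    null (both individuals' alleles independent draws from pooled frequencies).

    The test statistic r_hat is a boundary-constrained MLE with an atom at
    exactly 0 for unrelated pairs, so these p-values are valid
    (super-uniform) but carry an atom at 1 rather than being exactly uniform.
    """
    cfg = SimulationConfig(
        n_populations=4,
        n_individuals_per_pop=(20, 20, 20, 20),
        n_loci=14,
        n_generations=30,
        pop_sizes=100,
        rng_seed=seed,
    )
    table, _ = simulate_genotypes(cfg)
    freqs = allele_frequencies(table, by="pooled")
    locus_tables = [
        _locus_freq_lookup(freqs, name, 0.0) for name in table.locus_names
    ]
    ss = np.random.SeedSequence(seed + 1)
    out = np.empty(n_rep)
    L = table.n_loci
    for k, child in enumerate(ss.spawn(n_rep)):
        rng = np.random.default_rng(child)
        # observed pair AND null pairs from the same pooled-frequency null
        P = np.ones((n_rand + 1, L, 3))
        for l, (codes, vals) in enumerate(locus_tables):
            p = vals / vals.sum()
            draws = rng.choice(codes, size=(n_rand + 1, 4), p=p)
            x1, x2, y1, y2 = draws[:, 0], draws[:, 1], draws[:, 2], draws[:, 3]
            P0, P1, P2 = _genotype_pair_triples(
                x1, x2, y1, y2,
                _lookup(codes, vals, x1), _lookup(codes, vals, x2),
                _lookup(codes, vals, y1), _lookup(codes, vals, y2),
            )
            P[:, l, 0], P[:, l, 1], P[:, l, 2] = P0, P1, P2
        ks = fit_k_batch(P)
        r = ks[:, 1] / 2.0 + ks[:, 2]
        r_obs, r_null = r[0], r[1:]
        out[k] = (1 + int((r_null >= r_obs).sum())) / (n_rand + 1)
    return out


# ---------------------------------------------------------------------------
# Closed-form limits
# ---------------------------------------------------------------------------


def island_model_fst(
    n_rep: int = 20,
    N: int = 100,
    m: float = 0.01,
    n_pops: int = 4,
    n_generations: int = 250,
    n_sampled: int = 25,
    seed: int = 0,
) -> np.ndarray:
    """Mean multi-locus pairwise theta per replicate under Wright's island
    model at drift-migration equilibrium; expectation ~ 1 / (1 + 4Nm)."""
    out = np.empty(n_rep)
    iu = np.triu_indices(n_pops, 1)
    for rep in range(n_rep):
        cfg = SimulationConfig(
            n_populations=n_pops,
            n_individuals_per_pop=(n_sampled,) * n_pops,
            n_loci=14,
            n_generations=n_generations,
            pop_sizes=N,
            migration_model="island",
            island_m=m,
            rng_seed=seed * 1_000 + rep,
        )
        table, _ = simulate_genotypes(cfg)
        f = pairwise_fst(table)
        out[rep] = np.nanmean(f.values[iu])
    return out


def heterozygosity_decay_ratio(
    n_rep: int = 40, N: int = 50, n_generations: int = 50, seed: int = 0
) -> float:
    """Observed / expected gene-pool heterozygosity after drift in a closed
    population; the expectation decays by (1 - 1/(2N)) per generation."""
    ratios = []
    factor = (1.0 - 1.0 / (2 * N)) ** n_generations
    for rep in range(n_rep):
        cfg = SimulationConfig(
            n_populations=1,
            n_individuals_per_pop=(2,),
            n_loci=14,
            n_generations=n_generations,
            pop_sizes=N,
            true_migration_matrix=np.eye(1),
            rng_seed=seed * 1_000 + rep,
        )
        _, truth = simulate_genotypes(cfg)
        for f0, ft in zip(truth.initial_freqs, truth.final_freqs):
            h0 = 1.0 - float((np.asarray(f0) ** 2).sum())
            ht = 1.0 - float((np.asarray(ft)[0] ** 2).sum())
            if h0 > 1e-6:
                ratios.append(ht / (h0 * factor))
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# Parameter recovery: migration MCMC
# ---------------------------------------------------------------------------

RECOVERY_TRUE_M = np.array(
    [
        [0.75, 0.20, 0.05],
        [0.05, 0.90, 0.05],
        [0.05, 0.05, 0.90],
    ]
)
RECOVERY_FOCAL = (0, 1)  # the 0.20 entry whose coverage is scored


def mcmc_recovery_replicate(
    rep: int,
    n_iter: int = 300_000,
    burn_in: int = 100_000,
    zero_migration: bool = False,
    seed: int = 0,
):
    """One recovery fit: diverged populations plus recent migrant sampling.

    Three populations drift in isolation for 250 generations (N = 60), then
    50 diploids per population are sampled with migrant ancestry drawn from
    the estimator's own ancestry model at the true rates (focal entry 0.20).
    Returns the posterior MigrationMatrix.
    """
    true_m = np.eye(3) if zero_migration else RECOVERY_TRUE_M
    cfg = SimulationConfig(
        n_populations=3,
        n_individuals_per_pop=(50, 50, 50),
        n_loci=14,
        n_generations=250,
        pop_sizes=60,
        true_migration_matrix=true_m,
        recent_migrant_ancestry=True,
        rng_seed=(900 if zero_migration else 600) + seed * 10_000 + rep,
    )
    table, _ = simulate_genotypes(cfg)
    mcmc = MCMCConfig(
        n_iter=n_iter,
        burn_in=burn_in,
        thin=200,
        n_chains=1,
        delta_m=0.1,
        seed=seed * 1_000 + rep,
    )
    mm, _ = run_bayesass(table, mcmc)
    return mm


def mcmc_recovery_coverage(n_rep: int = 20, seed: int = 0, **kw) -> int:
    """Number of replicates whose 95% credible interval covers the 0.20 rate."""
    i, j = RECOVERY_FOCAL
    truth = RECOVERY_TRUE_M[i, j]
    covered = 0
    for rep in range(n_rep):
        mm = mcmc_recovery_replicate(rep, seed=seed, **kw)
        covered += bool(mm.ci_low[i, j] <= truth <= mm.ci_high[i, j])
    return covered


def mcmc_zero_migration_max_offdiag(n_rep: int = 3, seed: int = 0, **kw) -> float:
    """Largest posterior-mean off-diagonal rate over zero-migration fits."""
    worst = 0.0
    for rep in range(n_rep):
        mm = mcmc_recovery_replicate(rep, zero_migration=True, seed=seed, **kw)
        off = mm.mean[~np.eye(3, dtype=bool)]
        worst = max(worst, float(off.max()))
    return worst


# ---------------------------------------------------------------------------
# Model-selection recovery: reciprocal causal modelling
# ---------------------------------------------------------------------------


def rcm_recovery_replicate(seed: int, n_perm: int = 199, row_alpha: float = 0.05):
    """One RCM recovery run on a resistance-driven lattice simulation.

    An 8 x 8 lattice of small demes (N = 15, 2 sampled individuals each,
    56 loci) exchanges migrants at rates decaying exponentially in the
    least-cost-path distance over a gently bumpy landscape split by a
    *permeable* mid-cost wall with one gap — permeability matters: an
    impassable wall reduces to a binary side split that any distance-like
    matrix mimics, whereas graded detour costs are visible only to the
    generating surface.  Candidate models: LCP over the generating surface,
    straight-line geographic distance, and LCP over a decoy surface (same
    bump process, different seed, no wall).  Returns the RcmSupportMatrix.
    """
    grid = 8
    xs = np.linspace(12_000.0, 108_000.0, grid)
    ys = np.linspace(12_000.0, 108_000.0, grid)
    cents = np.array([(x, y) for x in xs for y in ys])
    K = grid * grid
    cfg = SimulationConfig(
        n_populations=K,
        n_individuals_per_pop=(2,) * K,
        n_loci=56,
        n_generations=150,
        pop_sizes=15,
        migration_model="resistance_decay",
        pop_centroids=cents,
        decay_scale=1.0,  # replaced below with a quarter of the mean LCP
        total_immigration=0.3,
        landscape_wall=True,
        landscape_wall_cost=40.0,
        landscape_n_bumps=6,
        landscape_bump_amplitude=3.0,
        raster_shape=(50, 50),
        scatter_sd=2_000.0,
        rng_seed=seed,
    )
    surface, _ = make_landscape(cfg)
    d = _centroid_distances(cfg, surface)
    cfg = dataclasses.replace(
        cfg, decay_scale=float(np.mean(d[np.triu_indices(K, 1)]) / 4.0)
    )
    table, _ = simulate_genotypes(cfg, surface)
    decoy_surface, _ = make_landscape(
        dataclasses.replace(cfg, rng_seed=seed + 10_000, landscape_wall=False)
    )
    ar = rousset_ar(table)
    models = {
        "LCP_true": lcp_matrix(table, surface, "true").matrix,
        "IBD": euclidean_matrix(table, log_transform=False),
        "LCP_decoy": lcp_matrix(table, decoy_surface, "decoy").matrix,
    }
    return rcm(ar, models, n_perm=n_perm, seed=seed, row_alpha=row_alpha)


def rcm_recovery_rate(n_seeds: int = 20, seed: int = 0, **kw) -> float:
    """Fraction of seeds in which the generating model is fully supported."""
    wins = 0
    for k in range(n_seeds):
        support = rcm_recovery_replicate(seed * 1_000 + k, **kw)
        wins += support.verdicts["LCP_true"] == "fully_supported"
    return wins / n_seeds
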