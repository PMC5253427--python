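"""Synthetic landscapes, populations and genotypes with known ground truth.

The generator emulates the data structure of an individual-based landscape
genetics study of partially migratory woodland caribou: a handful of local
populations (default 8) of adult females (default 207 individuals in total)
genotyped at 14 microsatellite loci, sampled across a resistance landscape,
with per-individual migratory/sedentary/unclassified behaviour labels.

Genetics are simulated forward in time with Wright-Fisher multinomial drift:
initial allele frequencies per locus come from a symmetric Dirichlet over a
locus-specific allele count; each generation every gene copy in population i
is an immigrant from population j with probability m_ij, then 2N gene copies
are resampled multinomially.  Migration models:

``island``
    Wright's idealized island model — immigrant gene copies are drawn from
    the fixed ancestral-pool frequencies, so at drift-migration equilibrium
    the classical expectation F_ST ~= 1 / (1 + 4Nm) holds without a
    finite-island correction.
``distance_decay`` / ``resistance_decay``
    m_ij proportional to exp(-d_ij / decay_scale) with d the Euclidean or
    least-cost-path distance between population centroids, row-normalized so
    each population's total immigration equals ``total_immigration``
    (capped at 1/3, the support of the migration estimator's prior).
``island``/explicit: ``true_migration_matrix`` overrides everything.

Sampled individuals are drawn Hardy-Weinberg from their population's final
frequencies and scattered (Gaussian) around the population centroid.  With
``recent_migrant_ancestry`` the final sampling instead draws each
individual's migrant ancestry (non-migrant / first- / second-generation)
from the migration model's ancestry prior — the generative model of the
migration MCMC — recording the truth for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import BarrierSet, GenotypeTable, ResistanceSurface
from .errors import ValidationError
from .migration_mcmc import MAX_IMMIGRATION, ancestry_prior_row, ancestry_state_table

DEFAULT_POP_SIZES = (30, 28, 27, 26, 25, 25, 24, 22)  # sums to 207 sampled


@dataclass
class SimulationConfig:
    """Study-shaped simulation conditions.

    Defaults emulate the study design: 8 local populations, 207 sampled
    individuals, 14 loci with 5-15 alleles each, behaviour mix of roughly
    61% migratory / 10% sedentary / 29% unclassified, spatially limited
    migration over a ~100 km landscape.
    """

    n_populations: int = 8
    pop_centroids: np.ndarray | None = None  # (K, 2) metres
    n_individuals_per_pop: tuple = DEFAULT_POP_SIZES
    n_loci: int = 14
    n_alleles_per_locus: tuple = (5, 15)
    n_generations: int = 100
    pop_sizes: tuple | int = 100  # simulated N per population
    migration_model: str = "distance_decay"
    decay_scale: float = 30_000.0  # metres
    total_immigration: float = 0.25
    island_m: float = 0.01
    true_migration_matrix: np.ndarray | None = None
    history_migration_matrix: np.ndarray | None = None
    behaviour_fraction_migratory: float = 126 / 207
    behaviour_fraction_sedentary: float = 21 / 207
    scatter_sd: float = 6_000.0  # metres around each centroid
    recent_migrant_ancestry: bool = False
    sedentary_pure_descent: bool = False
    rng_seed: int = 0
    # landscape parameters (make_landscape)
    raster_shape: tuple = (60, 60)
    landscape_n_bumps: int = 6
    landscape_bump_amplitude: float = 6.0
    landscape_bump_sigma: float = 15_000.0
    landscape_wall: bool = False
    landscape_wall_cost: float = 60.0
    region_size: float = 120_000.0  # metres

    def __post_init__(self) -> None:
        K = self.n_populations
        if isinstance(self.pop_sizes, int):
            self.pop_sizes = (self.pop_sizes,) * K
        if len(self.pop_sizes) != K:
            raise ValidationError("pop_sizes length must equal n_populations")
        if len(self.n_individuals_per_pop) != K:
            if len(self.n_individuals_per_pop) > K:
                self.n_individuals_per_pop = tuple(self.n_individuals_per_pop[:K])
            else:
                raise ValidationError("n_individuals_per_pop length must equal n_populations")
        if any(s < 2 for s in self.pop_sizes):
            raise ValidationError("simulated population sizes must be >= 2")
        if not (
            0.0
            <= self.behaviour_fraction_migratory + self.behaviour_fraction_sedentary
            <= 1.0
        ):
            raise ValidationError("behaviour fractions must sum to <= 1")
        if self.migration_model not in ("island", "distance_decay", "resistance_decay"):
            raise ValidationError(f"unknown migration model {self.migration_model!r}")
        if self.true_migration_matrix is not None:
            m = np.asarray(self.true_migration_matrix, dtype=float)
            if m.shape != (K, K):
                raise ValidationError("true_migration_matrix has wrong shape")
            off = m.sum(axis=1) - np.diag(m)
            if (off > 1.0 + 1e-12).any():
                raise ValidationError("off-diagonal migration rates sum above 1")
            self.true_migration_matrix = m

    def centroids(self) -> np.ndarray:
        """Population centroids: provided, or a jittered ring spanning the region."""
        if self.pop_centroids is not None:
            return np.asarray(self.pop_centroids, dtype=float)
        rng = np.random.default_rng(np.random.SeedSequence([self.rng_seed, 0xC3]))
        K = self.n_populations
        angles = 2 * np.pi * np.arange(K) / K
        radius = 0.35 * self.region_size
        cx = self.region_size / 2 + radius * np.cos(angles)
        cy = self.region_size / 2 + radius * np.sin(angles)
        jitter = rng.normal(scale=0.04 * self.region_size, size=(K, 2))
        return np.column_stack([cx, cy]) + jitter


@dataclass
class TruthRecord:
    """Ground truth of one simulation run."""

    migration_matrix: np.ndarray  # the per-generation matrix actually applied
    initial_freqs: list  # per locus: (n_alleles,) ancestral-pool frequencies
    final_freqs: list  # per locus: (K, n_alleles)
    source_population: list  # per individual
    behaviours: list
    ancestry: list | None = None  # per individual (source, generation) if recent sampling

    def __post_init__(self) -> None:
        m = np.asarray(self.migration_matrix)
        if ((m < -1e-12) | (m > 1 + 1e-12)).any():
            raise ValidationError("realized migration rates outside [0, 1]")
        for fl in self.final_freqs:
            s = np.asarray(fl).sum(axis=-1)
            if not np.allclose(s, 1.0, atol=1e-9):
                raise ValidationError("final allele frequencies do not sum to 1")


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------


def make_landscape(
    config: SimulationConfig, with_barriers: bool = False
) -> tuple[ResistanceSurface, BarrierSet | None]:
    """Smooth positive-cost raster (base cost + Gaussian bumps), optionally a
    high-cost wall with a single gap and a set of barrier polylines.

    Deterministic given ``config.rng_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 0x1A]))
    nr, nc = config.raster_shape
    cell = config.region_size / max(nr, nc)
    ys, xs = np.mgrid[0:nr, 0:nc]
    # cell centers in map units (row 0 = top)
    cx = (xs + 0.5) * cell
    cy = (nr - ys - 0.5) * cell
    cost = np.ones((nr, nc))
    for _ in range(config.landscape_n_bumps):
        bx, by = rng.uniform(0, config.region_size, size=2)
        amp = config.landscape_bump_amplitude * rng.uniform(0.5, 1.0)
        sig = config.landscape_bump_sigma * rng.uniform(0.6, 1.4)
        cost += amp * np.exp(-(((cx - bx) ** 2 + (cy - by) ** 2) / (2 * sig**2)))
    barriers = None
    if config.landscape_wall:
        wall_col = nc // 2
        gap = slice(nr // 2 - max(nr // 20, 1), nr // 2 + max(nr // 20, 1))
        cost[:, wall_col] += config.landscape_wall_cost
        cost[gap, wall_col] -= config.landscape_wall_cost
    if with_barriers:
        from shapely.geometry import LineString

        feats = []
        for _ in range(3):
            x0 = rng.uniform(0.2, 0.8) * config.region_size
            feats.append(
                LineString([(x0, 0.0), (x0 + rng.normal(scale=5_000.0), config.region_size)])
            )
        barriers = BarrierSet(features=feats, barrier_class="linear_features")
    surface = ResistanceSurface(values=cost, cell_size=cell, origin_x=0.0, origin_y=0.0)
    return surface, barriers


def _centroid_distances(
    config: SimulationConfig, surface: ResistanceSurface | None
) -> np.ndarray:
    cents = config.centroids()
    if config.migration_model == "resistance_decay":
        if surface is None:
            raise ValidationError("resistance_decay migration requires a resistance surface")
        from scipy.sparse.csgraph import dijkstra

        from .landscape_distance import _lattice_graph

        graph = _lattice_graph(surface)
        cells = np.array(
            [r * surface.n_cols + c for r, c in (surface.cell_of(x, y) for x, y in cents)]
        )
        sources, inverse = np.unique(cells, return_inverse=True)
        dm = dijkstra(graph, directed=False, indices=sources)
        return dm[inverse][:, cells]
    diff = cents[:, None, :] - cents[None, :, :]
    return np.hypot(diff[:, :, 0], diff[:, :, 1])


def migration_matrix_for(config: SimulationConfig, surface: ResistanceSurface | None = None) -> np.ndarray:
    """The K x K per-generation migration matrix implied by the config."""
    K = config.n_populations
    if config.true_migration_matrix is not None:
        return np.asarray(config.true_migration_matrix, dtype=float)
    if config.migration_model == "island":
        # handled specially in the simulator (pool immigration); the matrix
        # form records the immigration fraction on the off-diagonal uniformly
        m = np.full((K, K), config.island_m / max(K - 1, 1))
        np.fill_diagonal(m, 0.0)
        np.fill_diagonal(m, 1.0 - m.sum(axis=1))
        return m
    d = _centroid_distances(config, surface)
    w = np.exp(-d / config.decay_scale)
    np.fill_diagonal(w, 0.0)
    total = min(config.total_immigration, MAX_IMMIGRATION)
    m = total * w / w.sum(axis=1, keepdims=True)
    np.fill_diagonal(m, 1.0 - m.sum(axis=1))
    return m


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------


def _draw_initial_freqs(config: SimulationConfig, rng: np.random.Generator) -> list:
    lo, hi = config.n_alleles_per_locus
    freqs = []
    for _ in range(config.n_loci):
        A = int(rng.integers(lo, hi + 1))
        freqs.append(rng.dirichlet(np.ones(A)))
    return freqs


def _drift_generations(
    pool: list,
    config: SimulationConfig,
    m: np.ndarray,
    rng: np.random.Generator,
    n_generations: int | None = None,
) -> list:
    """Run Wright-Fisher drift with migration; returns per-locus (K, A) freqs."""
    K = config.n_populations
    N = np.asarray(config.pop_sizes)
    island = config.migration_model == "island" and config.true_migration_matrix is None
    freqs = [np.tile(f, (K, 1)) for f in pool]
    n_gen = config.n_generations if n_generations is None else n_generations
    for _ in range(n_gen):
        for l, fl in enumerate(freqs):
            if island:
                mixed = (1 - config.island_m) * fl + config.island_m * pool[l][None, :]
            else:
                mixed = m @ fl
            new = np.empty_like(fl)
            for k in range(K):
                counts = rng.multinomial(2 * N[k], np.maximum(mixed[k], 0.0) / mixed[k].sum())
                new[k] = counts / (2 * N[k])
            freqs[l] = new
    return freqs


def _sample_hw(fl_row: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 2) allele codes (1-based) drawn Hardy-Weinberg from one frequency row."""
    return rng.choice(len(fl_row), size=(n, 2), p=fl_row) + 1


def simulate_genotypes(
    config: SimulationConfig, surface: ResistanceSurface | None = None
) -> tuple[GenotypeTable, TruthRecord]:
    """Forward-time simulation to a sampled GenotypeTable plus ground truth."""
    if config.migration_model == "resistance_decay" and surface is None:
        raise ValidationError("resistance_decay migration requires a resistance surface")
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 0x5E]))
    K = config.n_populations
    pool = _draw_initial_freqs(config, rng)
    m = migration_matrix_for(config, surface)
    # the drift history may differ from the sampling-time migration: the
    # recent-migration estimator's own model is differentiated populations
    # exchanging migrants in the last one or two generations only
    m_history = m
    if config.history_migration_matrix is not None:
        m_history = np.asarray(config.history_migration_matrix, dtype=float)
    elif config.recent_migrant_ancestry:
        m_history = np.eye(K)
    freqs = _drift_generations(pool, config, m_history, rng)
    pure_freqs = None
    if config.sedentary_pure_descent:
        # a parallel no-immigration lineage for sedentary individuals
        rng_pure = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 0x5F]))
        pure_freqs = _drift_generations(pool, _replace_model(config), np.eye(K), rng_pure)
    cents = config.centroids()
    ids: list[str] = []
    pops: list[str] = []
    behaviours: list[str] = []
    xs: list[float] = []
    ys: list[float] = []
    sources: list[str] = []
    ancestry: list[tuple[int, int]] | None = (
        [] if config.recent_migrant_ancestry else None
    )
    n_total = int(sum(config.n_individuals_per_pop))
    alleles = np.zeros((n_total, config.n_loci, 2), dtype=np.int32)
    row = 0
    pm = config.behaviour_fraction_migratory
    ps = config.behaviour_fraction_sedentary
    for k in range(K):
        n_k = config.n_individuals_per_pop[k]
        states = ancestry_state_table(K, k)
        prior = ancestry_prior_row(m, k) if config.recent_migrant_ancestry else None
        for _ in range(n_k):
            u = rng.uniform()
            behaviour = (
                "migratory" if u < pm else "sedentary" if u < pm + ps else "unclassified"
            )
            if config.recent_migrant_ancestry:
                s = int(rng.choice(len(states), p=prior))
                src, gen = states[s]
            else:
                src, gen = k, 0
            use_pure = (
                pure_freqs is not None and behaviour == "sedentary" and gen == 0
            )
            for l in range(config.n_loci):
                fl = (pure_freqs if use_pure else freqs)[l]
                if gen == 0:
                    alleles[row, l] = _sample_hw(fl[k], 1, rng)[0]
                elif gen == 1:
                    alleles[row, l] = _sample_hw(fl[src], 1, rng)[0]
                else:  # one gene from the source, one from home
                    a = rng.choice(len(fl[src]), p=fl[src]) + 1
                    b = rng.choice(len(fl[k]), p=fl[k]) + 1
                    alleles[row, l] = (a, b)
            ids.append(f"ind{row + 1:03d}")
            pops.append(f"pop{k + 1}")
            sources.append(f"pop{src + 1}")
            behaviours.append(behaviour)
            if ancestry is not None:
                ancestry.append((src, gen))
            xs.append(cents[k, 0] + rng.normal(scale=config.scatter_sd))
            ys.append(cents[k, 1] + rng.normal(scale=config.scatter_sd))
            row += 1
    du = ["DU-south" if k < K // 2 else "DU-north" for k in range(K)]
    table = GenotypeTable(
        individual_ids=ids,
        population_ids=pops,
        locus_names=[f"loc{l + 1}" for l in range(config.n_loci)],
        alleles=alleles,
        x=np.array(xs),
        y=np.array(ys),
        du_ids=[du[int(p[3:]) - 1] for p in pops],
        behaviours=behaviours,
    )
    truth = TruthRecord(
        migration_matrix=m,
        initial_freqs=pool,
        final_freqs=freqs,
        source_population=sources,
        behaviours=behaviours,
        ancestry=ancestry,
    )
    return table, truth


def _replace_model(cfg: SimulationConfig) -> SimulationConfig:
    """Config clone whose migration model is inert (identity matrix passed)."""
    from dataclasses import replace

    return replace(cfg, migration_model="distance_decay", true_migration_matrix=np.eye(cfg.n_populations))
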