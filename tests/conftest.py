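import numpy as np
import pytest

from landgenkit.core_data import MISSING, GenotypeTable


def build_table(genotypes, populations=None, coords=None, locus_names=None, **kw):
    """Compact GenotypeTable factory.

    ``genotypes``: list of per-individual locus genotypes, e.g.
    ``[[(1, 1), (3, 4)], [(1, 2), (3, 3)]]``; ``None`` marks a missing locus.
    """
    n = len(genotypes)
    L = len(genotypes[0])
    alleles = np.full((n, L, 2), MISSING, dtype=np.int32)
    for i, row in enumerate(genotypes):
        for l, geno in enumerate(row):
            if geno is not None:
                alleles[i, l] = geno
    if coords is None:
        coords = [(float(i), float(i % 3)) for i in range(n)]
    xs, ys = zip(*coords)
    return GenotypeTable(
        individual_ids=kw.pop("individual_ids", [f"i{k}" for k in range(n)]),
        population_ids=populations or ["p1"] * n,
        locus_names=locus_names or [f"L{k}" for k in range(L)],
        alleles=alleles,
        x=np.array(xs),
        y=np.array(ys),
        **kw,
    )


@pytest.fixture
def ar_fixture_table():
    """4 individuals, 2 loci — the hand-counted Rousset a_r worked example."""
    return build_table(
        [
            [(1, 1), (3, 4)],
            [(1, 2), (3, 3)],
            [(2, 2), (4, 4)],
            [(1, 2), (3, 4)],
        ]
    )


@pytest.fixture(scope="session")
def sim_table():
    """A medium simulated table shared by read-only tests."""
    from landgenkit.synthetic_data import SimulationConfig, simulate_genotypes

    cfg = SimulationConfig(
        n_populations=3,
        n_individuals_per_pop=(12, 12, 12),
        n_loci=8,
        n_generations=40,
        pop_sizes=60,
        rng_seed=7,
    )
    table, truth = simulate_genotypes(cfg)
    return table


def random_distance_matrix(n, rng, labels=None, kind="other"):
    from landgenkit.core_data import DistanceMatrix

    pts = rng.normal(size=(n, 2))
    d = np.hypot(pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1])
    return DistanceMatrix(
        labels=labels or [f"u{k}" for k in range(n)], values=d, kind=kind
    )
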