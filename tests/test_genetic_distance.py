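"""Allele frequencies, Rousset's a_r, and Weir-Cockerham pairwise theta."""

import numpy as np
import pytest

from landgenkit.errors import DegenerateDataError
from landgenkit.genetic_distance import (
    allele_frequencies,
    identity_probabilities,
    pairwise_fst,
    rousset_ar,
)
from landgenkit.synthetic_data import SimulationConfig, simulate_genotypes

from conftest import build_table


class TestAlleleFrequencies:
    def test_counting_two_individuals(self):
        t = build_table([[(1, 1)], [(1, 2)]])
        f = allele_frequencies(t, by="pooled")
        assert f.freqs["pooled"]["L0"] == {1: 0.75, 2: 0.25}

    def test_all_missing_locus_excluded_with_warning(self, caplog):
        t = build_table([[(1, 1), None], [(1, 2), None]])
        with caplog.at_level("WARNING"):
            f = allele_frequencies(t, by="pooled")
        assert f.freqs["pooled"]["L1"] == {}
        assert "entirely missing" in caplog.text

    def test_matches_hand_tally_on_random_fixture(self):
        rng = np.random.default_rng(12)
        genos = [
            [tuple(rng.integers(1, 5, size=2)) if rng.uniform() > 0.15 else None
             for _ in range(3)]
            for _ in range(10)
        ]
        t = build_table(genos)
        f = allele_frequencies(t, by="pooled")
        # brute-force tally oracle
        for l, name in enumerate(t.locus_names):
            tally = {}
            total = 0
            for row in genos:
                if row[l] is None:
                    continue
                for a in row[l]:
                    tally[a] = tally.get(a, 0) + 1
                    total += 1
            expected = {a: c / total for a, c in tally.items()}
            got = f.freqs["pooled"][name]
            assert set(got) == set(expected)
            for a in expected:
                assert got[a] == pytest.approx(expected[a], abs=1e-12)
            assert f.gene_counts["pooled"][name] % 2 == 0


class TestRoussetAr:
    def test_hand_counted_fixture(self, ar_fixture_table):
        # Qw = 0.5 at both loci; denominators all 1; numerators tallied by hand
        expected = np.array(
            [
                [0.0, 0.0, 0.5, 0.0],
                [0.0, 0.0, 0.5, 0.0],
                [0.5, 0.5, 0.0, 0.0],
                [0.0, 0.0, 0.0, 0.0],
            ]
        )
        ar = rousset_ar(ar_fixture_table)
        assert np.allclose(ar.values, expected, atol=1e-12, rtol=0)

    def test_identity_probabilities_bounds(self, sim_table):
        qw, qij = identity_probabilities(sim_table)
        assert np.nanmin(qw) >= 0 and np.nanmax(qw) <= 1
        assert np.nanmin(qij) >= 0 and np.nanmax(qij) <= 1

    def test_fully_heterozygous_no_shared_alleles_gives_zero(self):
        # every individual heterozygous (Qw = 0), pair shares no alleles
        t = build_table([[(1, 2), (5, 6)], [(3, 4), (7, 8)]])
        ar = rousset_ar(t)
        assert ar.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_twin_pair_is_closest(self):
        genos = [
            [(1, 2), (3, 4)],
            [(1, 2), (3, 4)],  # twin of i0
            [(5, 6), (7, 8)],
            [(1, 5), (3, 7)],
            [(2, 6), (4, 8)],
        ]
        ar = rousset_ar(build_table(genos))
        twin = ar.values[0, 1]
        others = [ar.values[i, j] for i in range(5) for j in range(i + 1, 5) if (i, j) != (0, 1)]
        assert all(twin <= v + 1e-12 for v in others)

    def test_allele_relabelling_invariance(self, sim_table):
        ar1 = rousset_ar(sim_table)
        relabeled = sim_table.subset(np.arange(sim_table.n_individuals))
        # permute allele identifiers per locus
        rng = np.random.default_rng(5)
        alleles = relabeled.alleles.copy()
        for l in range(relabeled.n_loci):
            obs = np.unique(alleles[:, l, :][alleles[:, l, :] > 0])
            newcode = dict(zip(obs, rng.permutation(obs) + 100))
            for a, b in newcode.items():
                alleles[:, l, :][relabeled.alleles[:, l, :] == a] = b
        relabeled.alleles = alleles
        ar2 = rousset_ar(relabeled)
        assert np.allclose(ar1.values, ar2.values, atol=1e-12, rtol=0)

    def test_missing_loci_pairwise_deletion(self):
        t_full = build_table([[(1, 1), (3, 4)], [(1, 2), (3, 3)], [(2, 2), (4, 4)]])
        t_miss = build_table([[(1, 1), (3, 4)], [(1, 2), None], [(2, 2), (4, 4)]])
        ar = rousset_ar(t_miss)
        # pair (0, 2) unaffected by i1's missing locus only through Qw of locus 2,
        # which still uses the scored individuals: recompute expectation directly
        qw, qij = identity_probabilities(t_miss)
        num = (qw[0] - qij[0, 1, 0])
        den = (1 - qw[0])
        assert ar.values[0, 1] == pytest.approx(num / den, abs=1e-12)

    def test_degenerate_all_homozygous_shared(self):
        t = build_table([[(1, 1)], [(1, 1)]])
        with pytest.raises(DegenerateDataError):
            rousset_ar(t)


def _wc_theta_textbook(n_i, n_j, counts_i, counts_j):
    """Independent textbook Weir & Cockerham (1984) theta for one locus,
    two demes, written directly from the printed formulas.

    counts_* map allele -> (n_hom, n_het): individuals homozygous for the
    allele and heterozygous carrying it.
    """
    alleles = sorted(set(counts_i) | set(counts_j))
    r = 2
    n = [n_i, n_j]
    nbar = sum(n) / r
    nc = (sum(n) - sum(v * v for v in n) / sum(n)) / (r - 1)
    A = B = C = 0.0
    for a in alleles:
        p = []
        h = []
        for k, counts in enumerate((counts_i, counts_j)):
            hom, het = counts.get(a, (0, 0))
            p.append((2 * hom + het) / (2 * n[k]))
            h.append(het / n[k])
        pbar = sum(n[k] * p[k] for k in range(r)) / (r * nbar)
        s2 = sum(n[k] * (p[k] - pbar) ** 2 for k in range(r)) / ((r - 1) * nbar)
        hbar = sum(n[k] * h[k] for k in range(r)) / (r * nbar)
        a_comp = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b_comp = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c_comp = hbar / 2
        A += a_comp
        B += b_comp
        C += c_comp
    return A / (A + B + C)


class TestPairwiseFst:
    def test_fixed_differences_give_theta_one(self):
        genos = [[(1, 1), (3, 3)]] * 4 + [[(2, 2), (4, 4)]] * 4
        t = build_table(genos, populations=["A"] * 4 + ["B"] * 4)
        f = pairwise_fst(t)
        assert f.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_duplicated_population_theta_near_zero(self):
        cfg = SimulationConfig(
            n_populations=2,
            n_individuals_per_pop=(50, 50),
            n_loci=14,
            n_generations=1,
            pop_sizes=500,
            true_migration_matrix=np.eye(2),
            rng_seed=21,
        )
        table, _ = simulate_genotypes(cfg)
        # both pops sampled from (almost) the ancestral pool after 1 generation
        f = pairwise_fst(table)
        assert abs(f.values[0, 1]) < 0.05

    def test_two_pop_one_locus_matches_textbook_script(self):
        # pop A: 3x(1,1), 2x(1,2), 1x(2,2); pop B: 1x(1,1), 2x(1,2), 4x(2,2)
        genos_a = [[(1, 1)]] * 3 + [[(1, 2)]] * 2 + [[(2, 2)]]
        genos_b = [[(1, 1)]] + [[(1, 2)]] * 2 + [[(2, 2)]] * 4
        t = build_table(genos_a + genos_b, populations=["A"] * 6 + ["B"] * 7)
        f = pairwise_fst(t)
        expected = _wc_theta_textbook(
            6, 7, {1: (3, 2), 2: (1, 2)}, {1: (1, 2), 2: (4, 2)}
        )
        assert f.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_relabelling_invariance(self, sim_table):
        f1 = pairwise_fst(sim_table)
        shifted = sim_table.subset(np.arange(sim_table.n_individuals))
        shifted.alleles = np.where(
            shifted.alleles > 0, shifted.alleles + 50, shifted.alleles
        )
        f2 = pairwise_fst(shifted)
        assert np.allclose(f1.values, f2.values, atol=1e-12, rtol=0)

    def test_negative_estimates_retained(self):
        rng = np.random.default_rng(3)
        genos = [[tuple(rng.integers(1, 3, size=2)) for _ in range(5)] for _ in range(12)]
        t = build_table(genos, populations=["A"] * 6 + ["B"] * 6)
        f = pairwise_fst(t)
        assert np.isfinite(f.values[0, 1])  # whatever the sign, it is reported
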