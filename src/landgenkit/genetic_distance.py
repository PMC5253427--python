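"""Individual- and population-level genetic distances from microsatellite genotypes.

Two estimators:

* Rousset's *a_r* between individuals — the identity-probability distance
  ``a_r(i, j) = sum_l (Qw_l - Qij_l) / sum_l (1 - Qw_l)`` where ``Qw_l`` is the
  mean within-individual identity in state at locus *l* over the whole sample
  and ``Qij_l`` the mean identity over the four between-individual gene pairs.
* Weir & Cockerham's theta (pairwise F_ST) between populations — multi-locus
  ratio of sums of the a/b/c variance components.

Missing genotypes are handled by locus-pairwise deletion: a locus missing in
either member of a pair is dropped from both the numerator and the denominator
for that pair.  Negative estimates are reported as computed (no truncation):
downstream Mantel/DISTLM analyses operate on the raw estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_data import MISSING, DistanceMatrix, GenotypeTable
from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class AlleleFrequencies:
    """Observed allele frequencies per group (population or pooled) per locus.

    ``freqs[group][locus]`` maps allele code -> frequency; ``gene_counts`` holds
    the number of scored gene copies behind each estimate (always even:
    diploids are dropped locus-wise, never half-counted).
    """

    groups: list[str]
    locus_names: list[str]
    freqs: dict
    gene_counts: dict

    def alleles_at(self, locus: str) -> list[int]:
        """Sorted union of allele codes observed at a locus across groups."""
        seen: set[int] = set()
        for g in self.groups:
            seen.update(self.freqs[g][locus])
        return sorted(seen)


def allele_frequencies(g: GenotypeTable, by: str = "population") -> AlleleFrequencies:
    """Tally observed allele frequencies, excluding missing genotypes locus-wise.

    ``by="pooled"`` treats the whole table as one group labelled ``"pooled"``.
    A locus entirely missing within a group is flagged with a warning and gets
    an empty frequency dict (excluded downstream).
    """
    if by not in ("population", "pooled"):
        raise ValidationError(f"unknown grouping {by!r}")
    if by == "pooled":
        group_of = {"pooled": np.ones(g.n_individuals, dtype=bool)}
    else:
        group_of = {
            p: np.array([q == p for q in g.population_ids]) for p in g.populations
        }
    freqs: dict = {}
    counts: dict = {}
    for grp, mask in group_of.items():
        freqs[grp] = {}
        counts[grp] = {}
        sub = g.alleles[mask]
        for l, name in enumerate(g.locus_names):
            col = sub[:, l, :].ravel()
            col = col[col != MISSING]
            counts[grp][name] = int(col.size)
            if col.size == 0:
                logger.warning("locus %r entirely missing in group %r", name, grp)
                freqs[grp][name] = {}
                continue
            vals, n = np.unique(col, return_counts=True)
            freqs[grp][name] = {int(a): c / col.size for a, c in zip(vals, n)}
    return AlleleFrequencies(
        groups=list(group_of), locus_names=list(g.locus_names), freqs=freqs, gene_counts=counts
    )


# ---------------------------------------------------------------------------
# Rousset's a_r
# ---------------------------------------------------------------------------


def identity_probabilities(g: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus within-individual identity Qw and pairwise identity Qij.

    Returns ``(qw, qij)``: ``qw`` is (L,) with NaN where no individual is
    scored; ``qij`` is (n, n, L) with NaN where either individual is missing.
    ``qij[i, j, l]`` is the mean of the four between-individual allele
    comparisons (identity in state, not descent).
    """
    a = g.alleles  # (n, L, 2)
    miss = g.missing_mask()  # (n, L)
    with np.errstate(invalid="ignore"):
        within = (a[:, :, 0] == a[:, :, 1]).astype(float)
        within[miss] = np.nan
        qw = np.nanmean(within, axis=0) if len(a) else np.full(g.n_loci, np.nan)
    # four cross comparisons, vectorized over pairs
    a0 = a[:, :, 0]
    a1 = a[:, :, 1]
    qij = (
        (a0[:, None, :] == a0[None, :, :]).astype(float)
        + (a0[:, None, :] == a1[None, :, :])
        + (a1[:, None, :] == a0[None, :, :])
        + (a1[:, None, :] == a1[None, :, :])
    ) / 4.0
    pair_miss = miss[:, None, :] | miss[None, :, :]
    qij[pair_miss] = np.nan
    return qw, qij


def rousset_ar(g: GenotypeTable) -> DistanceMatrix:
    """Rousset's genetic distance *a_r* between all individual pairs.

    The within-individual reference Qw is computed over the whole sample per
    locus (the convention of the SPAGeDi software); for each pair, loci where
    either individual is unscored are dropped from both sums.
    """
    if g.n_individuals < 2:
        raise ValidationError("a_r needs at least 2 individuals")
    qw, qij = identity_probabilities(g)
    n = g.n_individuals
    num_terms = qw[None, None, :] - qij  # (n, n, L); NaN where pair-missing
    den_terms = np.broadcast_to((1.0 - qw)[None, None, :], qij.shape).copy()
    den_terms[np.isnan(qij)] = np.nan
    with np.errstate(invalid="ignore"):
        num = np.nansum(num_terms, axis=2)
        den = np.nansum(den_terms, axis=2)
    usable = (~np.isnan(qij)).sum(axis=2) > 0
    values = np.full((n, n), np.nan)
    zero_den = usable & (den <= 0)
    off = ~np.eye(n, dtype=bool)
    if zero_den[off].all():
        raise DegenerateDataError(
            "sum_l (1 - Qw_l) is zero for every pair: no within-individual "
            "heterozygosity anywhere in the sample"
        )
    ok = usable & (den > 0)
    values[ok] = num[ok] / den[ok]
    values[~usable] = np.nan
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(
        labels=list(g.individual_ids), values=values, kind="genetic_ar", diagonal_policy="zero"
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham pairwise F_ST
# ---------------------------------------------------------------------------


def _wc_components_pair(g: GenotypeTable, mask_i: np.ndarray, mask_j: np.ndarray):
    """Sum of W&C (1984) a, b, c variance components over loci and alleles
    for one pair of populations (r = 2 demes)."""
    sum_a = sum_b = sum_c = 0.0
    any_locus = False
    for l in range(g.n_loci):
        comps = []
        for mask in (mask_i, mask_j):
            al = g.alleles[mask, l, :]
            al = al[al[:, 0] != MISSING]
            comps.append(al)
        ni, nj = len(comps[0]), len(comps[1])
        if ni < 1 or nj < 1 or ni + nj < 3:
            continue
        alleles = np.unique(np.concatenate([comps[0].ravel(), comps[1].ravel()]))
        if len(alleles) < 2:
            # monomorphic locus for this pair: contributes nothing
            any_locus = True
            continue
        n = np.array([ni, nj], dtype=float)
        r = 2
        nbar = n.mean()
        nc = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)
        for allele in alleles:
            p = np.array(
                [
                    (comps[k] == allele).sum() / (2 * n[k])
                    for k in range(2)
                ]
            )
            h = np.array(
                [
                    (
                        ((comps[k][:, 0] == allele) ^ (comps[k][:, 1] == allele)).sum()
                        / n[k]
                    )
                    for k in range(2)
                ]
            )
            pbar = (n * p).sum() / (r * nbar)
            s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n * h).sum() / (r * nbar)
            a = (nbar / nc) * (
                s2
                - (1.0 / (nbar - 1))
                * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - s2 * (r - 1) / r
                - hbar * (2 * nbar - 1) / (4 * nbar)
            )
            c = hbar / 2.0
            sum_a += a
            sum_b += b
            sum_c += c
        any_locus = True
    return sum_a, sum_b, sum_c, any_locus


def pairwise_fst(g: GenotypeTable) -> DistanceMatrix:
    """Pairwise Weir–Cockerham theta between populations (multi-locus ratio of sums).

    Negative estimates are retained as computed.  A population pair with no
    shared scored polymorphic locus gets a NaN entry and a logged warning.
    """
    pops = g.populations
    if len(pops) < 2:
        raise ValidationError("pairwise F_ST needs at least 2 populations")
    masks = {p: np.array([q == p for q in g.population_ids]) for p in pops}
    k = len(pops)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sa, sb, sc, ok = _wc_components_pair(g, masks[pops[i]], masks[pops[j]])
            tot = sa + sb + sc
            if not ok or tot == 0.0:
                logger.warning(
                    "population pair (%s, %s) has no usable shared locus", pops[i], pops[j]
                )
                theta = np.nan
            else:
                theta = sa / tot
            values[i, j] = values[j, i] = theta
    return DistanceMatrix(labels=pops, values=values, kind="fst", diagonal_policy="zero")
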