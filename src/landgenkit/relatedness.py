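"""Maximum-likelihood pairwise relatedness from codominant genotypes.

For each pair of non-inbred individuals the IBD-coefficient vector
(k0, k1, k2) — the probabilities of sharing zero, one or two gene pairs
identical by descent — is estimated by maximizing the product over loci of
the genotype-pair likelihood

    P(G_i, G_j | k) = k0 * P0 + k1 * P1 + k2 * P2,

with P0/P1/P2 the classical zero/one/two-gene transition probabilities under
the pooled allele frequencies (Thompson's tables).  The point estimate of
relatedness is ``r_hat = k1/2 + k2``.

The maximizer is a coarse simplex grid (step 0.05) followed by a compass
(pattern) local search with shrinking steps; ties are broken toward larger k0
(less related).  The k-simplex is deliberately NOT restricted by the
genealogical constraint k1^2 >= 4*k0*k2.

Null alleles: when requested, a per-locus null-allele frequency is estimated
from the heterozygote deficit (Brookfield's estimator 1, (He-Ho)/(1+He)) and
an extra allele is appended to the frequency set; an observed homozygote is
then treated as the mixture {true homozygote, null heterozygote}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import MISSING, DistanceMatrix, GenotypeTable
from .errors import ValidationError
from .genetic_distance import AlleleFrequencies, allele_frequencies

CATEGORIES = ("unrelated", "weak", "moderate", "high", "full")

NULL_CODE = 0  # allele code reserved for the latent null allele


@dataclass
class RelatednessEstimate:
    pair: tuple[str, str]
    k0: float
    k1: float
    k2: float
    r_hat: float
    category: str
    p_value: float | None = None


def categorize_relatedness(r_hat: float) -> str:
    """Translate r_hat into the printed category intervals.

    0 -> unrelated; (0, 0.25] -> weak; (0.25, 0.5] -> moderate;
    (0.5, 1) -> high; exactly 1 -> full.
    """
    if not (0.0 <= r_hat <= 1.0) or not np.isfinite(r_hat):
        raise ValidationError(f"r_hat {r_hat} outside [0, 1]")
    if r_hat == 0.0:
        return "unrelated"
    if r_hat == 1.0:
        return "full"
    if r_hat <= 0.25:
        return "weak"
    if r_hat <= 0.5:
        return "moderate"
    return "high"


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


def _genotype_pair_triples(x1, x2, y1, y2, pa, pb, pc, pd):
    """Vectorized (P0, P1, P2) for genotype pairs {x1,x2} vs {y1,y2}.

    ``pa..pd`` are the allele frequencies of x1, x2, y1, y2.  Implements the
    standard transition probabilities via the unified identities
    P0 = P(Gi) P(Gj);  P2 = [Gi == Gj unordered] P(Gi);
    P1 = P(Gi)/2 * sum_{g in Gi} f(Gj, g)  with
    f({c,d}, g) = (d(c,g) p_d + d(d,g) p_c) / (1 + d(c,d)).
    """
    dab = (x1 == x2).astype(float)
    dcd = (y1 == y2).astype(float)
    Pi = (2.0 - dab) * pa * pb
    Pj = (2.0 - dcd) * pc * pd
    P0 = Pi * Pj
    eq = ((x1 == y1) & (x2 == y2)) | ((x1 == y2) & (x2 == y1))
    P2 = eq.astype(float) * Pi
    def f_of(g):
        return ((y1 == g).astype(float) * pd + (y2 == g).astype(float) * pc) / (1.0 + dcd)
    P1 = Pi / 2.0 * (f_of(x1) + f_of(x2))
    return P0, P1, P2


def _locus_freq_lookup(freqs: AlleleFrequencies, locus: str, null_freq: float = 0.0):
    """Return (codes, values) arrays for frequency lookup at one locus.

    With a null allele, observed frequencies are scaled by (1 - null_freq) and
    code ``NULL_CODE`` carries the null frequency.
    """
    fdict = freqs.freqs[freqs.groups[0]][locus]
    codes = np.array(sorted(fdict), dtype=np.int32)
    vals = np.array([fdict[c] for c in codes], dtype=float)
    if null_freq > 0.0:
        vals = vals * (1.0 - null_freq)
        codes = np.concatenate([[NULL_CODE], codes])
        vals = np.concatenate([[null_freq], vals])
    return codes, vals


def _lookup(codes: np.ndarray, vals: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(codes, alleles)
    idx = np.clip(idx, 0, len(codes) - 1)
    out = np.where(codes[idx] == alleles, vals[idx], 0.0)
    return out


def brookfield_null_freq(g: GenotypeTable, freqs: AlleleFrequencies) -> np.ndarray:
    """Brookfield (1996) estimator 1 of the null-allele frequency per locus:
    (He - Ho) / (1 + He), clipped at zero."""
    out = np.zeros(g.n_loci)
    miss = g.missing_mask()
    grp = freqs.groups[0]
    for l, name in enumerate(g.locus_names):
        scored = ~miss[:, l]
        if scored.sum() == 0:
            continue
        a = g.alleles[scored, l, :]
        ho = float((a[:, 0] != a[:, 1]).mean())
        f = np.array(list(freqs.freqs[grp][name].values()))
        he = 1.0 - float((f**2).sum())
        out[l] = max(0.0, (he - ho) / (1.0 + he))
    return out


def _pair_locus_mixture(
    g: GenotypeTable,
    pairs: np.ndarray,
    freqs: AlleleFrequencies,
    null_alleles: bool,
) -> np.ndarray:
    """(n_pairs, L, 3) array of P0/P1/P2 per pair per locus.

    Loci missing in either member contribute (1, 1, 1): a neutral factor in
    the likelihood product (locus-pairwise deletion).
    """
    n_pairs = len(pairs)
    L = g.n_loci
    out = np.ones((n_pairs, L, 3))
    null_f = (
        brookfield_null_freq(g, freqs) if null_alleles else np.zeros(L)
    )
    i_idx = pairs[:, 0]
    j_idx = pairs[:, 1]
    for l, name in enumerate(g.locus_names):
        codes, vals = _locus_freq_lookup(freqs, name, null_f[l])
        x1 = g.alleles[i_idx, l, 0]
        x2 = g.alleles[i_idx, l, 1]
        y1 = g.alleles[j_idx, l, 0]
        y2 = g.alleles[j_idx, l, 1]
        ok = (x1 != MISSING) & (y1 != MISSING)
        if not ok.any():
            continue

        def triples(a1, a2, b1, b2):
            return _genotype_pair_triples(
                a1, a2, b1, b2,
                _lookup(codes, vals, a1), _lookup(codes, vals, a2),
                _lookup(codes, vals, b1), _lookup(codes, vals, b2),
            )

        P0, P1, P2 = triples(x1, x2, y1, y2)
        if null_alleles and null_f[l] > 0.0:
            hom_i = (x1 == x2) & ok
            hom_j = (y1 == y2) & ok
            nul = np.full_like(x1, NULL_CODE)
            for mask_i, mask_j, a2_, b2_ in (
                (hom_i, np.ones_like(hom_j), nul, y2),
                (np.ones_like(hom_i), hom_j, x2, nul),
                (hom_i, hom_j, nul, nul),
            ):
                q0, q1, q2 = triples(x1, a2_, y1, b2_)
                w = (mask_i & mask_j).astype(float)
                P0 = P0 + w * q0
                P1 = P1 + w * q1
                P2 = P2 + w * q2
        out[ok, l, 0] = P0[ok]
        out[ok, l, 1] = P1[ok]
        out[ok, l, 2] = P2[ok]
    return out


def _simplex_grid(step: float = 0.05) -> np.ndarray:
    """(G, 3) grid over the k-simplex, ordered by decreasing k0 so that argmax
    tie-breaking lands on the least-related point."""
    pts = []
    m = int(round(1.0 / step))
    for i1 in range(m + 1):
        for i2 in range(m + 1 - i1):
            k1 = i1 * step
            k2 = i2 * step
            pts.append((1.0 - k1 - k2, k1, k2))
    pts.sort(key=lambda t: (-t[0], t[1]))
    return np.array(pts)


_GRID = _simplex_grid(0.05)


def _loglik(P: np.ndarray, k: np.ndarray) -> np.ndarray:
    """log-likelihood for P (B, L, 3) under coefficient rows k (..., 3)."""
    mix = P @ k.T if k.ndim == 2 else (P * k).sum(axis=-1)
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(mix, 1e-300)).sum(axis=1)


def fit_k_batch(P: np.ndarray, tol: float = 1e-4) -> np.ndarray:
    """Constrained MLE of (k0, k1, k2) for a batch of pairs.

    ``P`` is (B, L, 3).  Coarse grid (step 0.05), then a compass search over
    (k1, k2) with step halving down to ``tol``.  Returns (B, 3).
    """
    B = P.shape[0]
    ks = np.empty((B, 3))
    chunk = 2048
    for s in range(0, B, chunk):
        Pc = P[s : s + chunk]
        ll = _loglik(Pc, _GRID)  # (b, G)
        best = np.argmax(ll, axis=1)
        k12 = _GRID[best][:, 1:].copy()  # (b, 2)

        # vectorized loglik at arbitrary per-pair points
        def ll_at(pts):
            kfull = np.column_stack([1 - pts.sum(axis=1), pts])
            mix = (Pc * kfull[:, None, :]).sum(axis=2)
            with np.errstate(divide="ignore"):
                return np.log(np.maximum(mix, 1e-300)).sum(axis=1)

        cur = ll_at(k12)
        step = 0.05
        while step > tol:
            improved = np.zeros(len(k12), dtype=bool)
            for d in ((step, 0.0), (-step, 0.0), (0.0, step), (0.0, -step)):
                cand = k12 + np.array(d)
                feasible = (
                    (cand[:, 0] >= -1e-12)
                    & (cand[:, 1] >= -1e-12)
                    & (cand.sum(axis=1) <= 1.0 + 1e-12)
                )
                cand = np.clip(cand, 0.0, 1.0)
                trial = np.where(feasible[:, None], cand, k12)
                llt = ll_at(trial)
                gain = feasible & (llt > cur + 1e-12)
                k12[gain] = trial[gain]
                cur[gain] = llt[gain]
                improved |= gain
            if not improved.any():
                step /= 2.0
        k12 = np.clip(k12, 0.0, 1.0)
        over = k12.sum(axis=1) > 1.0
        k12[over] /= k12[over].sum(axis=1, keepdims=True)
        ks[s : s + chunk] = np.column_stack([1.0 - k12.sum(axis=1), k12])
    return ks


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def ml_relatedness(
    g: GenotypeTable,
    freqs: AlleleFrequencies | None = None,
    null_alleles: bool = False,
) -> tuple[DistanceMatrix, list[RelatednessEstimate]]:
    """ML relatedness for every individual pair.

    Returns a relatedness DistanceMatrix (r_hat, NaN diagonal) plus the full
    per-pair estimate list.  A pair with zero shared scored loci gets NaN and
    is flagged in its estimate with category ``"unrelated"`` and NaN r_hat.
    """
    if g.n_individuals < 2:
        raise ValidationError("relatedness needs at least 2 individuals")
    if freqs is None:
        freqs = allele_frequencies(g, by="pooled")
    n = g.n_individuals
    pairs = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
    P = _pair_locus_mixture(g, pairs, freqs, null_alleles)
    shared = (P != 1.0).any(axis=2).sum(axis=1)  # loci contributing per pair
    ks = fit_k_batch(P)
    r = ks[:, 1] / 2.0 + ks[:, 2]
    values = np.full((n, n), np.nan)
    estimates = []
    for (i, j), (k0, k1, k2), rh, ns in zip(pairs, ks, r, shared):
        pair_lab = (g.individual_ids[i], g.individual_ids[j])
        if ns == 0:
            estimates.append(
                RelatednessEstimate(pair=pair_lab, k0=np.nan, k1=np.nan, k2=np.nan,
                                    r_hat=np.nan, category="unrelated")
            )
            continue
        rh = float(min(max(rh, 0.0), 1.0))
        values[i, j] = values[j, i] = rh
        estimates.append(
            RelatednessEstimate(
                pair=pair_lab, k0=float(k0), k1=float(k1), k2=float(k2),
                r_hat=rh, category=categorize_relatedness(rh),
            )
        )
    dm = DistanceMatrix(
        labels=list(g.individual_ids), values=values, kind="relatedness",
        diagonal_policy="undefined",
    )
    return dm, estimates


def relatedness_significance(
    g: GenotypeTable,
    pair: tuple[str, str],
    n_rand: int = 5_000,
    seed: int | None = None,
    freqs: AlleleFrequencies | None = None,
    null_alleles: bool = False,
) -> float:
    """Randomization p-value for one pair's relatedness.

    The null re-draws both individuals' alleles independently from the pooled
    frequencies at every locus the pair shares (locus structure preserved);
    ``p = (1 + #{r_null >= r_obs}) / (n_rand + 1)``.
    """
    import warnings

    if n_rand < 1:
        raise ValidationError("n_rand must be >= 1")
    if n_rand < 100:
        warnings.warn(f"n_rand={n_rand} gives poor p-value resolution", stacklevel=2)
    if freqs is None:
        freqs = allele_frequencies(g, by="pooled")
    ids = list(g.individual_ids)
    try:
        i, j = ids.index(pair[0]), ids.index(pair[1])
    except ValueError as e:
        raise ValidationError(f"unknown individual in pair: {e}") from None
    rng = np.random.default_rng(seed)
    pair_arr = np.array([[i, j]])
    P_obs = _pair_locus_mixture(g, pair_arr, freqs, null_alleles)
    k_obs = fit_k_batch(P_obs)[0]
    r_obs = float(k_obs[1] / 2.0 + k_obs[2])
    miss = g.missing_mask()
    shared_loci = [l for l in range(g.n_loci) if not (miss[i, l] or miss[j, l])]
    grp = freqs.groups[0]
    # draw null genotype pairs locus-by-locus and evaluate in one batch
    P_null = np.ones((n_rand, g.n_loci, 3))
    for l in shared_loci:
        name = g.locus_names[l]
        codes, vals = _locus_freq_lookup(freqs, name, 0.0)
        if len(codes) == 0:
            continue
        draws = rng.choice(codes, size=(n_rand, 4), p=vals / vals.sum())
        x1, x2, y1, y2 = draws[:, 0], draws[:, 1], draws[:, 2], draws[:, 3]
        P0, P1, P2 = _genotype_pair_triples(
            x1, x2, y1, y2,
            _lookup(codes, vals, x1), _lookup(codes, vals, x2),
            _lookup(codes, vals, y1), _lookup(codes, vals, y2),
        )
        P_null[:, l, 0] = P0
        P_null[:, l, 1] = P1
        P_null[:, l, 2] = P2
    k_null = fit_k_batch(P_null)
    r_null = k_null[:, 1] / 2.0 + k_null[:, 2]
    return (1 + int((r_null >= r_obs).sum())) / (n_rand + 1)
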