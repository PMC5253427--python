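"""Bayesian estimation of recent directional migration rates (BayesAss model).

The model (Wilson & Rannala 2003) assigns each sampled individual a latent
migrant ancestry: non-migrant, first-generation migrant from population j, or
second-generation migrant (one parent from j).  Genotype likelihoods given
ancestry for an individual sampled in population i:

* non-migrant / first-generation migrant from j (j = i for non-migrants):
  homozygote aa -> p_ja^2 (1 - F_j) + p_ja F_j;
  heterozygote ab -> 2 p_ja p_jb (1 - F_j)
* second-generation migrant from j: one gene from j, one from i —
  homozygote aa -> p_ja p_ia; heterozygote ab -> p_ja p_ib + p_jb p_ia
  (no inbreeding term).

Ancestry prior given the migration matrix m (m[i][j] = fraction of population
i composed of migrants from j): P(first-gen from j) = m_ij, P(second-gen from
j) = 2 m_ij m_ii, P(non-migrant) = the remainder.  The prior over each row of
m is uniform on the constrained simplex  sum_{j != i} m_ij <= 1/3 (so the
non-migrant fraction m_ii >= 2/3); F is uniform on [0, 1] and allele
frequencies are Dirichlet(1).

Sampling is Metropolis-within-Gibbs: per iteration one move is drawn —
a Gibbs re-assignment of one individual's ancestry, or a reflected
random-walk proposal of window delta on one m entry, one F, or one pair of
allele frequencies.  Migrant generations are limited to {0, 1, 2}; deeper
ancestry is collapsed into the non-migrant class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core_data import MISSING, GenotypeTable
from .errors import ValidationError

logger = logging.getLogger(__name__)

MAX_IMMIGRATION = 1.0 / 3.0

GENE_FLOW_CLASSES = ("low", "moderate", "high")


def classify_gene_flow(m: float) -> str:
    """Qualitative class of a migration rate: < 0.030 low, 0.030-0.100
    moderate (closed interval), > 0.100 high."""
    if not (0.0 <= m <= 1.0) or not np.isfinite(m):
        raise ValidationError(f"migration rate {m} outside [0, 1]")
    if m < 0.030:
        return "low"
    if m <= 0.100:
        return "moderate"
    return "high"


@dataclass
class MCMCConfig:
    """Run plan and proposal windows.

    The default plan is the full analysis profile (3e6 iterations, 1e6
    burn-in, thinning 2000, 3 chains); reduced desk-scale profiles are passed
    explicitly where speed matters.
    """

    n_iter: int = 3_000_000
    burn_in: int = 1_000_000
    thin: int = 2_000
    n_chains: int = 3
    delta_p: float = 0.15
    delta_F: float = 0.15
    delta_m: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValidationError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        for name in ("delta_p", "delta_F", "delta_m"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name} must lie in (0, 1]")


@dataclass
class MigrationMatrix:
    """Posterior summary of directional migration rates.

    ``mean[i][j]`` is the posterior mean fraction of population i composed of
    migrants from population j (diagonal = non-migrant fraction); equal-tailed
    95% credible bounds, a qualitative class per off-diagonal entry, and net
    emigration per population.
    """

    labels: list[str]
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    classes: list[list[str]] = field(default_factory=list)
    rhat: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.classes:
            k = len(self.labels)
            self.classes = [
                [
                    "" if i == j else classify_gene_flow(float(self.mean[i, j]))
                    for j in range(k)
                ]
                for i in range(k)
            ]

    def to_table(self):
        """Long-format rows (into, source, mean, ci_low, ci_high, class)."""
        rows = []
        k = len(self.labels)
        for i in range(k):
            for j in range(k):
                rows.append(
                    {
                        "into": self.labels[i],
                        "source": self.labels[j],
                        "mean": float(self.mean[i, j]),
                        "ci_low": float(self.ci_low[i, j]),
                        "ci_high": float(self.ci_high[i, j]),
                        "class": "self" if i == j else self.classes[i][j],
                    }
                )
        return rows


def net_emigration(mm: MigrationMatrix, pop: str) -> float:
    """Sum of outgoing minus incoming migration for one population.

    Under the m[i][j] = "into i from j" convention, outgoing gene flow of
    ``pop`` is sum_i m[i][pop] and incoming is sum_j m[pop][j] (off-diagonal).
    """
    if pop not in mm.labels:
        raise ValidationError(f"unknown population {pop!r}")
    k = mm.labels.index(pop)
    m = mm.mean
    outgoing = float(m[:, k].sum() - m[k, k])
    incoming = float(m[k, :].sum() - m[k, k])
    return outgoing - incoming


# ---------------------------------------------------------------------------
# Ancestry bookkeeping
# ---------------------------------------------------------------------------


def ancestry_state_table(K: int, home: int) -> list[tuple[int, int]]:
    """States for an individual sampled in ``home``: [(home, 0)] then
    (j, 1), (j, 2) for every other population j in index order."""
    states = [(home, 0)]
    for j in range(K):
        if j == home:
            continue
        states.append((j, 1))
        states.append((j, 2))
    return states


def ancestry_prior_row(m: np.ndarray, home: int) -> np.ndarray:
    """Prior probabilities of the 2K-1 ancestry states for one home population."""
    K = m.shape[0]
    states = ancestry_state_table(K, home)
    probs = np.empty(len(states))
    mii = m[home, home]
    total = 0.0
    for s, (j, gen) in enumerate(states):
        if gen == 0:
            continue
        p = m[home, j] if gen == 1 else 2.0 * m[home, j] * mii
        probs[s] = p
        total += p
    probs[0] = 1.0 - total
    if probs[0] < 0:
        raise ValidationError("ancestry prior became negative (m outside support)")
    return probs


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------


class _BayesAssData:
    """Pre-encoded genotypes: dense allele codes per locus, per-individual
    home population index, and the relative-state source table."""

    def __init__(self, g: GenotypeTable):
        pops = g.populations
        if len(pops) < 2:
            raise ValidationError("migration estimation needs >= 2 populations")
        self.pop_labels = pops
        self.K = len(pops)
        self.N = g.n_individuals
        self.L = g.n_loci
        pop_index = {p: k for k, p in enumerate(pops)}
        self.home = np.array([pop_index[p] for p in g.population_ids])
        self.n_alleles = []
        self.geno = []  # per locus: (N, 2) dense codes, MISSING -> -1
        for l in range(g.n_loci):
            col = g.alleles[:, l, :]
            obs = np.unique(col[col != MISSING])
            code = {a: k for k, a in enumerate(obs)}
            dense = np.full((self.N, 2), -1, dtype=np.int64)
            for a, k in code.items():
                dense[col == a] = k
            self.n_alleles.append(max(len(obs), 1))
            self.geno.append(dense)
        K = self.K
        self.S = 2 * K - 1
        # src[h, s] = source population of state s for individual h; gen[s] pattern
        self.src = np.empty((self.N, self.S), dtype=np.int64)
        self.gen = np.empty((self.K, self.S), dtype=np.int64)
        for i in range(K):
            states = ancestry_state_table(K, i)
            hmask = self.home == i
            for s, (j, gen) in enumerate(states):
                self.src[hmask, s] = j
                self.gen[i, s] = gen
        self.gen_by_ind = self.gen[self.home]  # (N, S)
        # dense genotype caches (clamped codes, hom/scored masks) per locus
        self.a1c = np.empty((self.L, self.N), dtype=np.int64)
        self.a2c = np.empty((self.L, self.N), dtype=np.int64)
        self.hom = np.empty((self.L, self.N), dtype=bool)
        self.scored = np.empty((self.L, self.N), dtype=bool)
        for l in range(self.L):
            a1, a2 = self.geno[l][:, 0], self.geno[l][:, 1]
            self.scored[l] = a1 >= 0
            self.a1c[l] = np.where(self.scored[l], a1, 0)
            self.a2c[l] = np.where(self.scored[l], a2, 0)
            self.hom[l] = self.a1c[l] == self.a2c[l]
        # for each source population k: the single gen<=1 state per individual
        # that references (p_k, F_k) — their own-state for residents of k, the
        # first-generation-from-k state for everyone else
        self.state_gen01 = np.empty((self.K, self.N), dtype=np.int64)
        for k in range(self.K):
            for h in range(self.N):
                col = np.flatnonzero((self.src[h] == k) & (self.gen_by_ind[h] <= 1))
                self.state_gen01[k, h] = col[0]


class _Chain:
    def __init__(self, data: _BayesAssData, cfg: MCMCConfig, rng: np.random.Generator):
        self.d = data
        self.cfg = cfg
        self.rng = rng
        d = data
        # initial state
        self.m = np.zeros((d.K, d.K))
        off = 0.1 / max(d.K - 1, 1)
        self.m += off
        np.fill_diagonal(self.m, 0.0)
        np.fill_diagonal(self.m, 1.0 - self.m.sum(axis=1))
        self.F = np.full(d.K, 0.1)
        self.p = []
        for l in range(d.L):
            A = d.n_alleles[l]
            counts = np.ones((d.K, A))
            gl = d.geno[l]
            for k in range(d.K):
                sub = gl[d.home == k].ravel()
                sub = sub[sub >= 0]
                if sub.size:
                    counts[k] += np.bincount(sub, minlength=A)
            self.p.append(counts / counts.sum(axis=1, keepdims=True))
        # padded frequency tensor (K, L, A_max) kept in sync with self.p for
        # fully vectorized likelihood kernels
        amax = max(d.n_alleles) if d.L else 1
        self.p_pad = np.zeros((d.K, d.L, amax))
        for l in range(d.L):
            self.p_pad[:, l, : d.n_alleles[l]] = self.p[l]
        self.ancestry = np.zeros(d.N, dtype=np.int64)
        self.log_prior_anc = np.stack(
            [np.log(ancestry_prior_row(self.m, i)) for i in range(d.K)]
        )  # (K, S)
        self.C = np.zeros((d.N, d.L, d.S))
        for l in range(d.L):
            self.C[:, l, :] = self._locus_loglik(l)
        self.S_sum = self.C.sum(axis=1)
        self.accept = {"m": [0, 0], "F": [0, 0], "p": [0, 0]}

    # -- likelihood kernels -------------------------------------------------

    def _locus_loglik(self, l: int) -> np.ndarray:
        """(N, S) per-state log-likelihood contributions of locus l."""
        d = self.d
        scored = d.scored[l]
        pl = self.p[l]  # (K, A)
        idx = np.arange(d.N)
        f1 = pl[:, d.a1c[l]]  # (K, N)
        f2 = pl[:, d.a2c[l]]
        hom = d.hom[l][:, None]  # (N, 1)
        f1h = f1[d.home, idx][:, None]
        f2h = f2[d.home, idx][:, None]
        # gather per (individual, state): source frequencies and inbreeding
        f1j = f1[d.src, idx[:, None]]  # (N, S)
        f2j = f2[d.src, idx[:, None]]
        Fj = self.F[d.src]
        hw = np.where(
            hom,
            f1j * f1j * (1.0 - Fj) + f1j * Fj,
            2.0 * f1j * f2j * (1.0 - Fj),
        )
        g2 = np.where(hom, f1j * f1h, f1j * f2h + f2j * f1h)
        like = np.where(d.gen_by_ind == 2, g2, hw)
        out = np.log(np.maximum(like, 1e-300))
        out[~scored, :] = 0.0
        return out

    # -- moves --------------------------------------------------------------

    def move_ancestry(self) -> None:
        d = self.d
        h = int(self.rng.integers(d.N))
        logits = self.S_sum[h] + self.log_prior_anc[d.home[h]]
        w = np.exp(logits - logits.max())
        cw = np.cumsum(w)
        u = self.rng.uniform() * cw[-1]
        self.ancestry[h] = int(np.searchsorted(cw, u))

    @staticmethod
    def _reflect(x: float, lo: float, hi: float) -> float:
        width = hi - lo
        if width <= 0:
            return lo
        y = (x - lo) % (2 * width)
        if y < 0:
            y += 2 * width
        return lo + (width - abs(y - width))

    def move_m(self) -> None:
        d = self.d
        self.accept["m"][1] += 1
        i = int(self.rng.integers(d.K))
        others = [j for j in range(d.K) if j != i]
        j = others[int(self.rng.integers(d.K - 1))]
        row_off = self.m[i].sum() - self.m[i, i]
        upper = MAX_IMMIGRATION - (row_off - self.m[i, j])
        prop = self.m[i, j] + self.rng.uniform(-self.cfg.delta_m, self.cfg.delta_m)
        prop = self._reflect(prop, 0.0, upper)
        m_new = self.m.copy()
        m_new[i, j] = prop
        m_new[i, i] = 1.0 - (m_new[i].sum() - m_new[i, i])
        new_prior_row = np.log(ancestry_prior_row(m_new, i))
        hmask = d.home == i
        anc_i = self.ancestry[hmask]
        delta = float(
            new_prior_row[anc_i].sum() - self.log_prior_anc[i][anc_i].sum()
        )
        if np.log(self.rng.uniform()) < delta:
            self.m = m_new
            self.log_prior_anc[i] = new_prior_row
            self.accept["m"][0] += 1

    def _gen01_loglik(self, k: int, Fk: float) -> np.ndarray:
        """(N, L) per-locus log-likelihood of each individual's genotype as a
        non-migrant/first-generation draw from population k."""
        d = self.d
        if d.L == 0:
            return np.zeros((d.N, 0))
        lidx = np.arange(d.L)[:, None]
        f1 = self.p_pad[k][lidx, d.a1c].T  # (N, L)
        f2 = self.p_pad[k][lidx, d.a2c].T
        hom = d.hom.T
        like = np.where(
            hom, f1 * f1 * (1.0 - Fk) + f1 * Fk, 2.0 * f1 * f2 * (1.0 - Fk)
        )
        out = np.log(np.maximum(like, 1e-300))
        out[~d.scored.T] = 0.0
        return out

    def move_F(self) -> None:
        d = self.d
        self.accept["F"][1] += 1
        k = int(self.rng.integers(d.K))
        prop = self._reflect(
            self.F[k] + self.rng.uniform(-self.cfg.delta_F, self.cfg.delta_F), 0.0, 1.0
        )
        # F_k enters only through the single gen<=1 state per individual that
        # sources from population k
        s_k = d.state_gen01[k]
        idx = np.arange(d.N)
        touched = self.ancestry == s_k
        vl_new = self._gen01_loglik(k, prop)  # (N, L)
        v_new = vl_new.sum(axis=1)
        v_old = self.S_sum[idx, s_k]
        delta = float(v_new[touched].sum() - v_old[touched].sum())
        if np.log(self.rng.uniform()) < delta:
            self.F[k] = prop
            self.C[idx[:, None], np.arange(d.L)[None, :], s_k[:, None]] = vl_new
            self.S_sum[idx, s_k] = v_new
            self.accept["F"][0] += 1

    def move_p(self) -> None:
        d = self.d
        if d.L == 0:
            return
        self.accept["p"][1] += 1
        k = int(self.rng.integers(d.K))
        l = int(self.rng.integers(d.L))
        A = d.n_alleles[l]
        if A < 2:
            return
        a, b = self.rng.choice(A, size=2, replace=False)
        pl = self.p[l]
        total = pl[k, a] + pl[k, b]
        prop = self._reflect(
            pl[k, a] + self.rng.uniform(-self.cfg.delta_p, self.cfg.delta_p), 0.0, total
        )
        old_a, old_b = pl[k, a], pl[k, b]
        pl[k, a] = prop
        pl[k, b] = total - prop
        self.p_pad[k, l, a] = prop
        self.p_pad[k, l, b] = total - prop
        new_locus = self._locus_loglik(l)
        idx = np.arange(d.N)
        delta = float(
            new_locus[idx, self.ancestry].sum() - self.C[idx, l, self.ancestry].sum()
        )
        if np.log(self.rng.uniform()) < delta:
            self.S_sum += new_locus - self.C[:, l, :]
            self.C[:, l, :] = new_locus
            self.accept["p"][0] += 1
        else:
            pl[k, a] = old_a
            pl[k, b] = old_b
            self.p_pad[k, l, a] = old_a
            self.p_pad[k, l, b] = old_b

    def step(self) -> None:
        u = self.rng.uniform()
        if u < 0.40:
            self.move_ancestry()
        elif u < 0.70:
            self.move_p()
        elif u < 0.90:
            self.move_m()
        else:
            self.move_F()

    def run(self, n_iter: int, burn_in: int, thin: int) -> np.ndarray:
        samples = []
        for it in range(n_iter):
            self.step()
            if it >= burn_in and (it - burn_in) % thin == 0:
                off = self.m.sum(axis=1) - np.diag(self.m)
                assert (off <= MAX_IMMIGRATION + 1e-12).all(), "immigration constraint violated"
                samples.append(self.m.copy())
        return np.array(samples)

    def acceptance_rates(self) -> dict:
        return {
            k: (a / t if t else np.nan) for k, (a, t) in self.accept.items()
        }


def _split_rhat(chains: np.ndarray) -> float:
    """Split R-hat for one scalar over (n_chains, n_samples) draws."""
    half = chains.shape[1] // 2
    if half < 2:
        return np.nan
    seqs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    mchain = seqs.mean(axis=1)
    svar = seqs.var(axis=1, ddof=1)
    W = svar.mean()
    B = half * mchain.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (half - 1) / half * W + B / half
    return float(np.sqrt(var_plus / W))


def run_bayesass(
    g: GenotypeTable, cfg: MCMCConfig
) -> tuple[MigrationMatrix, dict]:
    """Run the migration-rate sampler and summarize the posterior.

    Returns the posterior ``MigrationMatrix`` (means, 95% equal-tailed
    credible intervals, per-entry class) and a trace dict with the thinned
    per-chain samples and acceptance rates.  Chains disagreeing (split R-hat
    > 1.2 on any entry) trigger a warning.
    """
    data = _BayesAssData(g)
    ss = np.random.SeedSequence(cfg.seed)
    chain_seeds = ss.spawn(cfg.n_chains)
    chain_samples = []
    rates = []
    for c in range(cfg.n_chains):
        chain = _Chain(data, cfg, np.random.default_rng(chain_seeds[c]))
        chain_samples.append(chain.run(cfg.n_iter, cfg.burn_in, cfg.thin))
        rates.append(chain.acceptance_rates())
    stacked = np.stack(chain_samples)  # (chains, draws, K, K)
    pooled = stacked.reshape(-1, data.K, data.K)
    mean = pooled.mean(axis=0)
    ci_low = np.percentile(pooled, 2.5, axis=0)
    ci_high = np.percentile(pooled, 97.5, axis=0)
    K = data.K
    rhat = np.full((K, K), np.nan)
    if cfg.n_chains >= 2:
        for i in range(K):
            for j in range(K):
                if i != j:
                    rhat[i, j] = _split_rhat(stacked[:, :, i, j])
        worst = np.nanmax(rhat)
        if worst > 1.2:
            warnings.warn(
                f"chains disagree: split R-hat up to {worst:.3f} on migration entries",
                stacklevel=2,
            )
    mm = MigrationMatrix(
        labels=data.pop_labels, mean=mean, ci_low=ci_low, ci_high=ci_high, rhat=rhat
    )
    trace = {
        "m": stacked,
        "acceptance": rates,
        "labels": data.pop_labels,
    }
    return mm, trace


def tune_deltas(
    g: GenotypeTable,
    cfg: MCMCConfig,
    pilot_iter: int = 20_000,
    target: tuple[float, float] = (0.40, 0.60),
    max_rounds: int = 20,
) -> MCMCConfig:
    """Adjust proposal windows until acceptance rates fall in ``target``.

    Each round runs a short pilot chain and bisects the window of any family
    outside the target band (acceptance measured over the last half of the
    pilot); windows are capped at (0, 1].  A window pinned at a bound with
    acceptance still outside the band triggers a warning and keeps the nearest
    attainable value.
    """
    if pilot_iter < 10_000:
        raise ValidationError("pilot run needs >= 10,000 iterations")
    data = _BayesAssData(g)
    lo, hi = target
    deltas = {"m": cfg.delta_m, "F": cfg.delta_F, "p": cfg.delta_p}
    bounds = {k: [1e-4, 1.0] for k in deltas}
    ss = np.random.SeedSequence(cfg.seed)
    for rnd in range(max_rounds):
        trial = replace(
            cfg, delta_m=deltas["m"], delta_F=deltas["F"], delta_p=deltas["p"]
        )
        chain = _Chain(data, trial, np.random.default_rng(ss.spawn(1)[0]))
        for _ in range(pilot_iter // 2):
            chain.step()
        chain.accept = {k: [0, 0] for k in chain.accept}  # keep only the last half
        for _ in range(pilot_iter - pilot_iter // 2):
            chain.step()
        rates = chain.acceptance_rates()
        all_ok = True
        for fam, rate in rates.items():
            if np.isnan(rate):
                continue
            if rate > hi:
                # too timid: widen the window
                bounds[fam][0] = deltas[fam]
                if deltas[fam] >= 1.0 - 1e-9:
                    warnings.warn(
                        f"delta_{fam} pinned at 1.0 with acceptance {rate:.2f} > {hi}",
                        stacklevel=2,
                    )
                    continue
                deltas[fam] = min(1.0, (deltas[fam] + bounds[fam][1]) / 2)
                all_ok = False
            elif rate < lo:
                bounds[fam][1] = deltas[fam]
                if deltas[fam] <= bounds[fam][0] + 1e-9:
                    warnings.warn(
                        f"delta_{fam} pinned at lower bound with acceptance {rate:.2f} < {lo}",
                        stacklevel=2,
                    )
                    continue
                deltas[fam] = (bounds[fam][0] + deltas[fam]) / 2
                all_ok = False
        if all_ok:
            break
    return replace(cfg, delta_m=deltas["m"], delta_F=deltas["F"], delta_p=deltas["p"])
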