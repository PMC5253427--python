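# landgenkit

Individual-based landscape genetics for diploid codominant markers.

`landgenkit` is for population geneticists and conservation ecologists who
ask *what shapes gene flow across a landscape*: does genetic differentiation
among individuals follow plain geographic distance, the cost of moving
through unsuitable habitat, predation risk, or human barriers? The package
takes genotype tables (Genepop or CSV), sampling coordinates, resistance
rasters (ESRI ASCII grids) and barrier features (GeoJSON), and produces the
full analysis chain used in individual-based studies of structured,
partially migratory populations such as woodland caribou:

* **Genetic distances** — Rousset's *a_r* between individuals,
  `a_r(i,j) = Σ_l (Q_w,l − Q_ij,l) / Σ_l (1 − Q_w,l)` built from
  identity-in-state probabilities, and pairwise Weir–Cockerham θ (F_ST)
  between populations (multi-locus ratio of sums of the a/b/c variance
  components).
* **Relatedness** — maximum-likelihood IBD coefficients (k0, k1, k2) per
  pair with `r̂ = k1/2 + k2`, optional null-allele accommodation, the
  standard category translation, and allele-randomization significance.
* **Landscape distances** — log-Euclidean isolation-by-distance, least-cost
  paths over resistance rasters (8-connected Dijkstra), and per-feature
  barrier-crossing counts.
* **Matrix statistics** — simple and partial Mantel tests with permutation
  nulls, and reciprocal causal modelling (RCM): each candidate model is
  tested partialling out each alternative and vice versa; a fully supported
  model has a positive column and a clean row in the support matrix.
* **Distance-based linear models (DISTLM)** — Gower-centered trace
  machinery with pseudo-F
  `F = [tr(HGH)/q] / [tr((I−H)G(I−H))/(n−q−1)]`, marginal, covariate-
  adjusted and forward-sequential tests; reduces exactly to the classical
  ANOVA F for univariate Euclidean responses.
* **Recent migration** — a Bayesian multilocus assignment sampler
  (Wilson–Rannala model: latent non-migrant / first- / second-generation
  ancestry, constrained migration simplex, inbreeding coefficients) giving
  directional rates m[into][from] with 95% credible intervals, low /
  moderate / high classes and net emigration per population.
* **Synthetic data** — a forward-time Wright–Fisher generator (island,
  distance-decay and resistance-decay migration, behaviour labels, truth
  records) so every stage above is testable end to end without field data.

## Worked example

Estimate directional recent-migration rates on simulated data whose truth
is known (three diverged populations, 50 diploids each, 14 loci, a focal
rate of 0.20 from population 2 into population 1 — see
`examples/06_migration_mcmc.py`):

```python
mig, trace = run_bayesass(table, MCMCConfig(
    n_iter=300_000, burn_in=100_000, thin=200, n_chains=1, delta_m=0.1, seed=0))
```

prints

```
into   from    truth   mean           95% CI class
pop1   pop1    0.750  0.747    (0.687-0.811) self
pop1   pop2    0.200  0.215    (0.155-0.276) high
pop1   pop3    0.050  0.038    (0.012-0.076) moderate
pop2   pop1    0.050  0.066    (0.034-0.108) moderate
pop2   pop2    0.900  0.914    (0.871-0.951) self
pop2   pop3    0.050  0.020    (0.004-0.048) low
pop3   pop1    0.050  0.013    (0.001-0.036) low
pop3   pop2    0.050  0.048    (0.020-0.083) moderate
pop3   pop3    0.900  0.939    (0.900-0.970) self
net emigration of pop1: -0.174
net emigration of pop2: +0.177
net emigration of pop3: -0.003
```

Each row is the posterior mean fraction of the *into* population composed
of migrants from the *from* population (diagonal = non-migrant fraction),
with its equal-tailed 95% credible interval and qualitative class
(m < 0.030 low, 0.030–0.100 moderate, > 0.100 high). The 0.20 truth is
recovered at 0.215 with an interval that covers it; population 2 is
correctly identified as the net exporter.

The other scripts in `examples/` walk through simulation, genetic and
landscape distances, Mantel tests with RCM model selection, DISTLM tables,
and the one-command pipeline (`run_pipeline`), each printing a few numbers
and what they mean. A thin CLI mirrors the library:
`landgenkit simulate|ardist|fst|relate|euclid|lcp|barriers|mantel|pmantel|rcm|distlm|bayesass|run`.

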