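# Methods

`landgenkit` implements an individual-based landscape-genetics workflow for
diploid codominant markers (microsatellites): genetic distance and
relatedness estimation, geographic/resistance/barrier distances, matrix
correlation tests with model selection, distance-based linear models, and
Bayesian estimation of recent migration rates — plus a forward-time
synthetic-data generator so that every stage can be validated without field
data. This note records the models, the conventions, and the design choices
made where the design was genuinely open.

## Coordinate and raster conventions

All coordinates are planar metres in one shared projection; no geodesy is
performed, and reprojection is the caller's responsibility. Rasters follow
the ESRI ASCII grid layout: row 0 is the top row, and cell `(r, c)` has its
center at `(origin_x + (c + 0.5)·s, origin_y + (n_rows − r − 0.5)·s)` for
cell size `s`, with `(origin_x, origin_y)` the lower-left corner. This one
convention is used by the reader, the writer, point-to-cell snapping and the
path graph.

## Genetic distances

**Rousset's a_r (between individuals).** For each locus `l`, `Qw_l` is the
mean identity in state of the two genes within an individual, averaged over
*all* individuals scored at that locus (a sample-wide reference — the
pair-only variant is undefined whenever both members of a pair are
heterozygous at most loci). For a pair `(i, j)`, `Qij_l` is the mean of the
four between-individual gene comparisons. Then

    a_r(i, j) = Σ_l (Qw_l − Qij_l) / Σ_l (1 − Qw_l),

with both sums running over the loci at which *both* individuals are scored
(locus-pairwise deletion keeps the estimator a ratio over a common locus
set). Negative values are reported as computed: downstream matrix
correlations and linear models operate on raw estimates, and truncation
would bias them. The estimator is undefined (an error) only when every
usable locus is homozygous for one shared allele across the whole sample,
which makes the denominator zero.

**Weir–Cockerham theta (between populations).** Pairwise F_ST uses the
standard a/b/c variance components per allele per locus for r = 2 demes and
the multi-locus ratio of sums `Σa / Σ(a+b+c)`. Monomorphic loci contribute
nothing; negative estimates are retained. A population pair with no usable
shared polymorphic locus yields NaN and a logged warning.

## Relatedness

Pairwise relatedness is estimated by maximum likelihood over the
IBD-coefficient simplex `(k0, k1, k2)` (probabilities of sharing 0/1/2 gene
pairs identical by descent, non-inbred model), with the classical
genotype-pair transition probabilities under pooled allele frequencies. The
point estimate is `r̂ = k1/2 + k2`.

The maximizer is a coarse simplex grid (step 0.05) followed by a compass
search over `(k1, k2)` with step halving to 1e-4, vectorized over batches of
pairs; ties prefer larger `k0` (less related). The genealogical constraint
`k1² ≥ 4·k0·k2` is deliberately *not* imposed. With `null_alleles=True`, a
per-locus null-allele frequency is estimated from the heterozygote deficit
(`(He − Ho)/(1 + He)`, clipped at 0), observed frequencies are rescaled, and
each observed homozygote is treated as the two-component mixture {true
homozygote, null heterozygote} in the pair likelihood.

Categories follow the printed translation: exactly 0 → unrelated; (0, 0.25]
→ weak; (0.25, 0.5] → moderate; (0.5, 1) → high; exactly 1 → full.

**Randomization significance.** The null redraws both individuals' alleles
independently from the pooled frequencies at each shared locus and reports
`p = (1 + #{r̂_null ≥ r̂_obs}) / (n_rand + 1)` (default 5,000
randomizations). Because the constrained MLE has positive probability of
landing exactly on the `k0 = 1` corner for unrelated pairs (measured ≈ 0.47
on a 14-locus fixture), `r̂` has an atom at 0 and the p-value has matching
mass at 1.0. The p-value is therefore *valid* (super-uniform: `P(p ≤ x) ≤
x`) but not exactly uniform under the null — the correct behaviour for a
randomization test with a boundary-constrained statistic, and what the
calibration suite asserts.

## Landscape distances

Euclidean distances are plain `hypot`; the isolation-by-distance matrix is
natural-log transformed by default (log is applied to Euclidean distances
only — least-cost and barrier matrices are left on their raw scales, with a
generic log helper available to the caller). Least-cost paths run Dijkstra
over the 8-connected cell lattice with edge weight `mean(cost_a, cost_b) ·
cell_size · √2^[diagonal]`; individuals snap to the cell containing their
coordinates; individuals on no-data cells are an error; disconnected pairs
become NaN entries that downstream tests drop by pairwise deletion. Forward
and backward path sums can differ by float rounding, so the matrix is
symmetrized by averaging. Barrier "distance" counts *features* (not
crossings): a winding road crossed twice counts once; tangency and endpoint
contact count as intersections.

## Mantel tests and reciprocal causal modelling

Matrix vectorization uses the lower triangle excluding the diagonal,
everywhere. Simple Mantel permutes rows+columns of the predictor jointly;
when all label permutations fit in the permutation budget (tiny n), the
null is enumerated exhaustively and the p-value is the exact proportion.
Otherwise `p = (1 + #{r_perm ≥ r_obs}) / (n_perm + 1)` for the `greater`
tail (mirrored for `less`, on |r| for `two_sided`); the smallest attainable
p is `1/(n_perm+1)`. Missing entries are dropped by pairwise deletion,
re-evaluated per permutation.

Partial Mantel residualizes both the response and the tested matrix on the
control over the vectorizations, then permutes the *residualized predictor
matrix* (residuals reshaped to a labelled square matrix and label-permuted),
which preserves the control structure. Controls that are constant or
perfectly collinear with the tested matrix are errors.

**RCM.** For a response G and candidate models M_1..M_K, the support matrix
holds `entry[i, j] = r(G, M_j | M_i)` (columns = principal models, rows =
alternatives; diagonal exactly 0). The default verdict is the crisp sign
rule: a model is *fully supported* iff its column is all positive and its
row all non-positive; *partially supported* if only the column condition
holds. An optional significance-aware row condition (`row_alpha`) tolerates
positive row entries whose cell permutation p-value exceeds `row_alpha`:
under stepping-stone gene flow the conditional correlation of a spatially
correlated alternative remains slightly positive even when the candidate is
the true generating model (saturating differentiation and multi-path gene
flow leave curvature residuals that any distance-like matrix partially
explains), so the crisp rule converts near-zero noise and small real
residuals into verdict flips; reading *small* positives as non-support
matches how confusion matrices of this kind are interpreted in practice.
The model-selection recovery experiment uses `row_alpha = 0.05`.

## Distance-based linear models

The response matrix is Gower-centered, `G = J(−D²/2)J`, and a design X
(intercept + columns) yields the hat matrix H via QR. The pseudo-F is

    F = [tr(HGH)/q] / [tr((I−H)G(I−H))/(n − q − 1)],

which reduces *exactly* to the classical regression/ANOVA F when D is the
Euclidean distance of a single variable (the module's primary oracle).
Percent variance is `100·tr(HGH)/tr(G)` marginally, and the added-trace
analogue conditionally — which may legitimately be negative for
non-Euclidean responses and is reported unfloored. Categorical predictors
are dummy-coded against the first observed level; declared groups (e.g.
coordinates = longitude + latitude) enter and leave as one block with q =
block size. Permutation schemes: raw unit permutation for marginal tests;
Freedman–Lane permutation of reduced-model residuals for conditional and
sequential tests. Forward selection greedily adds the block with the
largest added explained trace, reporting the conditional F/p/%var at each
step; collinear additions are flagged with zero added variance. The
non-Euclidean negative-eigenvalue component of G is handled implicitly by
the trace machinery (no correction applied).

Population-level analyses treat the two directions of the migration matrix
as separate dissimilarity responses via `1 − m` (each unordered pair takes
one direction's rate per matrix). The geographic covariate is each
population's mean centroid distance to the others — a unit-level summary of
the distance matrix, since the linear-model design requires per-unit
columns; F_ST enters as an additional covariate when a dispersal matrix is
the response.

## Recent-migration MCMC

The model assigns each individual a latent ancestry: non-migrant,
first-generation migrant from population j, or second-generation migrant
(one parent from j), with genotype likelihoods

* non-migrant / first-generation from j: homozygote `p_ja²(1−F_j) + p_ja F_j`,
  heterozygote `2 p_ja p_jb (1−F_j)` — population-j frequencies and
  inbreeding coefficient;
* second-generation from j: one gene from j and one from the home
  population, no inbreeding term.

The ancestry prior given the migration matrix is `P(first-gen from j) =
m_ij`, `P(second-gen from j) = 2·m_ij·m_ii` (one migrant, one resident
parent), non-migrant the remainder — positive everywhere on the support.
Priors: uniform over each row's constrained simplex (off-diagonal sum
≤ 1/3, so the non-migrant fraction is ≥ 2/3), uniform F on [0,1],
Dirichlet(1) allele frequencies. Migrant generations deeper than 2 are
collapsed into the non-migrant class.

Sampling is Metropolis-within-Gibbs: per iteration one move — Gibbs
re-assignment of one random individual's ancestry (40%), a reflected
random-walk on one pair of allele frequencies (30%), on one off-diagonal
migration entry with the row's remaining headroom as the reflecting bound
(20%), or on one population's F (10%). Proposal windows (`delta_p`,
`delta_F`, `delta_m`) are tunable by bisection against a 40–60% acceptance
band over short pilot runs. The documented full run plan is 3×10⁶
iterations, 10⁶ burn-in, thinning 2,000, three chains; validation uses an
explicit desk profile (3×10⁵ / 10⁵ / 200, one chain) under which split
R-hat across chains was ≈ 1.00 in the recovery conditions. Posterior
summaries are means with equal-tailed 95% credible intervals over pooled
thinned draws; chains with split R-hat > 1.2 on any entry trigger a
warning. Rates are classed low (< 0.030), moderate (0.030–0.100, closed)
or high (> 0.100); net emigration of a population is the off-diagonal
column sum minus row sum under the `m[into][from]` convention.

## Synthetic data generator

The generator emulates the structure of a partial-migration caribou study:
8 local populations, 207 sampled adult females, 14 microsatellite loci with
5–15 alleles per locus, behaviour labels ≈ 61% migratory / 10% sedentary /
29% unclassified, sampling scattered (Gaussian, 6 km) around population
centroids spread over a ~120 km region, and a 30 m-class resistance raster
abstracted to a coarser synthetic grid (base cost 1 plus Gaussian bumps,
optionally a wall with a gap, and straight-line barrier features).

Genetics are forward-time Wright–Fisher: per-locus ancestral frequencies
from a symmetric Dirichlet(1); each generation, gene-copy immigration
(`f'_i = (1−Σm) f_i + Σ_j m_ij f_j`) followed by multinomial resampling of
2N gene copies; sampled individuals drawn Hardy–Weinberg from final
frequencies. Migration models:

* `island` — Wright's idealized island model: immigrants come from the
  *fixed ancestral pool*. This is what makes the classical equilibrium
  `F_ST ≈ 1/(1+4Nm)` hold exactly as written; a finite K-island exchange
  carries a `(K/(K−1))²` correction (≈ 0.16 rather than 0.20 at K = 8,
  N = 100, m = 0.01). The exact discrete-generation equilibrium at N = 100,
  m = 0.01 is 0.1976.
* `distance_decay` / `resistance_decay` — `m_ij ∝ exp(−d_ij/decay_scale)`
  with d Euclidean or least-cost between centroids, row-normalized to a
  configured total immigration capped at 1/3 (the migration estimator's
  prior support, keeping parameter-recovery tests fair).
* an explicit `true_migration_matrix` overrides both.

Because the migration estimator explicitly does **not** assume
migration–drift equilibrium, recovery experiments separate history from the
present: populations may drift in isolation (`history_migration_matrix`,
defaulting to identity when `recent_migrant_ancestry` is set) and migration
enters only at sampling time, by drawing each individual's latent ancestry
from the estimator's own ancestry prior and its genotype from the matching
likelihood. The truth record stores the migration matrix, initial and final
frequencies, and per-individual source/ancestry.

What the generator does *not* emulate: mutation, overlapping generations,
selection, genotyping error, real null alleles, spatially autocorrelated
environmental covariates, and within-population spatial structure beyond
Gaussian scatter. Passing tests therefore demonstrate correctness of the
estimators and their calibration under clean drift–migration genetics — not
robustness to marker artefacts or to model misspecification in real data.

## Validation experiments

* **Exact oracles** — Mantel p against full enumeration at n = 5; LCP costs
  against an explicit-edge-list Dijkstra on masked 20×20 rasters; pseudo-F
  against the classical F (1e-9); a_r against a hand-tallied 4-individual /
  2-locus fixture.
* **Calibration** — Mantel, partial-Mantel and DISTLM p-values are KS-tested
  for uniformity under their nulls (200 replicates, 999 permutations);
  relatedness randomization p-values are tested one-sided for validity
  (super-uniformity), for the boundary-atom reason above.
* **Closed-form limits** — island-model mean multi-locus theta ≈ 0.20
  (tolerance 0.03 over 20 replicates at N = 100, m = 0.01, 250 generations
  to equilibrium); gene-pool heterozygosity decays by `(1 − 1/(2N))` per
  generation (ratio within 0.06 over 40 closed-population replicates).
* **Migration-rate recovery** — three populations diverge in isolation (250
  generations, N = 60, multi-locus F_ST ≈ 0.2–0.4), then 50 diploids per
  population are sampled with recent-migrant ancestry at a focal rate of
  0.20 (remaining entries 0.05; row sums within the prior support). The
  95% credible interval covers the focal truth in ≥ 18/20 replicates
  (measured 19/20 in development), and zero-migration data yield all
  off-diagonal posterior means < 0.03 (measured ≤ 0.007).
* **Model-selection recovery** — an 8×8 lattice of demes (N = 15, 2 sampled
  individuals each, 56 loci here to tame deme-level drift noise) exchanges
  migrants by exponential decay in least-cost distance over a gently bumpy
  landscape crossed by a *permeable* wall with one gap; candidate models
  are the generating LCP, straight-line distance, and a decoy surface. The
  wall's permeability is essential: an impassable wall reduces the signal
  to a binary side split that any distance-like matrix mimics. With the
  significance-aware row rule (α = 0.05) the generating model is fully
  supported in 75–85% of seeds (15–17 of 20 across three disjoint seed
  bases measured in development). This fraction is honest but *marginal*
  around the 80% design goal: at this problem size the unique conditional
  signal of the true surface is limited by drift noise, and simulation
  studies reporting ~90% identification use an order of magnitude more
  individuals on higher-contrast landscapes.

## Numerical choices and degenerate inputs

Distance matrices are validated symmetric to relative 1e-8 and then made
bitwise-symmetric by averaging; NaN encodes undefined entries throughout and
propagates by pairwise deletion with logged counts. Likelihood mixtures are
floored at 1e-300 before logs. All random streams derive from explicit
integer seeds through `numpy.random.SeedSequence`; fixed seeds give
bit-identical outputs, including the full pipeline's artifact files (no
timestamps are written). Degenerate inputs fail loudly and early:
zero-variance vectorizations, collinear controls, singular designs,
constant predictors, individuals on no-data cells, half-called genotypes
and asymmetric matrices all raise typed errors naming the offender.

## Known limitations

* The relatedness optimizer is a grid-plus-compass search; likelihood
  surfaces with multiple boundary optima could in principle defeat it,
  though the 3-parameter simplex makes this unlikely in practice.
* The migration sampler is single-threaded pure NumPy; the full-scale run
  plan (9×10⁶ total iterations) takes on the order of an hour.
* Partial-Mantel-based model selection inherits the known weaknesses of
  partial Mantel tests; the significance-aware row rule mitigates but does
  not remove them (see the recovery experiment's marginality note).
* Barrier counting is O(pairs × features) without a spatial index; large
  feature sets will be slow.
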