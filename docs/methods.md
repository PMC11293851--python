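# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `benthicnet`, in the order data flows through the
package.

## 1. From tape to network

A transect is an ordered sequence of species codes, one per centimetre,
1-based and inclusive. Maximal same-species runs are the observation
units: each pair of *adjacent* runs contributes one boundary observation
to the edge between their species. The network is built on the simple
graph for modelling, with multiplicities (repeated boundaries) retained as
edge attributes and reflected in the vertex covariates `size` (total cm of
cover) and `count` (number of runs). Conservation laws hold by
construction and are enforced in tests: run lengths sum to the transect
length, vertex sizes sum to the transect length, vertex counts sum to the
number of runs, and the multiplicity-weighted edge count equals
(runs − 1) because a line transect has two ends and no wrap-around.

Tokens in a configurable non-species set (e.g. bare rock markers) are not
vertices, and they *break* adjacency: two organisms separated by a bare
gap do not share a boundary. The default set is empty — every recorded
category, including general categories such as crustose coralline algae,
is a vertex — because that is how mixed-category survey data are usually
recorded. Species codes are case-sensitive and whitespace-stripped.

## 2. The exponential random graph model

`Pr(Y=y) = exp(θ·g(y)) / k(θ)` over simple undirected graphs on the fixed
vertex set. Implemented statistics:

- `edges` — tie count;
- `gwesp(τ, fixed)` — `e^τ Σ_{k≥1} [1 − (1 − e^{−τ})^k] EP_k`, where
  `EP_k` is the number of edges whose endpoints share exactly `k`
  neighbours. τ is fixed at 0.25 (the curved, estimated-τ family is out of
  scope). The change statistic for toggling dyad (i,j) is computed
  locally: `e^τ(1 − u^c) + Σ_{k∈CN(i,j)} (u^{esp(i,k)} + u^{esp(j,k)})`
  with `u = 1 − e^{−τ}` and `c = |CN(i,j)|`, which costs
  O(n·|CN|) per toggle instead of a full recount;
- `nodecov(x)` — `Σ_{(i,j)∈E} (x_i + x_j)`;
- `nodefactor(a)` — per level, the number of edge endpoints at that
  level; levels are discovered from the data and the lexicographically
  first level is the omitted reference, so expansion is deterministic and
  independent of row order. `vertex.names` uses the species identities
  themselves.

All kernels (statistics, change statistics, Metropolis–Hastings chain,
exhaustive enumeration) operate on a dense int8 adjacency matrix and are
JIT-compiled with numba; networks here have ≤ ~40 vertices, so dense is
the right representation.

## 3. Estimation

Three routes, used as appropriate:

**Exhaustive enumeration (n ≤ 7).** All `2^{n(n−1)/2}` graphs are
enumerated; `log k(θ)` is a log-sum-exp, the MLE maximizes the exact
likelihood (L-BFGS-B), and standard errors come from the exact statistic
covariance. This is the oracle for every stochastic estimator.

**Maximum pseudolikelihood.** Logistic regression of each dyad's
indicator on its change statistics in the observed graph. For
dyad-independent specifications (no gwesp) the pseudolikelihood *is* the
likelihood, so the species-factor model and the no-triad fallback model
are estimated exactly this way and need no MCMC. Optimization is bounded
(|θ| ≤ 30): on small networks the likelihood is often monotone in some
coefficient (complete/empty graphs, perfectly classified dyads), and the
bound keeps such fits finite. A fit whose optimum sits beyond the bound
with perfectly classified dyads is flagged as separated, with the
direction of divergence recorded; separated fits are reported
non-estimable rather than raising.

**Monte-Carlo maximum likelihood (MC-MLE).** For dyad-dependent models:
initialize at the MPLE (clipped to ±5; if the MPLE is separated, start
from the density-only model instead), then iterate: simulate `m` networks
at θ_t by Metropolis–Hastings tie toggles (uniform dyad proposal,
acceptance `min(1, exp(s·θ·Δg))`), and update θ by maximizing the
importance-sampled log-likelihood ratio
`(θ−θ_t)·g_obs − log mean exp((θ−θ_t)·g_i)` with a trust-region cap on the
step. The stopping rule is per-term t-ratios
`|g_obs − mean(g_sim)|/sd(g_sim) < 0.1` (configurable). On convergence,
two refinement rounds of fresh simulation plus importance polish are run
and the polished estimates averaged — the stopping rule alone leaves a
residual moment mismatch that maps to a θ error through the inverse
Fisher information, which matters when edges and gwesp are nearly
collinear on small graphs. Standard errors are
`sqrt(diag(Cov_sim(g)^{-1}))`; zero-variance terms get missing (not zero)
standard errors and z-values. The log-likelihood is computed against the
exact null `ℓ(0) = −D ln 2` by thermodynamic integration along
`t·θ̂, t ∈ (0,1)` (midpoint rule, short annealed chains), giving
well-defined AIC (`2p − 2ℓ`) and BIC (`p ln D − 2ℓ`).

Default chain controls: burn-in 10·D toggle proposals, thinning D, 1000
samples per iteration, at most 60 iterations; every stochastic call takes
an explicit seed. Degenerate drift (mean simulated density < 2% or > 98%)
aborts the iteration and returns a non-converged fit — never an
exception.

## 4. Goodness-of-fit, degeneracy, fallback

Goodness-of-fit simulates `n_sim = 100` networks at θ̂ (independent
Bernoulli dyads for dyad-independent fits; the MH chain started at the
observed graph otherwise) and reports, per term, the two-sided
Monte-Carlo p-value with add-one correction
`p = min(1, 2·min(r, 1−r))`, `r = (1 + #{sim ≥ obs})/(n_sim+1)` — never
exactly 0, symmetric, and high when the simulated distribution is centred
on the observed value. Degree and edgewise-shared-partner distributions
of simulated versus observed graphs are attached for distributional
checks.

A fit is degenerate when the final simulated sample has mean density
outside [2%, 98%], any per-term t-ratio above 4, or a zero-variance
statistic away from its observed value. Chain stationarity is summarized
by trace means centred on the observed statistics, lag-1 autocorrelation,
and a Geweke-style first-10%-vs-last-50% comparison whose variance uses
batch means (an iid variance would wildly over-reject on autocorrelated
traces). At the default thinning the statistic trace is strongly
autocorrelated and the Geweke check legitimately warns on a fraction of
seeds; diagnostic conclusions should use thinning of several times D.

`fit_with_fallback` encodes the analysis protocol: fit the triad model
(model 1); on non-convergence or degeneracy refit the no-triad restriction
(model 1A) and set the fallback flag; fit the species-factor model
(model 2) independently; attach goodness-of-fit to every estimable fit.
Exactly one covariate model is present per network.

## 5. Aggregation across the campaign

- **Species effects:** model-2 factor coefficients and z-values pooled per
  species over the networks where it occurs (the per-network reference
  species contributes no coefficient there). Species present in no more
  than 5 networks are excluded from the reported table.
- **Classification:** the default rule labels a species *preferential*
  when its median |z| falls below 0.05, splitting positive homophily from
  avoidance by the sign of the median coefficient. A near-zero Wald z in
  these fits marks coefficients at the boundary of the parameter space —
  attachment so consistent the logistic fit quasi-separates (the
  Hauck–Donner effect) — rather than ordinary statistical insignificance;
  the conventional reading (|z| > 1.96, `rule="wald"`) is available as a
  switch. Both the loose (all preferential) and strict (positive
  homophily with median |z| ≤ 0.005) counts are reported because the two
  consistency readings differ.
- **Phylum summary:** unweighted means of species-level mean coefficient
  and mean z per phylum; species without a phylum group under "unknown".
- **Site triad profiles:** per site, the distribution, median and sign
  counts of the gwesp coefficient across depths (triad-model fits only;
  fallback-only sites report an empty list).
- **Co-occurrence social diversity:** the fraction of networks whose
  covariate model is the full triad model, converged, with both the edges
  and gwesp goodness-of-fit p-values above 0.05 — the most direct
  operationalization of "the edge distribution and triad formation
  capture the network's formation".

## 6. Influence of survey factors

One row per network: site, depth, aspect, vertex count, multiplicity-
weighted edge count, with the triad-term goodness-of-fit p-value as the
response (fallback networks carry no such p-value and are excluded). A
seeded random forest (500 trees, minimum leaf 5) is the regression
engine. Relative influence is **cross-validated** permutation importance:
each predictor column is permuted as a whole within held-out folds and
the rise in held-out MSE, clipped at zero, is normalized to percentages.
Training-set permutation importance was rejected deliberately: it rewards
whatever the trees overfit and hands high-cardinality noise predictors (a
17-level site factor, a wide-range edge count) spurious credit, which
violates the module's null contract (a pure-noise response must yield no
dominant predictor). Partial dependence clamps one predictor to each grid
value and averages predictions over the table.

## 7. The synthetic campaign generator

The generator reproduces the study's observable regime — 500 points per
transect, geometric run lengths (mean 3 cm), a 35-species pool with
strongly skewed Dirichlet abundances (concentration 0.2) so that 14–27
species appear per transect, surveys × five depths (2, 4, 7, 14, 23 m)
with alternating sunlit/shaded aspects — while planting recoverable
truth:

- **Pairwise affinity** Φ (symmetric, 1 = neutral): the next run's
  species is drawn with probability ∝ abundance × Φ(previous, ·),
  so a planted Φ = 50 pair abuts far more often than abundance predicts.
- **Triangle closure:** with probability π the next run is a species
  already adjacent to the previous-but-one but not yet to the previous
  species, so the new boundary completes a triangle. (Choosing a species
  adjacent to *both* — the naive reading — would add no new simple-graph
  edge at all and plants nothing the model can see.)
- **Latent contact graphs:** per-step closure alone cannot move the
  fitted gwesp coefficient in this density regime — with ~170 runs over
  ≤ 27 species nearly every edge already has a shared partner and
  gwesp(0.25) saturates. Each site therefore receives a latent *contact
  graph* (which species pairs can share boundaries) sampled from the same
  edges + gwesp(0.25) family the pipeline fits, with triad coefficient
  `4.0 × π` (capped at 1.5, beyond which that family is degenerate) and
  an edges coefficient auto-calibrated to mean contact degree 3.5. The
  walk respects the contact graph up to a small leak (0.005). Planted
  truth then coincides with the estimand, and site-level recovery reduces
  to ERGM parameter recovery, which is verified independently.
- **Beta diversity:** per-site log-normal abundance jitter (σ = 0.3)
  makes sites genuinely different communities.
- An optional obligate-associate mode restricts planted pairs' contact to
  each other (epibiont-style); it sharpens the species-level signature
  but shrinks the networks, so it is off by default.

Seeding: a master seed is hashed (CRC32) with stable keys — site, survey,
depth — into per-record seeds, so campaigns are bit-reproducible and
independent of iteration order.

**What passing tests do and do not show.** The generator produces
run-structured, abundance-skewed, contact-constrained transects, but not
real settlement biology: no growth, succession, disturbance history, or
depth-dependent species pools. Recovery results certify that the pipeline
measures what it claims on data whose generating process is known; they
do not certify ecological conclusions on field data.

## 8. Known limitations

- The species-preference rule "median |z| < 0.05" detects a
  quasi-separation artifact, not pairwise homophily: for any
  well-conditioned fit the Wald z of a genuinely homophilous species stays
  well above 0.05 (planted species rank lowest by median |z| but never
  cross that threshold), so threshold-based sensitivity to planted pairs
  is poor under every planting mechanism we examined. The rank signal is
  real; the absolute threshold is not a reliable detector.
- Site identity does not dominate the influence decomposition on planted
  campaigns under honest (cross-validated) importance: once the triad
  model converges it reproduces networks about equally well at every site
  (mean gwesp GoF p ≈ 0.7–0.9), leaving little site-driven response
  variance. In-sample importance *does* make site dominate — by
  rewarding overfit on a 17-level factor — which is the likely origin of
  large site shares under traditional relative-influence measures.
- MC-MLE standard errors ignore Monte-Carlo noise in θ̂ itself; at the
  refinement settings used the residual MC error is a few hundredths per
  coefficient (verified against exhaustive enumeration at n = 6).
- Exhaustive enumeration is limited to n ≤ 7; bridge-sampled
  log-likelihoods carry Monte-Carlo error of order 0.1 nat at default
  bridge settings, which is what AIC/BIC comparisons inherit.
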