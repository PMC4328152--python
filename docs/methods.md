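# Methods

`karyosocial` tests whether eusociality shapes the evolution of haploid
chromosome number (n) in Hymenoptera — chromosome number being a coarse but
widely available proxy for recombination rate, since hymenopteran chromosomes
carry roughly one chiasma per arm.  The package implements the full
comparative chain: data coding, discrete-state modelling of sociality,
state-dependent rate tests for the continuous trait, Bayesian mixed models,
matched-pair sister contrasts, and geographic range scoring, together with a
synthetic-data generator that reproduces the statistical structure of the
compiled karyotype data so that every procedure can be validated end to end
without any external download.

## Data coding (`phylo_core`)

* Haploid counts: a species may have several published records; the analysed
  value is the arithmetic mean of all records, with a range record such as
  "53–60" contributing its midpoint (the unbiased single-value summary of an
  inclusive range).  The response everywhere is the natural logarithm of the
  aggregated count; significance statements are invariant to the log base.
* Sociality: 0 = solitary, 1 = cooperative breeder, 2 = facultatively
  eusocial, 3 = obligately eusocial; "eusocial" means code >= 2.
* Relatedness: polygyny or polyandry (or both) -> "low"; a singly mated
  monogynous species -> "high".  A missing flag excludes the species from
  relatedness analyses only, never from the pipeline.
* Species names match exactly after whitespace/underscore normalization and
  case-folding; no fuzzy matching.  Tree-trait intersection prunes the tree
  and suppresses the resulting unifurcations with branch lengths summed, so
  every retained tip keeps its root-to-tip distance.

## Sociality as a Markov chain and stochastic mapping (`mk_simmap`)

Sociality evolves as a continuous-time Markov (MK) process with an
all-rates-different matrix Q (an equal-rates option exists for sparse
states).  Because eusociality is a derived state in Hymenoptera, the root
state is *fixed* at solitary: the reported likelihood is the pruning partial
likelihood of the fixed root state, with no averaging over root states.
Rates are estimated by maximum likelihood on the log-rate scale inside the
box log-rate in [-12, 5] per unit tree depth, with 8 random restarts
(Nelder–Mead exploration, L-BFGS-B polish); ties are broken by likelihood and
then by the smaller rate-vector norm.  Transition probabilities use the dense
matrix exponential (k <= 4, trivial cost).

Stochastic maps are drawn conditional on the tip data and the fixed root:
node states pre-order from their joint conditional distribution (computed
from the pruning partials), then each branch filled in conditional on both
endpoints by **uniformization** (dominating rate = the largest diagonal
magnitude of Q).  Uniformization was chosen over rejection sampling because
rejection stalls when a branch must change state under small rates; a
rejection sampler is retained in the test suite as the distributional oracle.
Each map uses a named random substream `(seed, map_index)`, so any single map
is reproducible in isolation.

## Censored rate test (`bm_rates`)

Given a map, every branch segment has a known sociality state, so a
state-dependent Brownian motion defines the tip covariance
`V = sum_k sigma2_k * C_k`, where `C_k[i, j]` accumulates the duration each
state-k segment contributes to the shared root path of tips i and j.  The
single-rate model (one sigma2 on all branches) is compared with the per-state
model by maximum likelihood — ML, not REML, following the censored-test
literature — with the root mean mu profiled out by GLS at every step, so the
optimization runs over the log rates only, using the exact profile gradient
(the derivative through the profiled mean vanishes).  The equal-rates
solution is always included as a starting point, guaranteeing the nesting
inequality; a derivative-free rescue search runs only if the gradient route
fails to improve on it.  The LRT statistic 2*Delta logL is referred to
chi-square with df = (states present on that map) - 1; a state with zero
occupancy on a map is dropped for that map and df adjusted, never pinned to a
zero rate.

Because maps are not independent draws, no pooled P-value is reported across
maps: the result is the per-map P distribution, the fraction of maps
preferring the richer model at alpha = 0.05, and the headline rule "preferred
on all maps", plus per-map and mean per-state rates.

Numerical note: trees with near-twin tips make V numerically indefinite even
though it is PSD in exact arithmetic; the fitting path retries the Cholesky
once with a 1e-10 relative ridge.  `bm_loglik` itself is strict and raises on
a singular covariance.

The phylogenetically corrected one-way ANOVA takes the ordinary F statistic
on tip values and refers it to F statistics from single-rate BM simulations
on the same tree (the BM rate is immaterial; F is scale-free).  P-values use
the plus-one convention (1 + #{F_sim >= F_obs}) / (1 + n_sim), so P > 0.

## Phylogenetic / taxonomic mixed model (`phylo_mm`)

The animal-model form `y = X beta + u + e` with `u ~ N(0, sigma2_p A)` and
`e ~ N(0, sigma2_e I)`, where A is either the BM correlation of an
ultrametric tree (shared path length / depth) or four nested taxonomic
intercepts (superfamily/family/subfamily/genus, identity correlation each).
The per-draw phylogenetic heritability `lambda = sigma2_p / (sigma2_p +
sigma2_e)` is the analogue of Pagel's lambda.

Sampling is parameter-expanded Gibbs: the random effect is written
`u = alpha * eta` with `alpha ~ N(0, 625)` and an inverse-gamma(0.5, 0.5)
prior on the base variance; the residual variance has an
inverse-gamma(0.001, 0.001) prior; fixed effects are flat.  With a single
phylogenetic effect the model is rotated by the eigendecomposition of A
(eigenvalues clipped at 1e-8), making every sweep O(n).  Parameter expansion
keeps the chain mixing when a variance is near zero, where the plain
inverse-gamma Gibbs update is notoriously sticky.

The default chain is 60,000 iterations, 10,000 burn-in, thinning 10 — a
desk-scale setting at which these Gaussian chains mix thoroughly; a
13M/3M preset can be requested in config for strict protocol parity with
large published analyses.  Fixed effects are summarized by the KDE posterior
mode, the 95% highest-density interval, and pMCMC = twice the smaller
posterior tail probability of the coefficient's sign, floored at 2/N so it is
never zero and capped at 1.  Categorical predictors are treatment-coded
against their first level (solitary / high relatedness as references);
polynomial colony-size terms are centered before squaring to reduce
collinearity.

## Sister contrasts (`sister_pairs`)

Each contrast pairs a eusocial clade with its solitary sister and records
d = (eusocial mean n) - (solitary mean n).  Significance uses Siegel's
matched-pair randomization test: all 2^n sign assignments enumerated exactly
for n <= 20 (Monte Carlo beyond), two-tailed by the symmetry of the sign-flip
null, statistic = sum of differences (a sum-of-signs option exists; with
small all-positive samples the two coincide).  Zero differences are dropped
before enumeration.  The packaged comparison table flags the one pair in
which eusociality was secondarily *lost* (Euglossini); because that pair
tests the reverse prediction, the origins-only significance test excludes it,
while descriptive counts include every data-bearing pair.

## Area of occupancy (`range_grid`)

The score is the number of occupied 0.5-degree grid cells; cells are
half-open `[k*cell, (k+1)*cell)` anchored at (0, 0) with floor semantics for
negative coordinates.  A cell *count* (not an area) is used because any fixed
multiplier is absorbed by the intercept of the downstream log-scale
regression; single-cell species contribute log(1) = 0.

## Synthetic data (`synth_data`)

The generator emulates the compiled-karyotype study design at its natural
scales: 400-tip birth–death trees (birth 1.0, death 0.3) rescaled to unit
depth; sociality gained at rate 1.0 and lost at 0.5 from a solitary root
(roughly half the tips eusocial at depth 1); log n evolving by BM from
log(10) at sigma2 = 0.05 (solitary) vs 0.15 (eusocial), a three-fold rate
contrast; colony sizes spanning 10^1 to 10^7.

Three design choices matter for realism and are deliberate:

* The birth–death simulator stops exactly at the n-th speciation, which
  would leave zero-length sister branches and an exactly singular BM
  covariance; terminal branches are therefore extended by a residual waiting
  time drawn from the n-lineage event distribution, keeping the tree
  ultrametric.
* Log10 colony size is *heritable*: BM values on the eusocial subtree are
  rank-mapped onto a uniform grid over the configured bounds, so the marginal
  distribution is uniform while sister species get similar colony sizes, as
  in real data.  (An independent-uniform covariate would make near-twin tips
  differ by a non-BM signal and send ML rate estimates to the boundary.)
* The quadratic colony-size effect on log n (default coefficients 0.5 and
  -0.0625 on log10 colony size, peak at 10^4 individuals, peak-vs-extreme
  amplitude ~0.56 — about the magnitude seen in the published relation) is
  centered across the eusocial tips before being added, so it shapes
  variation within eusocial species without creating an absolute
  eusocial-solitary difference, matching the emulated pattern.

Chromosome counts are continuous by default (`measurement_sd = 0`,
integerization off): the inference chain is continuous, and both
integerization and multi-record jitter exist only as stress-test flags.
Consequently the censored test sees exactly its generative model, and the
mixed model on these data has a residual variance near zero (lambda near 1,
as in the real data, where lambda ~ 0.98).  What passing tests on these data
do *not* establish: robustness to discretized counts, within-species record
conflict, sampling-biased occurrences, or non-BM trait evolution — none of
which the generator emulates.

Every simulator is a pure function of (config, seed); written files are the
exact formats the parsers read, plus a truth JSON (rates, Q, tip states, node
states) so benchmarks can condition on the true history.

The eusocial rate recovered from the default dataset slightly *exceeds* the
3x BM contrast because the colony-size relation adds real extra variation to
eusocial tips; the pure-BM recovery property (median ratio within +-25% of
3x) is checked separately on trait data simulated without the colony effect.

## Pipeline (`cli`)

`karyosocial simulate|rates|mixedmodel|anova|sisters|range` over YAML
configs.  Every command writes a `manifest.json` (config hash, seed, package
version, input SHA-256 digests, output list, timestamp); deterministic
commands are bit-reproducible given the manifest.  alpha = 0.05 everywhere by
default, overridable.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run at desk scale, chosen so the
statistical checks have the power they need and no more: likelihood-vs-oracle
identities on 100 random <= 6-tip trees (1e-10 absolute); mapping
distribution versus a rejection oracle at 1e5 draws; censored-test type-I
calibration over 500 simulations at 200 tips and 3x-ratio recovery over 200
replicates at 400 tips; mixed-model coverage over 100 replicates at 200
species; the acceptance script's end-to-end pipeline at 300 tips with 50
stochastic maps.

## Known limitations

* No hidden-rate/covarion discrete models, no OU or rate-trend continuous
  models, no reversible-jump model averaging.
* The MK fit conditions maps on the ML Q (no hyperprior over Q).
* pMCMC and HPD summaries assume reasonably unimodal posteriors.
* Taxonomic random effects assume the written taxonomy is internally
  consistent; name resolution against external taxonomies is out of scope.
* The sister-pair table is taken as given; the package does not detect
  sister pairs from the tree.
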