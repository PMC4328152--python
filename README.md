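# karyosocial

Comparative phylogenetics of chromosome-number evolution and eusociality in
Hymenoptera (ants, bees, wasps and relatives).

Recombination rate is hard to measure but correlates with chromosome number:
with roughly one crossover per chromosome arm, more chromosomes mean more
recombination.  Several theories predict that eusocial species — whose
colonies of highly related workers are vulnerable to parasites and whose
reproductive skew shrinks effective population size — are selected for higher
recombination.  `karyosocial` implements the comparative machinery to test
this on compiled karyotype data: not just whether eusocial species have *more*
chromosomes, but whether their chromosome number *evolves faster*, and which
colony traits (size, relatedness, caste number, social parasitism, geographic
range) explain the variation.

It is aimed at researchers running phylogenetic comparative analyses of
discrete-state-dependent continuous traits who want every step testable and
reproducible from a single seed.

## What it computes

* **MK model + stochastic mapping** (`mk_simmap`): sociality as a
  continuous-time Markov chain with transition matrix Q and the root fixed at
  solitary; maximum-likelihood rates via Felsenstein pruning; full character
  histories sampled conditional on tip states (node states pre-order from the
  pruning partials, branch paths by endpoint-conditioned uniformization).
* **Censored rate test** (`bm_rates`): on each mapped tree, Brownian motion
  of log haploid number with a single rate sigma^2 versus state-specific
  rates sigma^2_k; LRT with df = (states present) - 1, repeated across maps
  (typically 100) and summarized by the fraction of maps preferring the
  richer model.  Plus a simulation-based phylogenetically corrected one-way
  ANOVA.
* **Phylogenetic / taxonomic mixed model** (`phylo_mm`): Gibbs-sampled
  animal model `y = X beta + u + e`, `u ~ N(0, sigma2_p A)` with A the BM
  correlation of the tree or nested taxonomic intercepts;
  parameter-expanded variance updates; pMCMC (twice the smaller sign tail)
  and the phylogenetic heritability `lambda = sigma2_p/(sigma2_p+sigma2_e)`.
* **Sister-group contrasts** (`sister_pairs`): clade-mean differences
  d = eusocial - solitary with Siegel's exact matched-pair sign-flip
  randomization test; the comparison table of eusocial clades and their
  solitary sisters ships with the package.
* **Area of occupancy** (`range_grid`): occupied 0.5-degree grid cells per
  species from occurrence coordinates.
* **Synthetic data** (`synth_data`): birth–death trees, forward-simulated
  sociality histories, state-dependent BM chromosome numbers, heritable
  colony sizes with a quadratic effect, nested taxonomy and clustered
  occurrences — the ground truth for every validation in the test suite.

## Worked example

```python
import numpy as np
from karyosocial import synth_data, mk_simmap, bm_rates

cfg = synth_data.GeneratorConfig(n_tips=300)   # study-scale defaults
ds = synth_data.generate_dataset(cfg, seed=1)

states = np.array([ds.truth["tip_states"][lb] for lb in ds.tree.tip_labels])
fit = mk_simmap.fit_mk(ds.tree, states, root_state=0, seed=1)
maps = mk_simmap.sample_histories(ds.tree, fit, n_maps=50, seed=1)

x = np.log([float(v) for v in ds.traits["chromosome_n"]])
res = bm_rates.censored_rate_test(ds.tree, maps, x, alpha=0.05)
print("gain/loss rates:", round(fit.Q[0, 1], 2), round(fit.Q[1, 0], 2))
print("mean sigma2 (solitary, eusocial):",
      {k: round(v, 3) for k, v in res.mean_rates.items()})
print("fraction of maps preferring two rates:", res.fraction_significant)
print("median eusocial/solitary ratio:",
      round(float(np.median(res.rate_ratios(1, 0))), 2))
```

prints

```
gain/loss rates: 1.29 0.54
mean sigma2 (solitary, eusocial): {0: 0.056, 1: 0.274}
fraction of maps preferring two rates: 1.0
median eusocial/solitary ratio: 4.81
```

The generator gained sociality at rate 1.0 and lost it at 0.5, and evolved
log chromosome number three times faster on eusocial branches (0.15 vs 0.05)
with an additional colony-size-driven quadratic component: the fitted MK
rates bracket the truth, the two-rate model wins on every stochastic map, and
the eusocial rate advantage is recovered (above 3x because the colony-size
relation adds real extra variation to eusocial tips).

The same analyses run from the shell:

```bash
karyosocial simulate --seed 1 --out data/            # synthetic dataset
karyosocial rates --config cfg.yaml --seed 1 --out out/rates
karyosocial mixedmodel --config cfg.yaml --seed 1 --out out/mm
karyosocial sisters --out out/sisters                # packaged table
karyosocial range --occurrences data/occurrences.tsv --out out/range
```

where `cfg.yaml` points at the tree and trait table:

```yaml
tree: data/tree.nwk
traits: data/traits.tsv
n_maps: 100
formula: "log_n ~ eusocial"
random: phylogeny
```

Every command writes a `manifest.json` with the config hash, seed, and input
digests; identical manifests reproduce identical outputs.

## Layout

```
src/karyosocial/
  phylo_core.py   trees, trait tables, karyotype coding rules
  mk_simmap.py    MK likelihood, ML fit, stochastic mapping
  bm_rates.py     painted-tree BM, censored rate test, phylo ANOVA
  phylo_mm.py     PX-Gibbs mixed model, pMCMC, lambda
  sister_pairs.py sister contrasts, exact randomization test
  range_grid.py   area-of-occupancy scoring
  synth_data.py   synthetic-data generator
  cli.py          command-line pipeline
  data/           packaged sister-group comparison table
docs/methods.md   modelling assumptions, priors, numerical choices
tests/            unit, property and statistical-calibration suites
```
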