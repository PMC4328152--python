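"""Synthetic data with the statistical structure the analyses assume.

The generator produces, from a config and a seed:

* an ultrametric birth-death tree rescaled to a target depth;
* a sociality character simulated forward under an MK process from a solitary
  root, with the exact branch-by-branch history retained (the truth for
  stochastic-mapping and rate-test benchmarks);
* log haploid chromosome numbers evolving by Brownian motion whose rate
  depends on the sociality state of each branch segment;
* colony covariates for the eusocial tips: colony sizes spanning several
  orders of magnitude (log10-uniform), queen and mate numbers (hence the
  binary relatedness coding), worker caste counts, and a social-parasite
  flag, with a quadratic colony-size effect added to the chromosome response;
* a nested taxonomy carved out of contiguous clades of the tree; and
* clustered occurrence coordinates per species.

Every simulator is a pure function of ``(config, seed)``; the written files
are exactly the formats :mod:`karyosocial.phylo_core` reads.
"""

from __future__ import annotations

import json
import random as _stdlib_random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from karyosocial.mk_simmap import StochasticMap, build_rate_matrix
from karyosocial.phylo_core import Phylogeny, write_trait_table
from karyosocial.phylo_mm import phylo_correlation

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "sim_tree",
    "sim_sociality",
    "sim_chromosomes",
    "sim_colony_traits",
    "sim_occurrences",
    "assign_taxonomy",
    "generate_dataset",
    "write_dataset",
]


@dataclass
class GeneratorConfig:
    """Study-scale defaults for the synthetic Hymenoptera-like dataset.

    The scales mirror the karyotype compilations the package targets: a few
    hundred analysed species, a tree rescaled to unit depth, roughly half the
    tips eusocial, a root haploid number of 10 chromosomes (log scale), a
    three-fold faster chromosome-number rate in eusocial lineages, and colony
    sizes spanning six orders of magnitude (10^1 to 10^7) with chromosome
    number maximal at intermediate colony sizes (negative quadratic term).
    """

    n_tips: int = 400
    birth_rate: float = 1.0
    death_rate: float = 0.3
    tree_depth: float = 1.0
    # sociality MK process (2-state: 0 = solitary, 1 = eusocial)
    gain_rate: float = 1.0
    loss_rate: float = 0.5
    # per-state BM rates of log chromosome number, and root value
    sigma2_solitary: float = 0.05
    sigma2_eusocial: float = 0.15
    root_log_n: float = float(np.log(10.0))
    measurement_sd: float = 0.0  # optional iid noise on log counts (stress test)
    # colony covariates (eusocial tips)
    log10_colony_bounds: tuple[float, float] = (1.0, 7.0)
    colony_beta: tuple[float, float, float] = (2.303, 0.5, -0.0625)
    lambda_target: float = 0.7
    colony_total_var: float = 0.04  # phylo + residual variance of the
    # standalone colony-size response
    polygyny_prob: float = 0.3
    polyandry_prob: float = 0.3
    caste_probs: tuple[float, ...] = (0.1, 0.5, 0.3, 0.1)
    parasite_prob: float = 0.1
    # taxonomy fan-out (superfamilies, families/sf, subfamilies/family,
    # genera/subfamily), carved from contiguous clades
    taxonomy_fanout: tuple[int, int, int, int] = (3, 3, 3, 4)
    # occurrences
    points_per_species: int = 20
    occurrence_dispersion: float = 2.0  # degrees

    def __post_init__(self):
        if self.n_tips < 4:
            raise ValueError("need at least 4 tips")
        for r in (self.birth_rate, self.gain_rate, self.loss_rate,
                  self.sigma2_solitary, self.sigma2_eusocial):
            if r < 0:
                raise ValueError("rates must be non-negative")

    def mk_matrix(self) -> np.ndarray:
        return build_rate_matrix([self.gain_rate, self.loss_rate], 2, "ARD")


@dataclass
class SyntheticDataset:
    tree: Phylogeny
    traits: pd.DataFrame
    occurrences: pd.DataFrame
    history: StochasticMap
    truth: dict = field(default_factory=dict)


# ------------------------------------------------------------------ pieces


def sim_tree(config: GeneratorConfig, seed: int = 0) -> Phylogeny:
    """Ultrametric birth-death tree with exactly ``n_tips`` surviving tips,
    rescaled to ``tree_depth``.

    The process stops exactly at the n-th speciation, which would leave the
    youngest sister pair with zero-length branches (and an exactly singular
    BM covariance); all terminal branches are therefore extended by a
    residual waiting time drawn from the n-lineage event distribution before
    rescaling, keeping the tree ultrametric.
    """
    rng = _stdlib_random.Random(seed)
    dtree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=config.birth_rate, death_rate=config.death_rate,
        num_extant_tips=config.n_tips, rng=rng,
        repeat_until_success=True)
    for i, leaf in enumerate(sorted(dtree.leaf_node_iter(),
                                    key=lambda nd: nd.taxon.label)):
        leaf.taxon.label = f"sp{i + 1:04d}"
    tree = Phylogeny.from_dendropy(dtree)
    total_rate = config.n_tips * (config.birth_rate + config.death_rate)
    extra = rng.expovariate(total_rate) if total_rate > 0 else 0.0
    lengths = tree.edge_length.copy()
    lengths[tree.tip_indices] += extra
    depth = (Phylogeny(tree.parent, lengths, tree.labels)
             .tip_depths().max())
    if depth <= 0:
        raise RuntimeError("degenerate simulated tree")
    return Phylogeny(tree.parent, lengths * (config.tree_depth / depth),
                     tree.labels)


def sim_sociality(tree: Phylogeny, Q: np.ndarray, root_state: int = 0,
                  seed: int = 0) -> tuple[np.ndarray, StochasticMap]:
    """Forward-simulate the MK process, recording the exact history.

    Returns (tip states in canonical tip order, true history map).
    """
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    rng = np.random.default_rng([seed, 101])
    node_states = np.empty(tree.n_nodes, dtype=np.int64)
    node_states[0] = root_state
    segments: list[list[tuple[int, float]]] = [[]]
    for i in range(1, tree.n_nodes):
        s = int(node_states[tree.parent[i]])
        t_total = float(tree.edge_length[i])
        segs: list[tuple[int, float]] = []
        pos = 0.0
        while True:
            rate = -Q[s, s]
            wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if pos + wait >= t_total:
                segs.append((s, t_total - pos))
                break
            segs.append((s, wait))
            pos += wait
            probs = Q[s].clip(min=0.0)
            probs[s] = 0.0
            s = int(rng.choice(k, p=probs / probs.sum()))
        # merge zero-duration oddities (possible when t_total == 0)
        segments.append([(st, d) for st, d in segs if d > 0] or [(s, 0.0)])
        node_states[i] = s
    smap = StochasticMap(tree=tree, node_states=node_states,
                         segments=segments, root_state=int(root_state),
                         seed_key=(seed, 101))
    tip_states = node_states[tree.tip_indices]
    return tip_states, smap


def sim_chromosomes(history: StochasticMap, sigma2,
                    root_value: float, seed: int = 0) -> np.ndarray:
    """Brownian motion along the recorded history with state-specific rates.

    ``sigma2`` maps state to rate (squared log-count units per unit time).
    Returns log trait values in canonical tip order.
    """
    tree = history.tree
    rng = np.random.default_rng([seed, 202])
    values = np.empty(tree.n_nodes)
    values[0] = root_value
    for i in range(1, tree.n_nodes):
        v = values[tree.parent[i]]
        for s, d in history.segments[i]:
            s2 = sigma2[s] if not np.isscalar(sigma2) else float(sigma2)
            if s2 < 0:
                raise ValueError("BM rates must be non-negative")
            if s2 > 0 and d > 0:
                v += rng.normal(0.0, np.sqrt(s2 * d))
        values[i] = v
    return values[tree.tip_indices]


def karyotype_field_from_log(log_n: np.ndarray, rng: np.random.Generator,
                             n_records: int = 1, jitter: bool = False
                             ) -> list[str]:
    """Render log values as integerized multi-record karyotype fields."""
    fields = []
    for v in log_n:
        base = max(1, int(round(np.exp(v))))
        recs = []
        for _ in range(n_records):
            r = base + (int(rng.integers(-1, 2)) if jitter else 0)
            recs.append(str(max(1, r)))
        fields.append(";".join(recs))
    return fields


def sim_colony_traits(tree: Phylogeny, eusocial_labels: list[str],
                      config: GeneratorConfig, seed: int = 0) -> pd.DataFrame:
    """Colony covariates for the eusocial tips.

    Returns one row per eusocial species with colony size (individuals),
    queen and mate numbers, caste count, parasite flag, the quadratic
    colony-size adjustment to the log chromosome response
    ``b1*z + b2*z^2`` (z = log10 colony size), and a standalone response
    ``b0 + b1*z + b2*z^2 + u + e`` whose phylogenetic share of variance is
    ``lambda_target``.
    """
    if len(eusocial_labels) == 0:
        raise ValueError("no eusocial tips")
    rng = np.random.default_rng([seed, 303])
    m = len(eusocial_labels)
    lo, hi = config.log10_colony_bounds
    sub = tree.prune_to(eusocial_labels)
    order = [sub.tip_labels.index(lb) for lb in eusocial_labels]
    A = phylo_correlation(sub)[np.ix_(order, order)]
    chol = np.linalg.cholesky(A + 1e-10 * np.eye(m)) if m > 1 else np.ones((1, 1))
    # colony size is itself heritable: BM values rank-mapped onto a uniform
    # grid over the configured bounds (marginally uniform, phylogenetically
    # correlated, so sister species get similar colony sizes)
    z_bm = chol @ rng.standard_normal(m)
    ranks = np.argsort(np.argsort(z_bm))
    z = lo + (hi - lo) * (ranks / max(m - 1, 1))
    b0, b1, b2 = config.colony_beta
    adjust = b1 * z + b2 * z ** 2
    queens = np.where(rng.uniform(size=m) < config.polygyny_prob, 5, 1)
    matings = np.where(rng.uniform(size=m) < config.polyandry_prob, 3, 1)
    castes = rng.choice(len(config.caste_probs), size=m, p=config.caste_probs)
    parasite = (rng.uniform(size=m) < config.parasite_prob).astype(int)
    # standalone response with the requested heritability
    s2_p = config.lambda_target * config.colony_total_var
    s2_e = (1.0 - config.lambda_target) * config.colony_total_var
    u = np.zeros(m)
    if s2_p > 0:
        u = np.sqrt(s2_p) * (chol @ rng.standard_normal(m))
    e = np.sqrt(s2_e) * rng.standard_normal(m) if s2_e > 0 else np.zeros(m)
    response = b0 + adjust + u + e
    return pd.DataFrame({
        "species": eusocial_labels,
        "colony_size": np.round(10.0 ** z).astype(np.int64),
        "log10_colony": z,
        "queens": queens,
        "matings": matings,
        "castes": castes,
        "parasite": parasite,
        "response_adjustment": adjust,
        "response": response,
    })


def assign_taxonomy(tree: Phylogeny, fanout: tuple[int, int, int, int]
                    ) -> pd.DataFrame:
    """Nested taxonomy carved from contiguous blocks of the preorder tip
    sequence (so groups are approximately monophyletic)."""
    labels = tree.tip_labels
    n = len(labels)
    names = {"superfamily": "SF", "family": "F", "subfamily": "SUBF",
             "genus": "G"}
    levels = list(names)
    totals = np.cumprod(fanout)
    cols: dict[str, list[str]] = {}
    for lvl, total in zip(levels, totals):
        total = min(int(total), n)
        bounds = np.linspace(0, n, total + 1).astype(int)
        col = np.empty(n, dtype=object)
        for g in range(total):
            col[bounds[g]:bounds[g + 1]] = f"{names[lvl]}{g + 1:03d}"
        cols[lvl] = list(col)
    return pd.DataFrame({"species": labels, **cols})


def sim_occurrences(species: list[str], points_per_species: int,
                    dispersion: float, seed: int = 0) -> pd.DataFrame:
    """Clustered coordinates: per species, normal scatter around a random
    centroid; latitudes clipped to the valid range, longitudes wrapped."""
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng([seed, 404])
    rows = []
    for sp in species:
        if points_per_species <= 0:
            continue
        c_lat = rng.uniform(-60.0, 60.0)
        c_lon = rng.uniform(-180.0, 180.0)
        lat = np.clip(rng.normal(c_lat, dispersion, points_per_species),
                      -89.999, 89.999)
        lon = (rng.normal(c_lon, dispersion, points_per_species)
               + 180.0) % 360.0 - 180.0
        for a, b in zip(lat, lon):
            rows.append({"species": sp, "latitude": float(a),
                         "longitude": float(b)})
    return pd.DataFrame(rows, columns=["species", "latitude", "longitude"])


# ------------------------------------------------------------ full dataset


def generate_dataset(config: GeneratorConfig | None = None,
                     seed: int = 0) -> SyntheticDataset:
    """Simulate the full study dataset.

    Chromosome response: BM along the true sociality history with
    state-specific rates, plus the quadratic colony-size adjustment for
    eusocial tips, plus iid measurement noise.  Sociality is written with the
    field's four-level coding (0 = solitary, 3 = obligately eusocial for the
    two-state generator).
    """
    config = config or GeneratorConfig()
    tree = sim_tree(config, seed)
    Q = config.mk_matrix()
    tip_states, history = sim_sociality(tree, Q, root_state=0, seed=seed)
    sigma2 = {0: config.sigma2_solitary, 1: config.sigma2_eusocial}
    log_n = sim_chromosomes(history, sigma2, config.root_log_n, seed=seed)
    labels = tree.tip_labels
    eusocial_labels = [lb for lb, s in zip(labels, tip_states) if s == 1]
    if not eusocial_labels:
        raise RuntimeError("simulation produced no eusocial tips; "
                           "increase gain_rate or tree depth")
    colony = sim_colony_traits(tree, eusocial_labels, config, seed=seed)
    rng = np.random.default_rng([seed, 505])
    adjust = pd.Series(0.0, index=labels)
    # centered over eusocial tips: the colony-size relation shapes variation
    # *within* the eusocial species without shifting their mean level (the
    # emulated pattern has no absolute eusocial-solitary difference)
    adj = colony["response_adjustment"].to_numpy()
    adjust.loc[colony["species"].to_numpy()] = adj - adj.mean()
    log_n_obs = (log_n + adjust.to_numpy()
                 + rng.normal(0.0, config.measurement_sd, len(labels)))
    counts = np.maximum(np.exp(log_n_obs), 1.0)

    taxonomy = assign_taxonomy(tree, config.taxonomy_fanout)
    traits = pd.DataFrame({
        "species": labels,
        "chromosome_n": [f"{c:.4f}" for c in counts],
        "sociality": [3 if s == 1 else 0 for s in tip_states],
    })
    traits = traits.merge(
        colony[["species", "colony_size", "queens", "matings", "castes",
                "parasite"]], on="species", how="left")
    traits = traits.merge(taxonomy, on="species", how="left")
    occurrences = sim_occurrences(labels, config.points_per_species,
                                  config.occurrence_dispersion, seed=seed)
    truth = {
        "seed": seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "Q": Q.tolist(),
        "sigma2": sigma2,
        "tip_states": {lb: int(s) for lb, s in zip(labels, tip_states)},
        "log_n_bm": {lb: float(v) for lb, v in zip(labels, log_n)},
        "node_states": history.node_states.tolist(),
    }
    return SyntheticDataset(tree=tree, traits=traits, occurrences=occurrences,
                            history=history, truth=truth)


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write tree.nwk, traits.tsv, occurrences.tsv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": outdir / "tree.nwk",
        "traits": outdir / "traits.tsv",
        "occurrences": outdir / "occurrences.tsv",
        "truth": outdir / "truth.json",
    }
    ds.tree.write(paths["tree"])
    write_trait_table(ds.traits, paths["traits"])
    ds.occurrences.to_csv(paths["occurrences"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth, fh, indent=1)
    return paths
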