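import numpy as np
import pandas as pd
import pytest

from karyosocial.phylo_core import Phylogeny
from karyosocial.phylo_mm import (
    ModelSpec,
    build_design,
    hpd_interval,
    phylo_correlation,
    pmcmc,
    posterior_mode,
    run_mcmc,
    summarize_fixed_effects,
    taxonomic_design,
)

from conftest import random_tree


def star_tree(n):
    tips = ",".join(f"t{i}:1.0" for i in range(n))
    return Phylogeny.from_newick(f"({tips});")


def batch_means_mcse(draws, n_batches=40):
    """Monte-Carlo standard error of the mean, robust to autocorrelation."""
    m = len(draws) // n_batches
    means = draws[:m * n_batches].reshape(n_batches, m).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(n_batches)


class TestPhyloCorrelation:
    def test_star_tree_gives_identity(self):
        A = phylo_correlation(star_tree(6))
        np.testing.assert_allclose(A, np.eye(6), atol=1e-12)

    def test_sister_pair_correlation_is_shared_fraction(self):
        t = Phylogeny.from_newick("((A:0.1,B:0.1):0.9,C:1.0);")
        A = phylo_correlation(t)
        i, j = t.tip_labels.index("A"), t.tip_labels.index("B")
        assert A[i, j] == pytest.approx(0.9, abs=1e-12)
        assert np.allclose(np.diag(A), 1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_positive_semidefinite(self, seed):
        rng = np.random.default_rng(seed)
        t = random_tree(rng, 15, ultrametric=True)
        A = phylo_correlation(t)
        assert np.linalg.eigvalsh(A).min() >= -1e-10

    def test_non_ultrametric_needs_flag(self):
        t = Phylogeny.from_newick("(A:1,(B:0.5,C:0.4):0.5);")
        with pytest.raises(ValueError, match="ultrametric"):
            phylo_correlation(t)
        A = phylo_correlation(t, rescale=True)
        assert np.allclose(np.diag(A), 1.0)


class TestTaxonomicDesign:
    def test_same_genus_shares_all_levels(self):
        df = pd.DataFrame({
            "superfamily": ["SF1"] * 2, "family": ["F1"] * 2,
            "subfamily": ["S1"] * 2, "genus": ["G1"] * 2})
        design = taxonomic_design(df)
        for _, codes, q in design:
            assert codes[0] == codes[1]

    def test_different_superfamilies_share_nothing(self):
        df = pd.DataFrame({
            "superfamily": ["SF1", "SF2"], "family": ["F1", "F2"],
            "subfamily": ["S1", "S2"], "genus": ["G1", "G2"]})
        design = taxonomic_design(df)
        for _, codes, q in design:
            assert codes[0] != codes[1]

    def test_genus_level_count(self):
        df = pd.DataFrame({
            "superfamily": ["SF1"] * 4, "family": ["F1"] * 4,
            "subfamily": ["S1"] * 4, "genus": ["G1", "G2", "G3", "G1"]})
        name, codes, q = taxonomic_design(df)[-1]
        assert name == "genus" and q == 3


class TestDesignMatrix:
    def test_numeric_categorical_and_interaction(self):
        df = pd.DataFrame({
            "y": [1.0, 2.0, 3.0, 4.0],
            "z": [0.0, 1.0, 2.0, 3.0],
            "rel": pd.Categorical(["high", "low", "high", "low"],
                                  categories=["high", "low"]),
        })
        y, X, names, rows = build_design(df, "y ~ z + rel + rel:z")
        assert names == ["(Intercept)", "z", "rel[low]", "rel[low]:z"]
        np.testing.assert_allclose(X[:, 3], [0, 1, 0, 3])

    def test_missing_rows_dropped(self):
        df = pd.DataFrame({"y": [1.0, 2.0, np.nan, 4.0],
                           "z": [0.0, np.nan, 2.0, 3.0]})
        y, X, names, rows = build_design(df, "y ~ z")
        assert list(rows) == [0, 3]

    def test_rank_deficiency_names_aliased_column(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "a": [1.0, 2.0, 3.0],
                           "b": [2.0, 4.0, 6.0]})
        with pytest.raises(ValueError, match="b"):
            build_design(df, "y ~ a + b")


class TestPmcmc:
    def test_definition(self):
        assert pmcmc(np.array([1.0, 2.0, 3.0, -1.0])) == 0.5

    def test_floor_two_over_n(self):
        assert pmcmc(np.ones(1000)) == pytest.approx(0.002)

    def test_cap_at_one(self):
        d = np.concatenate([np.ones(500), -np.ones(500)])
        assert pmcmc(d) == 1.0

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            pmcmc(np.zeros(200))


class TestSummaries:
    def test_hpd_contains_mode_of_normal_draws(self):
        rng = np.random.default_rng(0)
        d = rng.normal(3.0, 1.0, 20_000)
        lo, hi = hpd_interval(d, 0.95)
        m = posterior_mode(d)
        assert lo < m < hi
        assert m == pytest.approx(3.0, abs=0.25)
        assert hi - lo == pytest.approx(2 * 1.96, abs=0.15)


def _simulate_table(n, rng, beta=(1.0, 0.5), sd=0.5):
    z = rng.normal(size=n)
    y = beta[0] + beta[1] * z + sd * rng.standard_normal(n)
    return pd.DataFrame({"species": [f"t{i}" for i in range(n)],
                         "y": y, "z": z})


class TestRunMcmc:
    def test_identical_seed_identical_draws(self):
        rng = np.random.default_rng(1)
        df = _simulate_table(40, rng)
        tree = star_tree(40)
        spec = ModelSpec(formula="y ~ z", n_iter=1200, burnin=200, thin=2,
                         seed=77)
        a = run_mcmc(spec, df, tree=tree)
        b = run_mcmc(spec, df, tree=tree)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.sigma2_e, b.sigma2_e)
        assert a.n_draws == (1200 - 200) // 2

    def test_beta_matches_ols_on_independence_structure(self):
        """On a star tree the GLS/posterior mean of beta equals OLS."""
        rng = np.random.default_rng(2)
        df = _simulate_table(200, rng)
        tree = star_tree(200)
        spec = ModelSpec(formula="y ~ z", n_iter=6000, burnin=1000, thin=2,
                         seed=3)
        ps = run_mcmc(spec, df, tree=tree)
        X = np.column_stack([np.ones(200), df["z"]])
        ols = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
        for j in range(2):
            draws = ps.beta[:, j]
            assert abs(draws.mean() - ols[j]) < 2 * batch_means_mcse(draws)

    def test_taxonomic_random_effects_run(self):
        rng = np.random.default_rng(4)
        df = _simulate_table(60, rng)
        df["superfamily"] = ["SF1"] * 30 + ["SF2"] * 30
        df["family"] = [f"F{i // 15}" for i in range(60)]
        df["subfamily"] = [f"S{i // 5}" for i in range(60)]
        df["genus"] = [f"G{i}" for i in range(60)]
        spec = ModelSpec(formula="y ~ z", random="taxonomy", n_iter=1500,
                         burnin=300, thin=2, seed=5)
        ps = run_mcmc(spec, df)
        assert ps.group_names == ["superfamily", "family", "subfamily",
                                  "genus"]
        assert np.all(ps.sigma2_g > 0)
        summ = summarize_fixed_effects(ps)
        assert summ[1].ci_low < 0.5 < summ[1].ci_high

    def test_too_few_species_errors(self):
        df = _simulate_table(5, np.random.default_rng(0))
        with pytest.raises(ValueError, match="10"):
            run_mcmc(ModelSpec(formula="y ~ z"), df, tree=star_tree(5))

    def test_lambda_draws_in_unit_interval(self):
        rng = np.random.default_rng(6)
        df = _simulate_table(50, rng)
        tree = star_tree(50)
        spec = ModelSpec(formula="y ~ z", n_iter=1500, burnin=300, thin=2,
                         seed=8)
        ps = run_mcmc(spec, df, tree=tree)
        assert np.all((ps.lambda_ > 0) & (ps.lambda_ < 1))
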