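"""Phylogenetic mixed models: covariance construction, sampler
correctness against independent oracles, and diagnostics."""

import warnings

import dendropy
import numpy as np
import pandas as pd
import pytest

from gutkin.errors import (
    CollinearityWarning,
    DataError,
    DiagnosticError,
)
from gutkin.pmm import (
    McmcSettings,
    fit_gaussian_pmm,
    fit_poisson_pmm,
    gelman_rubin,
    pmcmc,
)
from gutkin.simulate import ComparativeSimParams, simulate_comparative_dataset
from gutkin.trees import covariance_for, phylo_covariance


def newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


class TestPhyloCovariance:
    def test_star_tree_is_identity(self):
        labels, C = phylo_covariance(newick("(A:1,B:1,C:1);"))
        np.testing.assert_allclose(C, np.eye(3))

    def test_toy_tree_shared_paths(self):
        labels, C = phylo_covariance(newick("((A:1,B:1):1,C:2);"))
        idx = {l: i for i, l in enumerate(labels)}
        assert C[idx["A"], idx["A"]] == pytest.approx(2.0)
        assert C[idx["A"], idx["B"]] == pytest.approx(1.0)
        assert C[idx["A"], idx["C"]] == pytest.approx(0.0)

    def test_symmetric_positive_semidefinite(self):
        from gutkin.simulate import simulate_pure_birth_tree

        tree = simulate_pure_birth_tree(25, seed=3)
        _, C = phylo_covariance(tree)
        np.testing.assert_allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() >= -1e-9

    def test_non_ultrametric_rejected(self):
        with pytest.raises(DataError, match="ultrametric"):
            phylo_covariance(newick("((A:1,B:2):1,C:2);"))

    def test_zero_internal_branches_equal_star_scaling(self):
        _, C = phylo_covariance(newick("((A:1,B:1):0,C:1);"), scale_to_unit=True)
        np.testing.assert_allclose(C, np.eye(3), atol=1e-12)


class TestDiagnostics:
    def test_pmcmc_one_sided(self):
        assert pmcmc(np.ones(500)) == 0.0

    def test_pmcmc_symmetric_null(self):
        rng = np.random.default_rng(1)
        assert pmcmc(rng.standard_normal(100_000)) == pytest.approx(1.0, abs=0.02)

    def test_pmcmc_counting(self):
        draws = np.concatenate([np.full(25, -1.0), np.full(975, 1.0)])
        assert pmcmc(draws) == pytest.approx(0.05)

    def test_pmcmc_negation_symmetry(self):
        rng = np.random.default_rng(2)
        draws = rng.standard_normal(5000) + 0.7
        assert pmcmc(draws) == pytest.approx(pmcmc(-draws))

    def test_pmcmc_needs_enough_draws(self):
        with pytest.raises(DiagnosticError):
            pmcmc(np.ones(10))

    def test_psrf_null_simulation(self):
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((2, 10_000))
        assert gelman_rubin(chains) < 1.01

    def test_psrf_divergent_chains(self):
        rng = np.random.default_rng(4)
        chains = np.stack([rng.standard_normal(2000), rng.standard_normal(2000) + 10])
        assert gelman_rubin(chains) > 3.0

    def test_psrf_identical_chains(self):
        chain = np.random.default_rng(5).standard_normal(1000)
        assert gelman_rubin(np.stack([chain, chain])) == pytest.approx(1.0, abs=1e-3)

    def test_psrf_single_chain_rejected(self):
        with pytest.raises(DiagnosticError):
            gelman_rubin(np.ones((1, 100)))


class TestPoissonModel:
    def test_retained_draw_bookkeeping(self):
        settings = McmcSettings(n_iterations=2017, burn_in=500, thinning=7, n_chains=2, seed=0)
        rng = np.random.default_rng(0)
        y = rng.poisson(5, 12)
        X = pd.DataFrame({"x": rng.normal(size=12)})
        fit = fit_poisson_pmm(y, X, np.eye(12), mcmc=settings)
        total = sum(arr.size for arr in fit.draws["x"][None:])  # over chains
        assert fit.draws["x"].shape == (2, (2017 - 500) // 7)
        assert total == 2 * ((2017 - 500) // 7)

    def test_glm_limit_matches_irls(self):
        """With both variance components pinned to zero the model is a
        plain Poisson regression; posterior means must agree with the
        maximum-likelihood IRLS fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        n = 60
        R = rng.uniform(0.1, 0.95, n)
        y = rng.poisson(np.exp(1.0 + 0.6 * R))
        fit = fit_poisson_pmm(
            y,
            pd.DataFrame({"relatedness": R}),
            np.eye(n),
            fix_variances={"phylo": 0.0, "resid": 0.0},
            mcmc=McmcSettings(n_iterations=20_000, burn_in=4_000, thinning=8, seed=1),
        )
        glm = sm.GLM(y, sm.add_constant(R), family=sm.families.Poisson()).fit()
        for term, ml in zip(["intercept", "relatedness"], glm.params):
            draws = fit.pooled(term)
            assert abs(draws.mean() - ml) < 2 * draws.std()

    def test_constant_predictor_flagged_and_uninformative(self):
        rng = np.random.default_rng(1)
        n = 30
        y = rng.poisson(8, n)
        X = pd.DataFrame({"relatedness": np.full(n, 0.5)})
        with pytest.warns(CollinearityWarning):
            fit = fit_poisson_pmm(
                y, X, np.eye(n),
                mcmc=McmcSettings(n_iterations=6000, burn_in=1000, thinning=5, seed=2),
            )
        assert fit.coefficient("relatedness")["pmcmc"] > 0.5

    def test_slope_recovery_coverage(self):
        """95% credible intervals cover the true relatedness slope in
        the expected fraction of replicate simulated comparative
        datasets (allowing binomial noise at 20 replicates)."""
        covered = 0
        n_reps = 20
        for rep in range(n_reps):
            tree, tab = simulate_comparative_dataset(
                ComparativeSimParams(n_species=100, true_slope=0.6, seed=3000 + rep)
            )
            C = covariance_for(tree, tab["species"].tolist())
            X = pd.DataFrame(
                {
                    "relatedness": tab["relatedness"],
                    "log_n": np.log(tab["genome_size"]),
                }
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_poisson_pmm(
                    tab["count"].to_numpy(),
                    X,
                    C,
                    mcmc=McmcSettings(
                        n_iterations=12_000, burn_in=2_000, thinning=10,
                        n_chains=1, seed=rep,
                    ),
                )
            coef = fit.coefficient("relatedness")
            if coef["ci_lower"] <= 0.6 <= coef["ci_upper"]:
                covered += 1
        assert covered >= int(0.85 * n_reps)


class TestGaussianModel:
    def test_intercept_only_limit_recovers_grand_mean(self):
        rng = np.random.default_rng(6)
        y = rng.normal(0.62, 0.1, 300)
        fit = fit_gaussian_pmm(
            y,
            pd.DataFrame(index=range(300)),
            species_codes=np.zeros(300, dtype=int),
            C=np.eye(2),
            fix_variances={"host": 0.0, "species": 0.0, "phylo": 0.0},
            mcmc=McmcSettings(n_iterations=4000, burn_in=1000, thinning=5, seed=3),
        )
        draws = fit.pooled("intercept")
        assert abs(draws.mean() - y.mean()) < 3 * draws.std()

    def test_variance_partition_recovery(self):
        """Host, species and residual variance components are recovered
        within two posterior SDs on ~2,000 observations."""
        from gutkin.simulate import simulate_relatedness_observations

        truth = {"var_host": 0.1, "var_species": 0.05, "var_resid": 0.02}
        tree, df = simulate_relatedness_observations(
            n_species=40, n_hosts=50,
            host_variance=0.1, species_variance=0.05,
            phylo_variance=0.0, residual_variance=0.02, seed=5,
        )
        assert len(df) == 2000
        species_levels = sorted(df["species"].unique())
        host_levels = sorted(df["host"].unique())
        C = covariance_for(tree, species_levels)
        sp = df["species"].map({s: i for i, s in enumerate(species_levels)}).to_numpy()
        ho = df["host"].map({h: i for i, h in enumerate(host_levels)}).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_gaussian_pmm(
                df["r_obs"].to_numpy(),
                pd.DataFrame({"abundance": df["abundance"], "sporulation": df["sporulation"]}),
                sp,
                C,
                host_codes=ho,
                fix_variances={"phylo": 0.0},  # matches the generative model
                mcmc=McmcSettings(n_iterations=8000, burn_in=2000, thinning=5, seed=4),
            )
        for name, true_val in truth.items():
            draws = fit.pooled(name)
            assert abs(draws.mean() - true_val) < 2 * draws.std(), name

    def test_duplicating_observations_tightens_posteriors(self):
        # the check uses the observation-level predictor (abundance),
        # whose information content actually doubles with the data
        from gutkin.simulate import simulate_relatedness_observations

        tree, df = simulate_relatedness_observations(
            n_species=20, n_hosts=15, beta_abundance=0.5, seed=8,
        )
        df2 = pd.concat([df, df], ignore_index=True)
        species_levels = sorted(df["species"].unique())
        host_levels = sorted(df["host"].unique())
        C = covariance_for(tree, species_levels)

        def fit_for(frame):
            sp = frame["species"].map({s: i for i, s in enumerate(species_levels)}).to_numpy()
            ho = frame["host"].map({h: i for i, h in enumerate(host_levels)}).to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return fit_gaussian_pmm(
                    frame["r_obs"].to_numpy(),
                    pd.DataFrame({"abundance": frame["abundance"]}),
                    sp, C, host_codes=ho,
                    mcmc=McmcSettings(n_iterations=8000, burn_in=2000, thinning=4, seed=9),
                )

        single, doubled = fit_for(df), fit_for(df2)
        sd1 = single.pooled("abundance").std()
        sd2 = doubled.pooled("abundance").std()
        assert sd2 < sd1
        assert abs(
            single.pooled("abundance").mean() - doubled.pooled("abundance").mean()
        ) < 3 * sd1
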