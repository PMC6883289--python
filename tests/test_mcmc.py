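"""Sampler machinery: schedule bookkeeping, update-block correctness,
diagnostics and posterior summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from elbowgen.liability import (
    PhenotypeRecord,
    PriorSpec,
    integrated_bernoulli_loglik,
)
from elbowgen.mcmc import (
    Chain,
    ChainConfig,
    MetropolisWithinGibbs,
    chain_diagnostics,
    effective_sample_size,
    lag1_autocorrelation,
    run_chain,
    sample_prior_genetic_correlation,
    summarize_posterior,
    thin_and_burn,
    update_genetic_covariance,
)
from elbowgen.pedigree import PedigreeRecord, topological_sort_pedigree
from elbowgen.synthetic import SimulationConfig, simulate_study


def _one_dog_pedigree():
    return topological_sort_pedigree([PedigreeRecord("d1", sex="F")])


def _one_dog_record(y_right=1, y_left=0):
    return PhenotypeRecord(
        "d1", y_left=y_left, y_right=y_right, sex="F", age_months=24
    )


class TestSchedule:
    def test_registry_schedule_retains_1500(self):
        cfg = ChainConfig(n_total=200_000, burn_in=50_000, thin=100)
        assert cfg.n_retained == 1500
        stub = list(range(1, 200_001))  # iteration numbers as a stub chain
        kept = thin_and_burn(stub, cfg)
        assert len(kept) == 1500
        assert kept[0] == 50_100 and kept[-1] == 200_000

    def test_thin_one_burn_zero_is_identity(self):
        cfg = ChainConfig(n_total=10, burn_in=0, thin=1)
        assert thin_and_burn(list(range(1, 11)), cfg) == list(range(1, 11))

    def test_small_enumeration(self):
        cfg = ChainConfig(n_total=10, burn_in=5, thin=2)
        assert thin_and_burn(list(range(1, 11)), cfg) == [7, 9]

    def test_burn_in_must_be_smaller_than_total(self):
        with pytest.raises(ValueError):
            ChainConfig(n_total=100, burn_in=100, thin=1)
        with pytest.raises(ValueError):
            thin_and_burn(list(range(5)), ChainConfig(n_total=10, burn_in=5, thin=2))

    def test_run_chain_retained_counts(self):
        ped = _one_dog_pedigree()
        cfg = ChainConfig(n_total=400, burn_in=0, thin=1, seed=0)
        chain = run_chain(ped, [_one_dog_record()], PriorSpec(), cfg)
        assert len(chain) == 400


class TestRunChain:
    def test_same_seed_identical_chains(self):
        st = simulate_study(SimulationConfig(seed=3, n_founders=20))
        cfg = ChainConfig(n_total=300, burn_in=100, thin=5, seed=11)
        c1 = run_chain(st.pedigree, st.phenotypes, PriorSpec(), cfg)
        c2 = run_chain(st.pedigree, st.phenotypes, PriorSpec(), cfg)
        np.testing.assert_array_equal(c1.fx_samples, c2.fx_samples)
        np.testing.assert_array_equal(c1.G_samples, c2.G_samples)

    def test_zero_proposal_scale_never_moves(self):
        ped = _one_dog_pedigree()
        cfg = ChainConfig(
            n_total=200, burn_in=0, thin=1, seed=1,
            initial_scale=0.0, adapt=False, sample_covariance=False, mix_reps=0,
        )
        chain = run_chain(ped, [_one_dog_record()], PriorSpec(), cfg)
        assert np.ptp(chain.fx_samples, axis=0).max() == 0.0

    def test_duplicate_phenotype_rejected(self):
        ped = _one_dog_pedigree()
        with pytest.raises(ValueError, match="duplicate"):
            run_chain(ped, [_one_dog_record(), _one_dog_record()], PriorSpec(),
                      ChainConfig(n_total=10, burn_in=0, thin=1))

    def test_phenotype_missing_from_pedigree_rejected(self):
        ped = _one_dog_pedigree()
        rec = PhenotypeRecord("ghost", y_left=0, y_right=0, sex="F", age_months=30)
        with pytest.raises(ValueError, match="missing from pedigree"):
            run_chain(ped, [rec], PriorSpec(), ChainConfig(n_total=10, burn_in=0, thin=1))

    def test_every_retained_G_is_psd_and_transforms_bounded(self):
        st = simulate_study(SimulationConfig(seed=5, n_founders=30))
        cfg = ChainConfig(n_total=600, burn_in=100, thin=5, seed=2)
        chain = run_chain(st.pedigree, st.phenotypes, PriorSpec(), cfg)
        df = chain.to_dataframe()
        for G in chain.G_samples:
            assert np.linalg.eigvalsh(G).min() > 0
        assert ((df["h2_R"] > 0) & (df["h2_R"] < 1)).all()
        assert ((df["rg"] >= -1) & (df["rg"] <= 1)).all()

    def test_intercept_marginal_matches_grid_posterior(self):
        """On a 1-dog pedigree with the latent blocks frozen, the MH chain's
        marginal for mu must match the exact grid posterior."""
        ped = _one_dog_pedigree()
        prior = PriorSpec(fixed_effect_variance=4.0)
        cfg = ChainConfig(
            n_total=30_000, burn_in=2_000, thin=2, seed=7,
            sample_latents=False, sample_covariance=False, mix_reps=0,
        )
        chain = run_chain(ped, [_one_dog_record(y_right=1)], prior, cfg)
        mu = np.sort(chain.fx_samples[:, 0, 0])
        grid = np.linspace(-12, 12, 4001)
        log_post = stats.norm.logpdf(grid, scale=2.0) + integrated_bernoulli_loglik(
            grid, np.ones_like(grid)
        )
        dens = np.exp(log_post - log_post.max())
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        grid_cdf_at_mu = np.interp(mu, grid, cdf)
        ecdf = (np.arange(mu.size) + 0.5) / mu.size
        assert np.abs(ecdf - grid_cdf_at_mu).max() < 0.05

    def test_acceptance_rates_after_adaptation(self):
        st = simulate_study(SimulationConfig(seed=9, n_founders=40))
        cfg = ChainConfig(n_total=2_000, burn_in=1_000, thin=10, seed=3)
        chain = run_chain(st.pedigree, st.phenotypes, PriorSpec(), cfg)
        for family, rate in chain.accept_rates.items():
            assert 0.2 <= rate <= 0.7, (family, rate)


class TestGeneticCovarianceUpdate:
    def test_zero_breeding_values_reduce_to_prior_scale(self):
        """With a = 0 the conditional is IW(V, n + q): the draw must equal a
        direct inverse-Wishart draw with those parameters and the same rng."""
        q = 6
        prior = PriorSpec()
        A_inv = np.eye(q)
        got = update_genetic_covariance(
            np.zeros(q), np.zeros(q), A_inv, prior, np.random.default_rng(5)
        )
        want = stats.invwishart.rvs(
            df=3 + q, scale=np.eye(2), random_state=np.random.default_rng(5)
        )
        np.testing.assert_allclose(got, want)

    def test_scatter_matrix_identity_relationship(self):
        """Two founders (A = I): the IW scale is V + W'W, checked through the
        Wishart moment identity E[G^-1] = df * scale^-1."""
        a_r = np.array([1.0, -2.0])
        a_l = np.array([0.5, 1.5])
        W = np.column_stack([a_r, a_l])
        scale = np.eye(2) + W.T @ W
        df = 3 + 2
        rng = np.random.default_rng(0)
        draws = np.array(
            [
                np.linalg.inv(
                    update_genetic_covariance(a_r, a_l, np.eye(2), PriorSpec(), rng)
                )
                for _ in range(4000)
            ]
        )
        want = df * np.linalg.inv(scale)
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - want) <= 4 * se)

    def test_mismatched_ainv_rejected(self):
        with pytest.raises(ValueError):
            update_genetic_covariance(
                np.zeros(3), np.zeros(3), np.eye(2), PriorSpec(),
                np.random.default_rng(0),
            )


class TestDiagnostics:
    def test_iid_sequence_has_small_lag1(self):
        x = np.random.default_rng(0).standard_normal(1500)
        assert abs(lag1_autocorrelation(x)) < 0.1

    def test_ar1_estimate(self):
        rng = np.random.default_rng(1)
        n = 10_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = 0.9 * x[i - 1] + eps[i]
        assert lag1_autocorrelation(x) == pytest.approx(0.9, abs=0.05)

    def test_alternating_sequence(self):
        x = np.tile([1.0, -1.0], 500)
        assert lag1_autocorrelation(x) == pytest.approx(-1.0, abs=0.01)

    def test_constant_chain_reported_as_constant(self):
        df = pd.DataFrame({"c": np.ones(50), "x": np.arange(50.0)})
        out = chain_diagnostics(df)
        assert out.loc["c", "constant"]
        assert np.isnan(out.loc["c", "lag1_autocorr"])
        assert not out.loc["c", "exceeds_bound"]

    def test_flagging_threshold(self):
        rng = np.random.default_rng(2)
        n = 2000
        slow = np.empty(n)
        slow[0] = 0.0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            slow[i] = 0.95 * slow[i - 1] + eps[i]
        out = chain_diagnostics(pd.DataFrame({"slow": slow}))
        assert out.loc["slow", "exceeds_bound"]

    def test_requires_ten_samples(self):
        with pytest.raises(ValueError):
            chain_diagnostics(pd.DataFrame({"x": np.arange(5.0)}))

    def test_ess_iid_near_n(self):
        x = np.random.default_rng(3).standard_normal(4000)
        assert effective_sample_size(x) == pytest.approx(4000, rel=0.25)

    def test_ess_close_to_arviz_on_ar1(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(4)
        n = 5000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = 0.8 * x[i - 1] + eps[i]
        ours = effective_sample_size(x)
        theirs = float(arviz.ess(x[None, :]))
        assert 0.5 < ours / theirs < 2.0


class TestSummaries:
    def test_constant_variance_chain(self):
        df = pd.DataFrame(
            {"var_gR": np.ones(20), "var_gL": np.ones(20), "cov_gRL": np.zeros(20)}
        )
        s = summarize_posterior(df)
        assert s.table.loc["h2_R", "mean"] == pytest.approx(0.5)
        assert s.table.loc["h2_R", "sd"] == 0.0

    def test_two_sample_arithmetic(self):
        df = pd.DataFrame(
            {"var_gR": [0.0, 1.0], "var_gL": [1.0, 1.0], "cov_gRL": [0.0, 0.0]}
        )
        s = summarize_posterior(df)
        assert s.table.loc["h2_R", "mean"] == pytest.approx(0.25)
        assert s.table.loc["h2_R", "sd"] == pytest.approx(0.25 * np.sqrt(2))

    def test_repeated_measures_flag(self):
        base = {"var_gR": np.ones(30), "var_gL": np.ones(30)}
        s_hi = summarize_posterior(pd.DataFrame({**base, "cov_gRL": np.full(30, 0.96)}))
        s_lo = summarize_posterior(pd.DataFrame({**base, "cov_gRL": np.full(30, 0.90)}))
        assert s_hi.repeated_measures_flag
        assert not s_lo.repeated_measures_flag

    def test_quantiles_ordered(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "var_gR": rng.gamma(2, 1, 200),
                "var_gL": rng.gamma(2, 1, 200),
                "cov_gRL": rng.normal(0, 0.1, 200),
            }
        )
        t = summarize_posterior(df).table
        assert (t["q2.5"] <= t["mean"]).all()
        assert (t["mean"] <= t["q97.5"]).all()

    def test_transforms_before_averaging(self):
        # mean of per-sample h2, not h2 of mean variance
        df = pd.DataFrame(
            {"var_gR": [0.0, 3.0], "var_gL": [1.0, 1.0], "cov_gRL": [0.0, 0.0]}
        )
        t = summarize_posterior(df).table
        assert t.loc["h2_R", "mean"] == pytest.approx((0.0 + 0.75) / 2)


class TestPriorCorrelation:
    def test_draws_bounded(self):
        r = sample_prior_genetic_correlation(PriorSpec(), 500, seed=0)
        assert np.all(r >= -1) and np.all(r <= 1)

    def test_high_df_concentrates(self):
        r3 = sample_prior_genetic_correlation(PriorSpec(iw_df=3), 4000, seed=1)
        r30 = sample_prior_genetic_correlation(PriorSpec(iw_df=30), 4000, seed=1)
        assert r30.var() < 0.5 * r3.var()

    def test_prior_only_chain_reproduces_prior_correlation(self):
        """Run the full sampler with no data: retained rg must be uniform."""
        ped = topological_sort_pedigree(
            [
                PedigreeRecord("A", sex="M"),
                PedigreeRecord("B", sex="F"),
                PedigreeRecord("C", sire_id="A", dam_id="B", sex="M"),
                PedigreeRecord("D", sire_id="A", dam_id="B", sex="F"),
            ]
        )
        cfg = ChainConfig(n_total=22_000, burn_in=2_000, thin=10, seed=13)
        chain = run_chain(ped, [], PriorSpec(), cfg)
        rg = chain.to_dataframe()["rg"].to_numpy()
        # thinned MCMC draws are mildly dependent; test at a conservative level
        p = stats.kstest(rg, stats.uniform(loc=-1, scale=2).cdf).pvalue
        assert p > 1e-3
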