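"""Likelihood and prior densities, sampler calibration, convergence checks."""

import math

import numpy as np
import pytest
from scipy import stats

import rickernoise as rn
from rickernoise import (
    McmcConfig,
    Model,
    PopulationSeries,
    PriorSpec,
    ThetaLatent,
    check_convergence,
    log_likelihood,
    log_prior,
    sample_conjugate_normal_mean,
    sample_posterior,
)
from rickernoise.inference import truncnorm_logpdf


def _point_m1(r=0.6, K=2.5, s2r=0.05, s2o=0.04, L=2, eps=None):
    return ThetaLatent(
        r=r, K=K, sigma2_r=s2r, sigma2_obs=s2o,
        eps=np.zeros(L) if eps is None else np.asarray(eps),
    )


class TestLikelihood:
    def test_matches_scipy_truncnorm(self):
        # independent oracle: scipy's truncated normal on (0, inf)
        series = PopulationSeries.from_values([2.0, 2.4, 2.1])
        pt = _point_m1(eps=[0.05, -0.1])
        got = log_likelihood(series, pt, Model.M1)
        from rickernoise.inference import conditional_means

        mu = conditional_means(series, pt, Model.M1)
        sd = math.sqrt(pt.sigma2_obs)
        want = sum(
            stats.truncnorm.logpdf(y, -m / sd, np.inf, loc=m, scale=sd)
            for y, m in zip(series.values[1:], mu)
        )
        assert got == pytest.approx(want, rel=1e-10)

    def test_maximized_when_observation_equals_mean(self):
        pt = _point_m1(eps=[0.0, 0.0])
        series = PopulationSeries.from_values([2.0, 2.0, 2.0])
        from rickernoise.inference import conditional_means

        mu = conditional_means(series, pt, Model.M1)
        base = truncnorm_logpdf(mu, mu, math.sqrt(pt.sigma2_obs)).sum()
        for shift in (-0.05, 0.03, 0.2):
            worse = truncnorm_logpdf(mu + shift, mu, math.sqrt(pt.sigma2_obs)).sum()
            assert worse < base

    def test_truncation_negligible_far_from_zero(self):
        # mu = 6 sigma: correction below 1e-8 against the untruncated density
        x, mu, sd = 6.2, 6.0, 1.0
        plain = stats.norm.logpdf(x, mu, sd)
        assert truncnorm_logpdf(x, mu, sd) == pytest.approx(plain, abs=1e-8)

    def test_half_normal_normalizer(self):
        # mu = 0: normalizer 1 - Phi(0) = 1/2, so log 2 is added back
        got = float(truncnorm_logpdf(np.array([1.0]), np.array([0.0]), 1.0)[0])
        assert got == pytest.approx(math.log(2) + stats.norm.logpdf(1.0), rel=1e-12)

    def test_rejects_bad_sigma_obs(self):
        series = PopulationSeries.from_values([2.0, 2.4, 2.1])
        with pytest.raises(ValueError):
            log_likelihood(series, _point_m1(s2o=0.0), Model.M1)


class TestPrior:
    def test_negative_growth_rate_excluded(self):
        pt = _point_m1()
        pt.r = -0.1
        assert log_prior(pt, PriorSpec(), Model.M1) == -np.inf

    def test_inverse_gamma_unit_density(self):
        # InvGamma(1,1) at x=1: -2 log 1 - 1 - log Gamma(1) = -1
        assert stats.invgamma.logpdf(1.0, 1.0, scale=1.0) == pytest.approx(-1.0)
        base = log_prior(_point_m1(K=1.0), PriorSpec(), Model.M1)
        other = log_prior(_point_m1(K=2.0), PriorSpec(), Model.M1)
        assert base - other == pytest.approx(
            stats.invgamma.logpdf(1.0, 1, scale=1) - stats.invgamma.logpdf(2.0, 1, scale=1)
        )

    def test_zero_shock_path_is_mode(self):
        flat = log_prior(_point_m1(eps=[0.0, 0.0]), PriorSpec(), Model.M1)
        bumped = log_prior(_point_m1(eps=[0.1, -0.1]), PriorSpec(), Model.M1)
        assert flat > bumped
        # the zero path contributes exactly L x the normal density at 0
        no_latents = flat - 2 * stats.norm.logpdf(0.0, 0.0, math.sqrt(0.05))
        assert np.isfinite(no_latents)

    def test_support_probing(self):
        # randomized points inside the support are finite, outside -inf
        rng = np.random.default_rng(2)
        pri = PriorSpec()
        for _ in range(50):
            pt = _point_m1(
                r=rng.uniform(0.01, 5), K=rng.uniform(0.1, 10),
                s2r=rng.uniform(0.01, 2), s2o=rng.uniform(0.01, 2),
                eps=rng.normal(0, 0.3, 2),
            )
            assert np.isfinite(log_prior(pt, pri, Model.M1))
        for field, bad in (("r", -1.0), ("sigma2_r", -0.5), ("sigma2_obs", 0.0)):
            pt = _point_m1()
            setattr(pt, field, bad)
            assert log_prior(pt, pri, Model.M1) == -np.inf

    def test_hierarchical_m2_density(self):
        pri = PriorSpec()
        pt = ThetaLatent(r=0.5, sigma2_obs=0.1, k=1.0, sigma2_k=0.2, eta=np.zeros(3))
        want = (
            pri.r_prior().logpdf(0.5)
            + stats.invgamma.logpdf(0.1, 1, scale=1)
            + stats.norm.logpdf(1.0, 0, 10)
            + stats.invgamma.logpdf(0.2, 1, scale=1)
            + 3 * stats.norm.logpdf(0.0, 0, math.sqrt(0.2))
        )
        assert log_prior(pt, pri, Model.M2) == pytest.approx(want, rel=1e-10)


class TestSamplerCalibration:
    def test_prior_recovery_without_data(self):
        # likelihood weight zero on a T=2 series: posterior of r equals its prior
        series = PopulationSeries.from_values([2.0, 2.5])
        mc = McmcConfig(n_chains=2, burn_in=2000, n_iter=10000, thin=2, seed=21)
        ch = sample_posterior(series, Model.M1, mcmc=mc, likelihood_scale=0.0)
        r = ch.flat(ch.scalars()["r"])
        ks = stats.kstest(r, PriorSpec().r_prior().cdf).statistic
        assert ks < 0.05

    def test_conjugate_normal_mean_closed_form(self):
        rng = np.random.default_rng(3)
        sigma, m0, tau = 1.0, 0.0, 2.0
        y = rng.normal(1.2, sigma, 25)
        prec = len(y) / sigma**2 + 1 / tau**2
        post_mean = (y.sum() / sigma**2 + m0 / tau**2) / prec
        post_sd = math.sqrt(1 / prec)
        draws = sample_conjugate_normal_mean(
            y, sigma, m0, tau, McmcConfig(n_chains=2, burn_in=2000, n_iter=20000, thin=2, seed=8)
        )
        import arviz as az

        ess = float(az.ess(az.convert_to_dataset(draws.reshape(2, -1)))["x"])
        se = post_sd / math.sqrt(ess)
        assert draws.mean() == pytest.approx(post_mean, abs=3 * se)
        assert draws.std() == pytest.approx(post_sd, rel=0.1)

    def test_determinism_bit_for_bit(self, m1_series, small_mcmc):
        a = sample_posterior(m1_series, Model.M1, mcmc=small_mcmc)
        b = sample_posterior(m1_series, Model.M1, mcmc=small_mcmc)
        assert np.array_equal(a.draws, b.draws)

    def test_stored_draws_satisfy_constraints(self, m1_chains):
        sc = m1_chains.scalars()
        assert np.all(sc["r"] > 0)
        assert np.all(sc["K"] > 0)
        assert np.all(sc["sigma2_obs"] > 0)
        assert m1_chains.n_draws == m1_chains.mcmc.n_stored

    @pytest.mark.parametrize("kt_prior", ["hierarchical", "iid-invgamma"])
    def test_m2_variants_run_and_store_kt(self, m1_series, small_mcmc, kt_prior):
        ch = sample_posterior(
            m1_series, Model.M2, priors=PriorSpec(kt_prior=kt_prior), mcmc=small_mcmc
        )
        Kt = ch.latent("K_t")
        assert Kt.shape == (2, small_mcmc.n_iter // small_mcmc.thin, len(m1_series) - 1)
        assert np.all(Kt > 0)


class TestChainsIO:
    def test_save_writes_csv_and_sidecar(self, m1_chains, tmp_path):
        import json

        m1_chains.save(tmp_path / "fit")
        df = __import__("pandas").read_csv(tmp_path / "fit" / "chains.csv")
        assert set(df.columns) == {"chain", "iteration", "parameter", "value"}
        assert set(df.parameter) >= {"r", "K", "sigma2_obs"}
        sidecar = json.loads((tmp_path / "fit" / "chains.json").read_text())
        assert sidecar["model"] == "M1"
        assert sidecar["mcmc"]["thin"] == m1_chains.mcmc.thin
        assert {d["parameter"] for d in sidecar["diagnostics"]} >= {"r", "K"}


class TestConvergence:
    def test_iid_chains_pass(self):
        rng = np.random.default_rng(0)
        fake = {"x": rng.normal(size=(3, 2000))}
        rep = check_convergence(fake, ess_min=100)
        assert rep.passed
        assert rep.table.loc[0, "rhat"] == pytest.approx(1.0, abs=0.01)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(0)
        fake = {"x": np.stack([rng.normal(0, 1, 500), rng.normal(20, 1, 500)])}
        rep = check_convergence(fake)
        assert not rep.passed
        assert rep.table.loc[0, "rhat"] > 1.1

    def test_constant_chains_degenerate(self):
        fake = {"x": np.ones((2, 100))}
        rep = check_convergence(fake)
        assert not rep.passed
        assert "degenerate" in rep.table.loc[0, "note"]

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            check_convergence({"x": np.zeros((1, 100))})
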