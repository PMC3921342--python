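import numpy as np
import pytest
from scipy import stats

from bymspat.bym_mcmc import (
    BYMConfig,
    Parameters,
    PosteriorDraws,
    dic,
    fit_bym,
    gelman_rubin,
    log_likelihood,
    mc_error,
    summarize_posterior,
)
from bymspat.ecological_indices import OutcomeTable


def _outcomes(observed, surveyed):
    return OutcomeTable.from_counts(
        [f"a{i}" for i in range(len(observed))], observed, surveyed
    )


def _manual_draws(beta0, beta, n_areas=0, config=None, names=None):
    """PosteriorDraws with given (chains, kept) scalar arrays and zero u, v."""
    beta0 = np.asarray(beta0, dtype=float)
    beta = np.asarray(beta, dtype=float)
    C, S = beta0.shape
    return PosteriorDraws(
        beta0=beta0,
        beta=beta,
        u=np.zeros((C, S, n_areas)) if n_areas else None,
        v=np.zeros((C, S, n_areas)) if n_areas else None,
        tau_u=None,
        tau_v=None,
        sigma2_e=None,
        deviance=np.zeros((C, S)),
        config=config or BYMConfig(),
        covariate_names=names or [f"x{j}" for j in range(beta.shape[2])],
    )


class TestLogLikelihood:
    def test_single_area_poisson(self):
        out = OutcomeTable(["a"], [1], [10], np.array([1.0]), np.array([1.0]))
        params = Parameters(0.0, np.zeros(0), np.zeros(1), np.zeros(1))
        ll = log_likelihood(params, out, np.zeros((1, 0)), "poisson")
        assert ll == pytest.approx(-1.0, abs=1e-12)

    def test_saturated_maximizes(self):
        rng = np.random.default_rng(0)
        out = _outcomes([3, 7, 2, 9], [20, 30, 10, 40])
        eta_hat = np.log(out.observed / out.expected)
        base = Parameters(0.0, np.zeros(0), eta_hat, np.zeros(4))
        best = log_likelihood(base, out, np.zeros((4, 0)), "poisson")
        for _ in range(20):
            pert = Parameters(0.0, np.zeros(0), eta_hat + rng.normal(0, 0.3, 4),
                              np.zeros(4))
            assert log_likelihood(pert, out, np.zeros((4, 0)), "poisson") <= best

    def test_poisson_matches_term_oracle(self):
        rng = np.random.default_rng(1)
        n, p = 8, 2
        out = _outcomes(rng.integers(0, 10, n), rng.integers(20, 50, n))
        X = rng.normal(size=(n, p))
        params = Parameters(0.2, np.array([0.3, -0.1]),
                            rng.normal(0, 0.2, n), rng.normal(0, 0.1, n))
        eta = params.beta0 + X @ params.beta + params.u + params.v
        oracle = sum(
            stats.poisson.logpmf(out.observed[i], out.expected[i] * np.exp(eta[i]))
            for i in range(n)
        )
        got = log_likelihood(params, out, X, "poisson")
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_lognormal_matches_norm_oracle(self):
        rng = np.random.default_rng(2)
        n = 6
        out = _outcomes(rng.integers(1, 10, n), rng.integers(20, 50, n))
        params = Parameters(0.1, np.zeros(0), np.zeros(n), np.zeros(n), sigma2_e=0.3)
        y = np.log(out.observed / out.expected)
        oracle = stats.norm.logpdf(y, loc=0.1, scale=np.sqrt(0.3)).sum()
        got = log_likelihood(params, out, np.zeros((n, 0)), "lognormal")
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_zero_correction_applied(self):
        out = _outcomes([0, 5], [20, 20])
        params = Parameters(0.0, np.zeros(0), np.zeros(2), np.zeros(2), sigma2_e=1.0)
        y = np.log((out.observed + 0.5) / out.expected)
        oracle = stats.norm.logpdf(y, 0.0, 1.0).sum()
        got = log_likelihood(params, out, np.zeros((2, 0)), "lognormal")
        assert got == pytest.approx(oracle, abs=1e-12)


class TestDIC:
    def test_degenerate_draws_zero_pd(self):
        out = _outcomes([3, 7], [20, 30])
        draws = _manual_draws(
            np.full((2, 100), 0.1), np.zeros((2, 100, 0)), n_areas=2
        )
        params = Parameters(0.1, np.zeros(0), np.zeros(2), np.zeros(2))
        d = -2 * log_likelihood(params, out, np.zeros((2, 0)), "poisson")
        draws.deviance[:] = d
        fit = dic(draws, out, np.zeros((2, 0)))
        assert fit.pD == pytest.approx(0.0, abs=1e-10)
        assert fit.dic == pytest.approx(fit.dbar, abs=1e-10)

    def test_identity_dic_dbar_pd(self, short_fit):
        ds, X, draws = short_fit
        fit = dic(draws, ds.outcomes, X)
        assert fit.dic == pytest.approx(fit.dbar + fit.pD, abs=1e-12)

    def test_stored_deviance_matches_per_draw_oracle(self, short_fit):
        ds, X, draws = short_fit
        rng = np.random.default_rng(3)
        idx = rng.integers(0, draws.n_kept, size=25)
        for c in range(draws.n_chains):
            for i in idx:
                params = Parameters(
                    beta0=draws.beta0[c, i],
                    beta=draws.beta[c, i],
                    u=draws.u[c, i],
                    v=draws.v[c, i],
                )
                d = -2 * log_likelihood(params, ds.outcomes, X, "poisson")
                assert d == pytest.approx(draws.deviance[c, i], abs=1e-8)

    def test_requires_enough_draws(self):
        out = _outcomes([3, 7], [20, 30])
        draws = _manual_draws(np.zeros((1, 10)), np.zeros((1, 10, 0)), n_areas=2)
        with pytest.raises(ValueError, match="100"):
            dic(draws, out)


class TestGelmanRubin:
    def test_identical_chains(self):
        x = np.random.default_rng(4).normal(size=3000)
        r = gelman_rubin(np.stack([x, x]))
        assert r < 1.001

    def test_iid_null(self):
        rng = np.random.default_rng(5)
        r = gelman_rubin(rng.normal(size=(2, 3000)))
        assert r < 1.02

    def test_separated_chains(self):
        rng = np.random.default_rng(6)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert gelman_rubin(chains) > 3

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            gelman_rubin(np.zeros((1, 100)))

    def test_named_parameter(self, short_fit):
        _, _, draws = short_fit
        assert gelman_rubin(draws, "beta0") < 1.2


class TestMCError:
    def test_iid_standard_error(self):
        x = np.random.default_rng(7).normal(size=5000)
        se = mc_error(x)
        assert abs(se - 1 / np.sqrt(5000)) < 0.3 / np.sqrt(5000)

    def test_constant_chain(self):
        assert mc_error(np.full(1000, 3.14)) == pytest.approx(0.0, abs=1e-12)

    def test_autocorrelated_exceeds_iid(self):
        rng = np.random.default_rng(8)
        n = 5000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = 0.9 * x[i - 1] + eps[i]
        assert mc_error(x) > 1.5 / np.sqrt(n)

    def test_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            mc_error(np.zeros(10))


class TestSummaries:
    def test_constant_coefficient_or(self):
        draws = _manual_draws(
            np.zeros((2, 100)), np.full((2, 100, 1), 0.074), names=["no_support"]
        )
        s = summarize_posterior(draws).set_index("parameter")
        assert round(s.loc["OR.no_support", "median"], 2) == 1.08

    def test_quantile_transform(self):
        rng = np.random.default_rng(9)
        b = rng.normal(0.074, 0.035, size=(2, 500, 1))
        draws = _manual_draws(np.zeros((2, 500)), b, names=["x"])
        s = summarize_posterior(draws).set_index("parameter")
        for col in ("q2.5", "median", "q97.5"):
            assert s.loc["OR.x", col] == pytest.approx(
                np.exp(s.loc["x", col]), abs=1e-14
            )

    def test_printed_upper_quantile(self):
        draws = _manual_draws(
            np.zeros((2, 100)), np.full((2, 100, 1), 0.142), names=["x"]
        )
        s = summarize_posterior(draws).set_index("parameter")
        assert round(s.loc["OR.x", "q97.5"], 2) == 1.15

    def test_symmetric_not_significant(self):
        rng = np.random.default_rng(10)
        b = rng.normal(0.0, 1.0, size=(2, 500, 1))
        draws = _manual_draws(np.zeros((2, 500)), b, names=["x"])
        s = summarize_posterior(draws).set_index("parameter")
        assert not s.loc["x", "significant"]


class TestFitBym:
    def test_intercept_only_null_data(self, adj4_path):
        # O == E implies RR ~ 1, so beta0 should concentrate near zero
        from bymspat.synthetic_data import SimulationSpec, simulate_outcomes

        spec = SimulationSpec(n_areas=36, beta0=0.0, sigma_u=0.0, sigma_v=0.0, seed=12)
        ds = simulate_outcomes(spec)
        cfg = BYMConfig(burn_in=400, samples=400, include_structured=False, seed=2)
        draws = fit_bym(ds.outcomes, None, None, cfg)
        b0 = draws.pooled("beta0")
        assert abs(b0.mean()) < 2 * b0.std()

    def test_icar_constraint_on_stored_draws(self, short_fit):
        _, _, draws = short_fit
        sums = draws.u.sum(axis=2)
        assert np.abs(sums).max() < 1e-8

    def test_all_zero_counts_rejected(self, adj4_path):
        out = OutcomeTable(["a", "b", "c", "d"], [0, 0, 0, 0], [10] * 4,
                           np.zeros(4), np.zeros(4))
        with pytest.raises(ValueError, match="all observed"):
            fit_bym(out, None, adj4_path, BYMConfig(seed=1))

    def test_structured_requires_adjacency(self):
        out = _outcomes([1, 2, 3, 4], [10, 10, 10, 10])
        with pytest.raises(ValueError, match="adjacency"):
            fit_bym(out, None, None, BYMConfig())

    def test_chains_have_equal_length(self, short_fit):
        _, _, draws = short_fit
        assert draws.beta0.shape == (2, 400)
        assert np.isfinite(draws.deviance).all()

    def test_deterministic_given_seed(self, synthetic_small):
        ds = synthetic_small
        cfg = BYMConfig(burn_in=100, samples=100, seed=5)
        X = ds.covariates[["var01"]].to_numpy()
        d1 = fit_bym(ds.outcomes, X, ds.adjacency, cfg)
        d2 = fit_bym(ds.outcomes, X, ds.adjacency, cfg)
        np.testing.assert_array_equal(d1.beta0, d2.beta0)
        np.testing.assert_array_equal(d1.u, d2.u)

    def test_parameter_lookup(self, short_fit):
        _, _, draws = short_fit
        assert draws.parameter("var01").shape == (2, 400)
        assert draws.parameter("u[3]").shape == (2, 400)
        with pytest.raises(KeyError):
            draws.parameter("nonexistent")

    def test_lognormal_fit_runs(self, synthetic_small):
        ds = synthetic_small
        cfg = BYMConfig(likelihood="lognormal", burn_in=200, samples=200, seed=3)
        X = ds.covariates[["var01"]].to_numpy()
        draws = fit_bym(ds.outcomes, X, ds.adjacency, cfg, covariate_names=["var01"])
        assert draws.sigma2_e is not None
        assert np.isfinite(draws.deviance).all()
        fit = dic(draws, ds.outcomes, X)
        assert np.isfinite(fit.dic)
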