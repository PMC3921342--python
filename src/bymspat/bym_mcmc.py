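"""Besag-York-Mollie spatial regression by MCMC.

The linear predictor is ``log theta_i = beta0 + x_i'beta + u_i + v_i``
with an intrinsic-CAR structured effect ``u`` (sum-to-zero, re-centred
every sweep) and iid normal unstructured effect ``v``; either random
effect can be switched off.  Two likelihoods are supported:

* ``poisson``  — ``O_i ~ Poisson(E_i * theta_i)`` (standard disease
  mapping); intercept/coefficients move by adaptive random-walk
  Metropolis, ``u_i``/``v_i`` by Metropolis with their conditional-prior
  proposal, precisions by conjugate Gamma draws.
* ``lognormal`` — ``log((O_i + c)/E_i) ~ N(log theta_i, sigma2_e)``;
  every update is a conjugate Gibbs draw.

Priors: intercept and coefficients N(0, 10000); random-effect precisions
Gamma(0.5, 0.0005).  DIC/pD, Gelman-Rubin, batch-means MC error and
posterior/odds-ratio summaries are provided alongside the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from bymspat.ecological_indices import OutcomeTable
from bymspat.geo_adjacency import AdjacencyMatrix

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class BYMConfig:
    """Sampler and prior settings for one BYM fit."""

    likelihood: str = "poisson"
    include_structured: bool = True
    include_unstructured: bool = True
    intercept_prior_variance: float = 10_000.0
    coef_prior_variance: float = 10_000.0
    precision_prior_shape: float = 0.5
    precision_prior_rate: float = 0.0005
    n_chains: int = 2
    burn_in: int = 3000
    samples: int = 3000
    thin: int = 1
    seed: int = 0
    lognormal_zero_correction: float = 0.5
    fixed_tau_u: Optional[float] = None
    fixed_tau_v: Optional[float] = None
    fixed_sigma2_e: Optional[float] = None

    def __post_init__(self) -> None:
        if self.likelihood not in ("poisson", "lognormal"):
            raise ValueError("likelihood must be 'poisson' or 'lognormal'")
        if self.burn_in <= 0 or self.samples <= 0 or self.thin < 1:
            raise ValueError("burn_in, samples must be > 0 and thin >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class Parameters:
    """One state of the model (used for plug-in deviance and tests)."""

    beta0: float
    beta: np.ndarray
    u: np.ndarray
    v: np.ndarray
    tau_u: float = 1.0
    tau_v: float = 1.0
    sigma2_e: float = 1.0


@dataclass
class ModelFit:
    dbar: float
    d_hat: float

    @property
    def pD(self) -> float:
        return self.dbar - self.d_hat

    @property
    def dic(self) -> float:
        return self.dbar + self.pD


@dataclass
class PosteriorDraws:
    """Kept MCMC samples, chain-major: arrays shaped (chains, kept, ...)."""

    beta0: np.ndarray
    beta: np.ndarray  # (C, S, p)
    u: Optional[np.ndarray]  # (C, S, n) or None
    v: Optional[np.ndarray]
    tau_u: Optional[np.ndarray]
    tau_v: Optional[np.ndarray]
    sigma2_e: Optional[np.ndarray]
    deviance: np.ndarray
    config: BYMConfig
    covariate_names: list[str] = field(default_factory=list)
    acceptance: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.beta0.shape[0]

    @property
    def n_kept(self) -> int:
        return self.beta0.shape[1]

    def parameter(self, name: str) -> np.ndarray:
        """Per-chain draws of a named scalar parameter, shape (chains, kept)."""
        if name == "beta0" or name == "intercept":
            return self.beta0
        for attr in ("tau_u", "tau_v", "sigma2_e", "deviance"):
            if name == attr:
                arr = getattr(self, attr)
                if arr is None:
                    raise KeyError(f"{name} not sampled in this fit")
                return arr
        if name in self.covariate_names:
            j = self.covariate_names.index(name)
            return self.beta[:, :, j]
        for prefix, arr in (("beta", self.beta), ("u", self.u), ("v", self.v)):
            if name.startswith(prefix + "[") and name.endswith("]"):
                if arr is None:
                    raise KeyError(f"{prefix} not sampled in this fit")
                return arr[:, :, int(name[len(prefix) + 1 : -1])]
        raise KeyError(f"unknown parameter {name!r}")

    def pooled(self, name: str) -> np.ndarray:
        return self.parameter(name).reshape(-1)

    def posterior_mean_state(self) -> Parameters:
        n = self.u.shape[2] if self.u is not None else (
            self.v.shape[2] if self.v is not None else 0
        )
        return Parameters(
            beta0=float(self.beta0.mean()),
            beta=self.beta.mean(axis=(0, 1)),
            u=self.u.mean(axis=(0, 1)) if self.u is not None else np.zeros(n),
            v=self.v.mean(axis=(0, 1)) if self.v is not None else np.zeros(n),
            tau_u=float(self.tau_u.mean()) if self.tau_u is not None else 1.0,
            tau_v=float(self.tau_v.mean()) if self.tau_v is not None else 1.0,
            sigma2_e=float(self.sigma2_e.mean()) if self.sigma2_e is not None else 1.0,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format (chain, iteration, parameter, value) table."""
        rows = []
        names = ["beta0"] + [f"beta[{j}]" for j in range(self.beta.shape[2])]
        names += [x for x in ("tau_u", "tau_v", "sigma2_e", "deviance")
                  if getattr(self, x) is not None]
        for name in names:
            arr = self.parameter(name)
            for c in range(self.n_chains):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(self.n_kept),
                            "parameter": name,
                            "value": arr[c],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def _lognormal_response(outcomes: OutcomeTable, correction: float) -> np.ndarray:
    O = outcomes.observed
    c = correction if (O == 0).any() else 0.0
    return np.log((O + c) / outcomes.expected)


def log_likelihood(
    params: Parameters,
    outcomes: OutcomeTable,
    X: np.ndarray,
    kind: str = "poisson",
    zero_correction: float = 0.5,
) -> float:
    """Model log-likelihood at one parameter state."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        X = np.zeros((outcomes.n, 0))
    eta = params.beta0 + (X @ params.beta if X.shape[1] else 0.0) + params.u + params.v
    if not np.isfinite(eta).all():
        raise FloatingPointError("non-finite linear predictor")
    O, E = outcomes.observed, outcomes.expected
    if kind == "poisson":
        if (E <= 0).any():
            raise ValueError("expected counts must be positive")
        log_mu = np.log(E) + eta
        return float((O * log_mu - E * np.exp(eta) - gammaln(O + 1)).sum())
    if kind == "lognormal":
        y = _lognormal_response(outcomes, zero_correction)
        s2 = params.sigma2_e
        return float(
            (-0.5 * (_LOG_2PI + np.log(s2)) - (y - eta) ** 2 / (2 * s2)).sum()
        )
    raise ValueError("kind must be 'poisson' or 'lognormal'")


def _greedy_colors(adj: AdjacencyMatrix) -> list[np.ndarray]:
    """Partition areas into independent sets for parallel single-site updates."""
    import networkx as nx

    coloring = nx.greedy_color(adj.to_graph(), strategy="largest_first")
    k = max(coloring.values()) + 1
    return [
        np.array(sorted(i for i, c in coloring.items() if c == col), dtype=int)
        for col in range(k)
    ]


def _run_chain_poisson(
    O, E, X, adj: AdjacencyMatrix | None, config: BYMConfig, seed: int
):
    rng = np.random.default_rng(seed)
    n, p = len(O), X.shape[1]
    logE = np.log(E)
    lgam = gammaln(O + 1).sum()
    sumO = O.sum()
    OX = X.T @ O if p else np.zeros(0)

    use_u = config.include_structured and adj is not None
    use_v = config.include_unstructured
    if use_u:
        W = adj.dense()
        num = W.sum(axis=1)
        colors = _greedy_colors(adj)
        ei, ej = adj.edges[:, 0], adj.edges[:, 1]

    beta0, beta = 0.0, np.zeros(p)
    u, v = np.zeros(n), np.zeros(n)
    tau_u = config.fixed_tau_u or 10.0
    tau_v = config.fixed_tau_v or 10.0
    a0, b0 = config.precision_prior_shape, config.precision_prior_rate
    pv0, pvb = config.intercept_prior_variance, config.coef_prior_variance

    scale0 = 0.1
    scales = np.full(p, 0.1)
    acc0 = np.zeros(2)  # (accepts, proposals) for beta0
    accb = np.zeros((p, 2))
    acc_u = np.zeros(2)
    acc_v = np.zeros(2)

    total = config.burn_in + config.samples * config.thin
    kept = config.samples
    out = {
        "beta0": np.empty(kept),
        "beta": np.empty((kept, p)),
        "u": np.empty((kept, n)) if use_u else None,
        "v": np.empty((kept, n)) if use_v else None,
        "tau_u": np.empty(kept) if (use_u and config.fixed_tau_u is None) else None,
        "tau_v": np.empty(kept) if (use_v and config.fixed_tau_v is None) else None,
        "deviance": np.empty(kept),
    }
    kidx = 0

    eta = beta0 + u + v  # X@beta is 0 at start
    mu = E * np.exp(eta)
    for it in range(total):
        adapting = it < config.burn_in

        # intercept random walk; O(1) via cached sums
        d = scale0 * rng.standard_normal()
        dll = sumO * d - (np.expm1(d)) * mu.sum()
        dlp = -((beta0 + d) ** 2 - beta0**2) / (2 * pv0)
        acc0[1] += 1
        if np.log(rng.random()) < dll + dlp:
            beta0 += d
            mu *= np.exp(d)
            acc0[0] += 1

        # coefficients, one at a time
        for j in range(p):
            d = scales[j] * rng.standard_normal()
            mult = np.exp(X[:, j] * d)
            dll = d * OX[j] - (mu * (mult - 1.0)).sum()
            dlp = -((beta[j] + d) ** 2 - beta[j] ** 2) / (2 * pvb)
            accb[j, 1] += 1
            if np.log(rng.random()) < dll + dlp:
                beta[j] += d
                mu *= mult
                accb[j, 0] += 1

        # structured effects: Metropolis with the ICAR conditional as proposal
        # (prior terms cancel, acceptance is the likelihood ratio alone)
        if use_u:
            for S in colors:
                nbr_mean = (W[S] @ u) / num[S]
                prop = nbr_mean + rng.standard_normal(len(S)) / np.sqrt(tau_u * num[S])
                d = prop - u[S]
                logr = O[S] * d - mu[S] * np.expm1(d)
                acc = np.log(rng.random(len(S))) < logr
                u[S] = np.where(acc, prop, u[S])
                mu[S] = np.where(acc, mu[S] * np.exp(d), mu[S])
                acc_u += (acc.sum(), len(S))
            m = u.mean()
            u -= m
            beta0 += m  # likelihood-invariant transfer of the level
            if config.fixed_tau_u is None:
                ss = ((u[ei] - u[ej]) ** 2).sum()
                tau_u = rng.gamma(a0 + (n - 1) / 2.0, 1.0 / (b0 + ss / 2.0))

        # unstructured effects: prior proposal, likelihood-ratio acceptance
        if use_v:
            prop = rng.standard_normal(n) / np.sqrt(tau_v)
            d = prop - v
            logr = O * d - mu * np.expm1(d)
            acc = np.log(rng.random(n)) < logr
            v = np.where(acc, prop, v)
            mu = np.where(acc, mu * np.exp(d), mu)
            acc_v += (acc.sum(), n)
            if config.fixed_tau_v is None:
                tau_v = rng.gamma(a0 + n / 2.0, 1.0 / (b0 + (v**2).sum() / 2.0))

        # adapt random-walk scales toward ~40% acceptance (burn-in only)
        if adapting and (it + 1) % 50 == 0:
            if acc0[1] > 0:
                scale0 *= np.exp((acc0[0] / acc0[1] - 0.44))
                acc0[:] = 0
            for j in range(p):
                if accb[j, 1] > 0:
                    scales[j] *= np.exp((accb[j, 0] / accb[j, 1] - 0.44))
                    accb[j] = 0

        if not adapting and (it - config.burn_in + 1) % config.thin == 0:
            eta = beta0 + (X @ beta if p else 0.0) + u + v
            mu = E * np.exp(eta)  # refresh against incremental drift
            if not np.isfinite(mu).all():
                raise FloatingPointError("divergent chain: non-finite Poisson mean")
            ll = (O * (logE + eta)).sum() - mu.sum() - lgam
            out["beta0"][kidx] = beta0
            out["beta"][kidx] = beta
            if use_u:
                out["u"][kidx] = u
                if out["tau_u"] is not None:
                    out["tau_u"][kidx] = tau_u
            if use_v:
                out["v"][kidx] = v
                if out["tau_v"] is not None:
                    out["tau_v"][kidx] = tau_v
            out["deviance"][kidx] = -2.0 * ll
            kidx += 1

    out["acceptance"] = {
        "beta0": float(acc0[0] / acc0[1]) if acc0[1] else 1.0,
        "u": float(acc_u[0] / acc_u[1]) if acc_u[1] else 1.0,
        "v": float(acc_v[0] / acc_v[1]) if acc_v[1] else 1.0,
    }
    return out


def _run_chain_lognormal(O, E, X, adj, config: BYMConfig, seed: int, y: np.ndarray):
    rng = np.random.default_rng(seed)
    n, p = len(O), X.shape[1]
    use_u = config.include_structured and adj is not None
    use_v = config.include_unstructured
    if use_u:
        W = adj.dense()
        num = W.sum(axis=1)
        colors = _greedy_colors(adj)
        ei, ej = adj.edges[:, 0], adj.edges[:, 1]

    Xt = np.column_stack([np.ones(n), X])
    prior_prec = np.concatenate(
        [[1.0 / config.intercept_prior_variance], np.full(p, 1.0 / config.coef_prior_variance)]
    )
    XtX = Xt.T @ Xt

    beta_all = np.zeros(p + 1)
    u, v = np.zeros(n), np.zeros(n)
    tau_u = config.fixed_tau_u or 10.0
    tau_v = config.fixed_tau_v or 10.0
    s2e = config.fixed_sigma2_e or 0.1
    a0, b0 = config.precision_prior_shape, config.precision_prior_rate

    total = config.burn_in + config.samples * config.thin
    kept = config.samples
    out = {
        "beta0": np.empty(kept),
        "beta": np.empty((kept, p)),
        "u": np.empty((kept, n)) if use_u else None,
        "v": np.empty((kept, n)) if use_v else None,
        "tau_u": np.empty(kept) if (use_u and config.fixed_tau_u is None) else None,
        "tau_v": np.empty(kept) if (use_v and config.fixed_tau_v is None) else None,
        "sigma2_e": np.empty(kept) if config.fixed_sigma2_e is None else None,
        "deviance": np.empty(kept),
    }
    kidx = 0
    for it in range(total):
        # regression block: joint conjugate normal draw
        r = y - u - v
        prec = XtX / s2e + np.diag(prior_prec)
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, Xt.T @ r / s2e)
        z = rng.standard_normal(p + 1)
        beta_all = mean + np.linalg.solve(chol.T, z)

        fitted = Xt @ beta_all
        if use_u:
            for S in colors:
                nbr_mean = (W[S] @ u) / num[S]
                prec_i = tau_u * num[S] + 1.0 / s2e
                resid = y[S] - fitted[S] - v[S]
                mean_i = (tau_u * num[S] * nbr_mean + resid / s2e) / prec_i
                u[S] = mean_i + rng.standard_normal(len(S)) / np.sqrt(prec_i)
            m = u.mean()
            u -= m
            beta_all[0] += m
            fitted += m
            if config.fixed_tau_u is None:
                ss = ((u[ei] - u[ej]) ** 2).sum()
                tau_u = rng.gamma(a0 + (n - 1) / 2.0, 1.0 / (b0 + ss / 2.0))

        if use_v:
            prec_i = tau_v + 1.0 / s2e
            resid = y - fitted - u
            mean_i = (resid / s2e) / prec_i
            v = mean_i + rng.standard_normal(n) / np.sqrt(prec_i)
            if config.fixed_tau_v is None:
                tau_v = rng.gamma(a0 + n / 2.0, 1.0 / (b0 + (v**2).sum() / 2.0))

        eta = fitted + u + v
        if config.fixed_sigma2_e is None:
            ss = ((y - eta) ** 2).sum()
            s2e = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + ss / 2.0))

        if it >= config.burn_in and (it - config.burn_in + 1) % config.thin == 0:
            ll = (-0.5 * (_LOG_2PI + np.log(s2e)) - (y - eta) ** 2 / (2 * s2e)).sum()
            out["beta0"][kidx] = beta_all[0]
            out["beta"][kidx] = beta_all[1:]
            if use_u:
                out["u"][kidx] = u
                if out["tau_u"] is not None:
                    out["tau_u"][kidx] = tau_u
            if use_v:
                out["v"][kidx] = v
                if out["tau_v"] is not None:
                    out["tau_v"][kidx] = tau_v
            if out["sigma2_e"] is not None:
                out["sigma2_e"][kidx] = s2e
            out["deviance"][kidx] = -2.0 * ll
            kidx += 1
    out["acceptance"] = {}
    return out


def fit_bym(
    outcomes: OutcomeTable,
    X: Optional[np.ndarray] = None,
    adj: Optional[AdjacencyMatrix] = None,
    config: Optional[BYMConfig] = None,
    covariate_names: Optional[Sequence[str]] = None,
) -> PosteriorDraws:
    """Run ``config.n_chains`` independent chains of the BYM sampler.

    Chain ``c`` uses seed ``config.seed + c * 10007``.  Covariates should
    be standardized (a warning is issued if any column sd is wildly off
    1).  Raises on all-zero observed counts and on divergent chains.
    """
    config = config or BYMConfig()
    if X is None:
        X = np.zeros((outcomes.n, 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != outcomes.n:
        raise ValueError("covariate rows != number of areas")
    if outcomes.observed.sum() == 0:
        raise ValueError("all observed counts are zero; nothing to fit")
    if config.include_structured:
        if adj is None:
            raise ValueError("structured component requested but no adjacency given")
        adj.require_connected()
    if not (config.include_structured or config.include_unstructured or X.shape[1]):
        raise ValueError("model has neither random effects nor covariates")
    if X.shape[1]:
        sds = X.std(axis=0)
        if (sds > 10).any() or ((sds > 0) & (sds < 0.1)).any():
            import warnings

            warnings.warn(
                "covariate scales far from 1; consider standardizing", stacklevel=2
            )

    O, E = outcomes.observed, outcomes.expected
    chains = []
    for c in range(config.n_chains):
        seed = config.seed + c * 10007
        if config.likelihood == "poisson":
            chains.append(_run_chain_poisson(O, E, X, adj, config, seed))
        else:
            y = _lognormal_response(outcomes, config.lognormal_zero_correction)
            chains.append(_run_chain_lognormal(O, E, X, adj, config, seed, y))

    def stack(key):
        if chains[0].get(key) is None:
            return None
        return np.stack([ch[key] for ch in chains])

    draws = PosteriorDraws(
        beta0=stack("beta0"),
        beta=stack("beta"),
        u=stack("u"),
        v=stack("v"),
        tau_u=stack("tau_u"),
        tau_v=stack("tau_v"),
        sigma2_e=stack("sigma2_e"),
        deviance=stack("deviance"),
        config=config,
        covariate_names=list(covariate_names or [f"beta[{j}]" for j in range(X.shape[1])]),
        acceptance={f"chain{c}": ch["acceptance"] for c, ch in enumerate(chains)},
    )
    if not np.isfinite(draws.deviance).all():
        raise FloatingPointError("divergent chain: non-finite deviance")
    return draws


def dic(
    draws: PosteriorDraws,
    outcomes: OutcomeTable,
    X: Optional[np.ndarray] = None,
    kind: Optional[str] = None,
) -> ModelFit:
    """Deviance information criterion from stored draws.

    ``dbar`` is the mean stored deviance pooled over chains; ``d_hat``
    is the deviance at the posterior means of every parameter (random
    effects included); ``pD = dbar - d_hat`` and ``DIC = dbar + pD``.
    """
    if draws.n_chains * draws.n_kept < 100:
        raise ValueError("need at least 100 kept iterations for DIC")
    kind = kind or draws.config.likelihood
    if X is None:
        X = np.zeros((outcomes.n, draws.beta.shape[2]))
    dbar = float(draws.deviance.mean())
    state = draws.posterior_mean_state()
    d_hat = -2.0 * log_likelihood(
        state, outcomes, X, kind, draws.config.lognormal_zero_correction
    )
    if not np.isfinite(d_hat):
        raise FloatingPointError("non-finite plug-in deviance")
    return ModelFit(dbar=dbar, d_hat=float(d_hat))


def gelman_rubin(draws: PosteriorDraws | np.ndarray, parameter: str | None = None) -> float:
    """Potential scale reduction factor (between/within chain variances)."""
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise ValueError("parameter name required")
        x = draws.parameter(parameter)
    else:
        x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains")
    m, s = x.shape
    chain_means = x.mean(axis=1)
    within = x.var(axis=1, ddof=1).mean()
    between = s * chain_means.var(ddof=1)
    var_plus = (s - 1) / s * within + between / s
    if within == 0:
        return 1.0
    return float(np.sqrt(var_plus / within))


def mc_error(values: np.ndarray, n_batches: int = 50) -> float:
    """Batch-means Monte Carlo standard error (WinBUGS convention)."""
    x = np.asarray(values, dtype=float).reshape(-1)
    if len(x) < n_batches or len(x) < 20:
        raise ValueError(f"chain too short for {n_batches} batches")
    batch = len(x) // n_batches
    trimmed = x[: batch * n_batches].reshape(n_batches, batch)
    means = trimmed.mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def _summary_row(x: np.ndarray) -> dict:
    q = np.quantile(x, [0.025, 0.5, 0.975])
    return {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)),
        "mc_error": mc_error(x),
        "q2.5": float(q[0]),
        "median": float(q[1]),
        "q97.5": float(q[2]),
    }


def summarize_posterior(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior summary table (coefficient scale + odds-ratio scale).

    Odds-ratio quantile columns are exact exponentials of the
    coefficient quantiles; OR mean/sd/MC error are computed on the
    exp-transformed draws.  ``significant`` marks coefficients whose 95%
    interval excludes zero.
    """
    rows = []
    names = ["intercept"] + list(draws.covariate_names)
    arrays = [draws.pooled("beta0")] + [
        draws.beta[:, :, j].reshape(-1) for j in range(draws.beta.shape[2])
    ]
    for name, x in zip(names, arrays):
        row = {"parameter": name, "scale": "coefficient", **_summary_row(x)}
        row["significant"] = bool(row["q2.5"] > 0 or row["q97.5"] < 0)
        rows.append(row)
    for name, x in zip(names, arrays):
        e = np.exp(x)
        r = _summary_row(e)
        cq = np.quantile(x, [0.025, 0.5, 0.975])
        r["q2.5"], r["median"], r["q97.5"] = map(float, np.exp(cq))
        rows.append({"parameter": f"OR.{name}", "scale": "odds_ratio", **r,
                     "significant": bool(cq[0] > 0 or cq[2] < 0)})
    for extra in ("tau_u", "tau_v", "sigma2_e"):
        arr = getattr(draws, extra)
        if arr is not None:
            rows.append({"parameter": extra, "scale": "precision",
                         **_summary_row(arr.reshape(-1)), "significant": False})
    return pd.DataFrame(rows)
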