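"""Model comparison: deviance/DIC from the chains, one-step forecasts, MSE.

The deviance is the conditional (observation-layer) deviance given the latent
shocks, ``D(y, theta) = -2 log L(y | theta)``. DIC decomposes as
``DIC = D_bar + p_D`` with ``p_D = D_bar - D_hat``: ``D_bar`` is the average
deviance over the stored draws and ``D_hat`` the deviance at the posterior
mean of parameters and latent path (log-scale means for variances).

Forecast accuracy uses cross-validation: fit on the first ``n`` points, then
for each held-out ``t`` form the one-step posterior predictive distribution
of ``y_t`` given the *observed* ``y_{t-1}`` (sufficient under the first-order
Markov structure), and score the predictive mean by mean squared error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from ._kernel import LOG2PI
from .inference import PosteriorChains, ThetaLatent, conditional_means, log_likelihood
from .types import Model, PopulationSeries

_SEED_MASK = 0x7FFFFFFF


@dataclass(frozen=True)
class PredictionConfig:
    """Train/test split for one-step-ahead cross-validation."""

    N: int
    n: int

    def __post_init__(self) -> None:
        if not 2 <= self.n < self.N:
            raise ValueError(f"need 2 <= n < N, got n={self.n}, N={self.N}")

    @property
    def s(self) -> int:
        return self.N - self.n

    @classmethod
    def default_split(cls, N: int, n_train: int = 90) -> "PredictionConfig":
        """The default split for T = 100 series: first 90 fit, last 10 scored."""
        return cls(N=N, n=min(n_train, N - 1))


def deviance(series: PopulationSeries, point: ThetaLatent, model: Model) -> float:
    """``D(y, theta) = -2 log L(y | theta)`` at one parameter-latent point."""
    return -2.0 * log_likelihood(series, point, model)


def _deviance_draws(chains: PosteriorChains, series: PopulationSeries) -> np.ndarray:
    """Conditional deviance at every stored draw, vectorized over draws."""
    y = series.values
    if len(y) != chains.T:
        raise ValueError(f"series length {len(y)} != fitted length {chains.T}")
    yprev, yobs = y[:-1], y[1:]

    sc = {k: chains.flat(v) for k, v in chains.scalars().items()}
    r = sc["r"][:, None]
    s_obs = np.sqrt(sc["sigma2_obs"])[:, None]
    Kt = chains.latent("K_t")
    Kt = chains.flat(Kt)
    eps = chains.latent("eps")
    eps = chains.flat(eps) if eps is not None else 0.0

    g = r * (1.0 - yprev[None, :] / Kt) + eps
    mu = yprev[None, :] * np.exp(g)
    z = (yobs[None, :] - mu) / s_obs
    ll = -0.5 * z * z - np.log(s_obs) - 0.5 * LOG2PI - np.log(ndtr(mu / s_obs))
    return -2.0 * ll.sum(axis=1)


def dic_decomposition(d_draws: np.ndarray, d_hat: float) -> dict[str, float]:
    """Assemble (D_bar, D_hat, p_D, DIC) and assert the defining identities."""
    d_bar = float(np.mean(d_draws))
    p_d = d_bar - d_hat
    out = {"d_bar": d_bar, "d_hat": float(d_hat), "p_d": p_d, "dic": d_bar + p_d}
    assert out["p_d"] == out["d_bar"] - out["d_hat"]
    assert out["dic"] == out["d_bar"] + out["p_d"]
    return out


def dic(chains: PosteriorChains, series: PopulationSeries, model: Model) -> dict[str, float]:
    """DIC decomposition from the stored draws of one fit."""
    if chains.n_draws < 100:
        raise ValueError("need >= 100 stored draws for a stable DIC")
    if model is not chains.model:
        raise ValueError("model id does not match the fitted chains")
    d_draws = _deviance_draws(chains, series)
    point = chains.posterior_mean_point()
    d_hat = deviance(series, point, model)
    if not np.isfinite(d_hat):
        raise FloatingPointError(
            "non-finite deviance at the posterior mean; variance means are "
            "taken on the log scale, check the chains for divergence"
        )
    return dic_decomposition(d_draws, d_hat)


# ---------------------------------------------------------------------------
# one-step-ahead posterior predictive


def _sample_truncnorm(mu: np.ndarray, sigma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draws from Normal(mu, sigma^2) truncated to (0, inf), elementwise.

    Degenerate sigma = 0 collapses to the location (the zero-noise limit).
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), mu.shape)
    out = mu.copy()
    live = sigma > 0
    if np.any(live):
        lo = ndtr(-mu[live] / sigma[live])
        u = rng.uniform(0.0, 1.0, size=live.sum())
        out[live] = mu[live] + sigma[live] * ndtri(lo + u * (1.0 - lo))
    return out


def one_step_predict(
    chains: PosteriorChains,
    y_prev: float,
    model: Model,
    seed: int,
) -> np.ndarray:
    """Posterior predictive draws of the next abundance given ``y_prev``.

    For every stored posterior draw: fresh shocks are drawn from their fitted
    distributions (never reused from the training latents), the conditional
    mean is formed, and one truncated-normal observation is sampled.
    """
    if y_prev <= 0:
        raise ValueError("y_prev must be > 0")
    rng = np.random.default_rng(seed)
    sc = {k: chains.flat(v) for k, v in chains.scalars().items()}
    n = len(sc["r"])
    r = sc["r"]

    eps = np.zeros(n)
    if model.has_eps:
        eps = rng.normal(0.0, 1.0, n) * np.sqrt(sc["sigma2_r"])

    if not model.has_eta:
        K = sc["K"]
    elif chains.kt_prior == "hierarchical":
        eta = rng.normal(0.0, 1.0, n) * np.sqrt(sc["sigma2_k"])
        K = np.exp(sc["k"] + eta)
    else:
        # literal iid prior: future K_t is a fresh InvGamma(u, v) variate
        pr = chains.priors
        K = pr.K_scale / rng.gamma(pr.K_shape, 1.0, n)

    mu = y_prev * np.exp(r * (1.0 - y_prev / K) + eps)
    sigma = np.sqrt(sc["sigma2_obs"])
    draws = _sample_truncnorm(mu, sigma, rng)
    if np.any(draws <= 0):
        raise FloatingPointError("non-positive predictive draw")
    return draws


def predict_heldout(
    series: PopulationSeries,
    chains: PosteriorChains,
    pred: PredictionConfig,
    model: Model,
    seed: int,
) -> pd.DataFrame:
    """One-step predictive summaries for every held-out time point.

    Each row predicts y_t from the observed y_{t-1} using chains fitted on
    the first ``n`` points only.
    """
    if pred.N != len(series):
        raise ValueError(f"pred.N={pred.N} != series length {len(series)}")
    if chains.T != pred.n:
        raise ValueError(
            f"chains were fitted on {chains.T} points but the split trains on {pred.n}"
        )
    ss = np.random.SeedSequence(seed)
    rows = []
    for child, i in zip(ss.spawn(pred.s), range(pred.n, pred.N)):
        draws = one_step_predict(
            chains, float(series.values[i - 1]), model,
            int(child.generate_state(1)[0]) & _SEED_MASK,
        )
        lo, hi = np.percentile(draws, [2.5, 97.5])
        rows.append(
            {
                "time": int(series.times[i]),
                "y_obs": float(series.values[i]),
                "pred_mean": float(np.mean(draws)),
                "lo95": float(lo),
                "hi95": float(hi),
            }
        )
    return pd.DataFrame(rows)


def mse(
    series: PopulationSeries,
    chains: PosteriorChains,
    pred: PredictionConfig,
    model: Model,
    seed: int,
) -> float:
    """Mean squared one-step prediction error over the held-out tail."""
    table = predict_heldout(series, chains, pred, model, seed)
    return float(np.mean((table["pred_mean"] - table["y_obs"]) ** 2))


# ---------------------------------------------------------------------------
# bundled result


@dataclass
class FitResult:
    """DIC decomposition plus held-out forecasts for one (series, model) fit."""

    model: Model
    d_bar: float
    d_hat: float
    p_d: float
    dic: float
    mse: float
    predictions: pd.DataFrame
    split: PredictionConfig
    rhat_max: float | None = None
    converged: bool | None = None

    def __post_init__(self) -> None:
        assert self.p_d == self.d_bar - self.d_hat
        assert self.dic == self.d_bar + self.p_d
        if self.mse < 0:
            raise ValueError("MSE cannot be negative")

    def to_json(self, path) -> None:
        payload = {
            "model": self.model.value,
            "d_bar": self.d_bar,
            "d_hat": self.d_hat,
            "p_d": self.p_d,
            "dic": self.dic,
            "mse": self.mse,
            "split": {"N": self.split.N, "n": self.split.n, "s": self.split.s},
            "rhat_max": self.rhat_max,
            "converged": self.converged,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def fit_and_score(
    series: PopulationSeries,
    model: Model,
    priors=None,
    mcmc=None,
    pred: PredictionConfig | None = None,
    predict_seed: int = 0,
    rhat_max: float = 1.1,
    ess_min: float = 200.0,
) -> FitResult:
    """Fit one model to the training window and score fit and forecasts."""
    from .inference import check_convergence, sample_posterior

    pred = pred or PredictionConfig.default_split(len(series))
    train = series.head(pred.n)
    chains = sample_posterior(train, model, priors=priors, mcmc=mcmc)
    parts = dic(chains, train, model)
    table = predict_heldout(series, chains, pred, model, predict_seed)
    mse_val = float(np.mean((table["pred_mean"] - table["y_obs"]) ** 2))
    report = check_convergence(chains, rhat_max=rhat_max, ess_min=ess_min)
    return FitResult(
        model=model,
        d_bar=parts["d_bar"],
        d_hat=parts["d_hat"],
        p_d=parts["p_d"],
        dic=parts["dic"],
        mse=mse_val,
        predictions=table,
        split=pred,
        rhat_max=report.worst_rhat,
        converged=report.passed,
    )
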