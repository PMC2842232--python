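"""Bayesian fitting of the stochastic Ricker models by MCMC.

Likelihood: for t = 2..T, ``y_t ~ Normal(mu_t, sigma_obs^2)`` truncated to
``(0, inf)``, with the conditional mean built per model variant::

    M1: mu_t = y_{t-1} exp{r (1 - y_{t-1}/K)   + eps_t}
    M2: mu_t = y_{t-1} exp{r (1 - y_{t-1}/K_t)}
    M3: mu_t = y_{t-1} exp{r (1 - y_{t-1}/K_t) + eps_t}

Priors: r has a normal prior truncated to positive values; carrying-capacity
quantities get inverse-gamma (static K) or a hierarchical log-normal
(``K_t = exp(k + eta_t)``, the default) with the literal iid inverse-gamma
prior on each K_t available via ``kt_prior="iid-invgamma"``; every variance
gets InvGamma(1, 1).

The sampler is adaptive random-walk Metropolis within a fixed block scan
(each scalar its own block, latent paths in blocks of 10), with proposal
scales tuned during burn-in only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from . import _kernel
from .types import Model, PopulationSeries

_SEED_MASK = 0x7FFFFFFF

HIERARCHICAL = "hierarchical"
IID_INVGAMMA = "iid-invgamma"


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of every prior in the model."""

    r_loc: float = 0.0
    r_scale: float = 10.0
    k_loc: float = 0.0
    k_scale: float = 10.0
    K_shape: float = 1.0
    K_scale: float = 1.0
    var_shape: float = 1.0
    var_scale: float = 1.0
    kt_prior: str = HIERARCHICAL

    def __post_init__(self) -> None:
        for name in ("r_scale", "k_scale", "K_shape", "K_scale", "var_shape", "var_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.kt_prior not in (HIERARCHICAL, IID_INVGAMMA):
            raise ValueError(f"kt_prior must be {HIERARCHICAL!r} or {IID_INVGAMMA!r}")

    def as_vector(self) -> np.ndarray:
        return np.array(
            [
                self.r_loc, self.r_scale,
                self.k_loc, self.k_scale,
                self.K_shape, self.K_scale,
                self.var_shape, self.var_scale,
                0.0, 0.0, 1.0,  # toy slots, unused here
            ]
        )

    def r_prior(self):
        """The truncated-normal prior on r as a frozen scipy distribution."""
        a = (0.0 - self.r_loc) / self.r_scale
        return stats.truncnorm(a, np.inf, loc=self.r_loc, scale=self.r_scale)


@dataclass(frozen=True)
class McmcConfig:
    """Chain-length and adaptation settings.

    Defaults mirror the published analysis: 3 chains, 4000 burn-in
    iterations, 16000 further iterations thinned to every 20th draw
    (2400 stored draws in total).
    """

    n_chains: int = 3
    burn_in: int = 4000
    n_iter: int = 16000
    thin: int = 20
    seed: int = 0
    latent_block: int = 10
    target_accept_scalar: float = 0.44
    target_accept_block: float = 0.25

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.thin < 1 or self.n_iter % self.thin != 0:
            raise ValueError("n_iter must be a positive multiple of thin")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")

    @property
    def n_stored(self) -> int:
        return self.n_chains * (self.n_iter // self.thin)


@dataclass
class ThetaLatent:
    """One parameter-and-latent point at which the likelihood can be evaluated."""

    r: float
    sigma2_obs: float
    K: float | None = None
    k: float | None = None
    sigma2_r: float | None = None
    sigma2_k: float | None = None
    eps: np.ndarray | None = None   # length T-1, shock into t=2..T
    eta: np.ndarray | None = None   # length T-1
    K_t: np.ndarray | None = None   # length T-1, overrides K/k+eta when given

    def carrying_capacities(self, L: int) -> np.ndarray:
        """Per-transition carrying capacity K_t for t = 2..T."""
        if self.K_t is not None:
            K_t = np.asarray(self.K_t, dtype=float)
        elif self.eta is not None:
            if self.k is None:
                raise ValueError("eta given without k")
            K_t = np.exp(self.k + np.asarray(self.eta, dtype=float))
        elif self.K is not None:
            K_t = np.full(L, float(self.K))
        elif self.k is not None:
            K_t = np.full(L, np.exp(self.k))
        else:
            raise ValueError("no carrying-capacity information in point")
        if len(K_t) != L:
            raise ValueError(f"expected {L} carrying capacities, got {len(K_t)}")
        return K_t


def conditional_means(series: PopulationSeries, point: ThetaLatent, model: Model) -> np.ndarray:
    """mu_t for t = 2..T given parameters and latent shocks."""
    y = series.values
    L = len(y) - 1
    K_t = point.carrying_capacities(L)
    eps = np.zeros(L)
    if model.has_eps:
        if point.eps is None:
            raise ValueError(f"{model.value} needs an eps path")
        eps = np.asarray(point.eps, dtype=float)
        if len(eps) != L:
            raise ValueError(f"expected {L} eps shocks, got {len(eps)}")
    g = point.r * (1.0 - y[:-1] / K_t) + eps
    mu = y[:-1] * np.exp(g)
    if not np.all(np.isfinite(mu)):
        t_bad = int(np.flatnonzero(~np.isfinite(mu))[0]) + 2
        raise FloatingPointError(f"non-finite conditional mean at t={t_bad}")
    return mu


def truncnorm_logpdf(x, mu, sigma) -> np.ndarray:
    """Log density of Normal(mu, sigma^2) truncated to (0, inf), elementwise."""
    z = (x - mu) / sigma
    return (
        -0.5 * z * z
        - np.log(sigma)
        - 0.5 * _kernel.LOG2PI
        - np.log(ndtr(mu / sigma))
    )


def log_likelihood(series: PopulationSeries, point: ThetaLatent, model: Model) -> float:
    """Truncated-normal log likelihood summed over t = 2..T."""
    if point.sigma2_obs is None or point.sigma2_obs <= 0:
        raise ValueError("sigma2_obs must be > 0")
    mu = conditional_means(series, point, model)
    sigma = np.sqrt(point.sigma2_obs)
    return float(np.sum(truncnorm_logpdf(series.values[1:], mu, sigma)))


def log_prior(
    point: ThetaLatent, priors: PriorSpec, model: Model, T: int | None = None
) -> float:
    """Joint log prior density at a natural-scale point (-inf off support)."""
    if point.r <= 0:
        return -np.inf
    lp = float(priors.r_prior().logpdf(point.r))

    ig = stats.invgamma
    if point.sigma2_obs is None or point.sigma2_obs <= 0:
        return -np.inf
    lp += float(ig.logpdf(point.sigma2_obs, priors.var_shape, scale=priors.var_scale))

    if model is Model.M1:
        if point.K is None or point.K <= 0 or point.sigma2_r is None or point.sigma2_r <= 0:
            return -np.inf
        lp += float(ig.logpdf(point.K, priors.K_shape, scale=priors.K_scale))
        lp += float(ig.logpdf(point.sigma2_r, priors.var_shape, scale=priors.var_scale))
        lp += float(np.sum(stats.norm.logpdf(point.eps, 0.0, np.sqrt(point.sigma2_r))))
        return lp

    if model.has_eps:
        if point.sigma2_r is None or point.sigma2_r <= 0:
            return -np.inf
        lp += float(ig.logpdf(point.sigma2_r, priors.var_shape, scale=priors.var_scale))
        lp += float(np.sum(stats.norm.logpdf(point.eps, 0.0, np.sqrt(point.sigma2_r))))

    if priors.kt_prior == IID_INVGAMMA:
        if point.K_t is None or np.any(np.asarray(point.K_t) <= 0):
            return -np.inf
        lp += float(np.sum(ig.logpdf(point.K_t, priors.K_shape, scale=priors.K_scale)))
    else:
        if point.k is None or point.sigma2_k is None or point.sigma2_k <= 0:
            return -np.inf
        lp += float(stats.norm.logpdf(point.k, priors.k_loc, priors.k_scale))
        lp += float(ig.logpdf(point.sigma2_k, priors.var_shape, scale=priors.var_scale))
        lp += float(np.sum(stats.norm.logpdf(point.eta, 0.0, np.sqrt(point.sigma2_k))))
    return lp


# ---------------------------------------------------------------------------
# sampler plumbing: z-vector layouts per model code


def _model_code(model: Model, kt_prior: str) -> int:
    if model is Model.M1:
        return _kernel.M1
    if model is Model.M2:
        return _kernel.M2H if kt_prior == HIERARCHICAL else _kernel.M2IID
    return _kernel.M3H if kt_prior == HIERARCHICAL else _kernel.M3IID


def _layout(code: int, L: int) -> tuple[list[str], list[tuple[int, int]]]:
    """Names of the z entries and (start, length) of each latent segment."""
    if code == _kernel.M1:
        scalars = ["log_r", "log_K", "log_sigma2_r", "log_sigma2_obs"]
        segs = [("u_eps", 4)]
    elif code == _kernel.M2H:
        scalars = ["log_r", "k", "log_sigma2_k", "log_sigma2_obs"]
        segs = [("u_eta", 4)]
    elif code == _kernel.M3H:
        scalars = ["log_r", "k", "log_sigma2_r", "log_sigma2_k", "log_sigma2_obs"]
        segs = [("u_eps", 5), ("u_eta", 5 + L)]
    elif code == _kernel.M2IID:
        scalars = ["log_r", "log_sigma2_obs"]
        segs = [("log_K_t", 2)]
    elif code == _kernel.M3IID:
        scalars = ["log_r", "log_sigma2_r", "log_sigma2_obs"]
        segs = [("u_eps", 3), ("log_K_t", 3 + L)]
    else:
        raise ValueError(f"unknown model code {code}")
    names = list(scalars)
    for seg_name, _start in segs:
        names += [f"{seg_name}[{j + 2}]" for j in range(L)]
    return names, [(s, L) for _, s in segs]


_N_SCALAR = {_kernel.M1: 4, _kernel.M2H: 4, _kernel.M3H: 5,
             _kernel.M2IID: 2, _kernel.M3IID: 3}


def _blocks(code: int, L: int, latent_block: int, t_scalar: float, t_block: float):
    n_scalar = _N_SCALAR[code]
    starts, sizes, targets, steps, modes = [], [], [], [], []
    for i in range(n_scalar):
        starts.append(i)
        sizes.append(1)
        targets.append(t_scalar)
        steps.append(0.2)
        modes.append(0)
    _, segs = _layout(code, L)
    for s0, seg_len in segs:
        j = 0
        while j < seg_len:
            w = min(latent_block, seg_len - j)
            starts.append(s0 + j)
            sizes.append(w)
            targets.append(t_scalar if w == 1 else t_block)
            steps.append(0.1)
            modes.append(0)
            j += w
        # whole-segment shift block: moves the path against r/k along the ridge
        starts.append(s0)
        sizes.append(seg_len)
        targets.append(t_scalar)
        steps.append(0.1)
        modes.append(1)
    return (
        np.asarray(starts, dtype=np.int64),
        np.asarray(sizes, dtype=np.int64),
        np.asarray(targets, dtype=np.float64),
        np.asarray(steps, dtype=np.float64),
        np.asarray(modes, dtype=np.int64),
    )


def _initial_point(code: int, L: int, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Dispersed starting values: data-informed centers, overdispersed jitter."""
    log_mean_y = np.log(np.mean(y))
    z0 = {"log_r": rng.normal(0.0, 1.0)}
    z0["log_K"] = log_mean_y + rng.normal(0.0, 0.5)
    z0["k"] = log_mean_y + rng.normal(0.0, 0.5)
    for v in ("log_sigma2_r", "log_sigma2_k"):
        z0[v] = rng.normal(np.log(0.05), 1.0)
    z0["log_sigma2_obs"] = rng.normal(np.log(max(np.var(y), 1e-4) / 4.0), 1.0)
    names, segs = _layout(code, L)
    n_scalar = len(names) - sum(L for _ in segs)
    out = np.empty(len(names))
    for i in range(n_scalar):
        out[i] = z0[names[i]]
    for seg_idx, (s0, seg_len) in enumerate(segs):
        seg_name = names[s0].split("[")[0]
        if seg_name == "log_K_t":
            out[s0 : s0 + seg_len] = log_mean_y + rng.normal(0.0, 0.3, seg_len)
        else:
            out[s0 : s0 + seg_len] = rng.normal(0.0, 0.01, seg_len)
    return out


@dataclass
class PosteriorChains:
    """Thinned post-burn-in MCMC draws from one model fit to one series."""

    model: Model
    kt_prior: str
    names: list[str]
    draws: np.ndarray          # (n_chains, n_kept, dim), unconstrained scale
    T: int
    priors: PriorSpec
    mcmc: McmcConfig
    accept_rates: np.ndarray   # (n_chains, n_blocks)

    def __post_init__(self) -> None:
        # -inf is a legal stored value (a log-scale exact zero); NaN/+inf never
        if np.any(np.isnan(self.draws)) or np.any(self.draws == np.inf):
            raise FloatingPointError("NaN or +inf draw stored")
        self._idx = {n: i for i, n in enumerate(self.names)}

    @property
    def code(self) -> int:
        return _model_code(self.model, self.kt_prior)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    @property
    def L(self) -> int:
        return self.T - 1

    def col(self, name: str) -> np.ndarray:
        """Raw (unconstrained) draws of one z entry, shape (n_chains, n_kept)."""
        return self.draws[:, :, self._idx[name]]

    def _segment(self, seg: str) -> np.ndarray | None:
        first = f"{seg}[2]"
        if first not in self._idx:
            return None
        s0 = self._idx[first]
        return self.draws[:, :, s0 : s0 + self.L]

    def scalars(self) -> dict[str, np.ndarray]:
        """Natural-scale scalar parameter draws, shape (n_chains, n_kept)."""
        out: dict[str, np.ndarray] = {"r": np.exp(self.col("log_r"))}
        if "log_K" in self._idx:
            out["K"] = np.exp(self.col("log_K"))
        if "k" in self._idx:
            out["k"] = self.col("k")
            out["K"] = np.exp(self.col("k"))
        for raw, nat in (
            ("log_sigma2_r", "sigma2_r"),
            ("log_sigma2_k", "sigma2_k"),
            ("log_sigma2_obs", "sigma2_obs"),
        ):
            if raw in self._idx:
                out[nat] = np.exp(self.col(raw))
        return out

    def latent(self, seg: str) -> np.ndarray | None:
        """Natural-scale latent draws (n_chains, n_kept, T-1); None if absent.

        Shocks are stored standardized (non-centered); this rescales them by
        the per-draw SD: ``eps = sigma_r u`` and ``eta = sigma_k u``.
        """
        if seg == "eps":
            u = self._segment("u_eps")
            if u is None:
                return None
            return u * np.sqrt(np.exp(self.col("log_sigma2_r")))[:, :, None]
        if seg == "eta":
            u = self._segment("u_eta")
            if u is None:
                return None
            return u * np.sqrt(np.exp(self.col("log_sigma2_k")))[:, :, None]
        if seg == "K_t":
            raw = self._segment("log_K_t")
            if raw is not None:
                return np.exp(raw)
            eta = self.latent("eta")
            if eta is not None:
                return np.exp(self.col("k")[:, :, None] + eta)
            if "log_K" in self._idx:
                return np.exp(self.col("log_K"))[:, :, None] * np.ones(self.L)
            return None
        raise ValueError(f"unknown latent segment {seg!r}")

    def flat(self, arr: np.ndarray) -> np.ndarray:
        """Collapse the chain axis: (n_chains, n_kept, ...) -> (n_total, ...)."""
        return arr.reshape(-1, *arr.shape[2:])

    def posterior_mean_point(self) -> ThetaLatent:
        """Plug-in point for the deviance at the posterior mean.

        Means are taken on the log scale for variance parameters and for
        carrying-capacity quantities (both posteriors are heavy-tailed to the
        right, where an arithmetic mean can land far outside the high-density
        region) and on the natural scale for r and the latent shocks.
        """
        def mean_of(name):
            return float(np.mean(self.col(name))) if name in self._idx else None

        point = ThetaLatent(
            r=float(np.mean(np.exp(self.col("log_r")))),
            sigma2_obs=float(np.exp(np.mean(self.col("log_sigma2_obs")))),
        )
        if "log_K" in self._idx:
            point.K = float(np.exp(np.mean(self.col("log_K"))))
        point.k = mean_of("k")
        if "log_sigma2_r" in self._idx:
            point.sigma2_r = float(np.exp(np.mean(self.col("log_sigma2_r"))))
        if "log_sigma2_k" in self._idx:
            point.sigma2_k = float(np.exp(np.mean(self.col("log_sigma2_k"))))
        eps = self.latent("eps")
        if eps is not None:
            point.eps = np.mean(eps, axis=(0, 1))
        eta = self.latent("eta")
        if eta is not None:
            point.eta = np.mean(eta, axis=(0, 1))
        logKt = self._segment("log_K_t")
        if logKt is not None:
            point.K_t = np.exp(np.mean(logKt, axis=(0, 1)))
        return point

    def save(self, out_dir) -> None:
        """Write the scalar chains (long CSV) plus a JSON sidecar.

        The sidecar records the model id, prior reading, MCMC settings and
        the split-R-hat / ESS table, so a fit can be audited without rerun.
        """
        import json
        from dataclasses import asdict
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out_dir / "chains.csv", index=False)
        report = check_convergence(self, ess_min=0)
        sidecar = {
            "model": self.model.value,
            "kt_prior": self.kt_prior,
            "series_length": self.T,
            "mcmc": asdict(self.mcmc),
            "priors": asdict(self.priors),
            "diagnostics": report.table.to_dict(orient="records"),
            "mean_accept_rates": np.nanmean(self.accept_rates, axis=0).tolist(),
        }
        with open(out_dir / "chains.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (chain, iteration, parameter, value) table of scalars."""
        rows = []
        for name, arr in self.scalars().items():
            nc, nk = arr.shape
            rows.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(nc), nk),
                        "iteration": np.tile(np.arange(nk), nc),
                        "parameter": name,
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def sample_posterior(
    series: PopulationSeries,
    model: Model,
    priors: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    likelihood_scale: float = 1.0,
) -> PosteriorChains:
    """Draw from the joint posterior of parameters and latent shocks.

    ``likelihood_scale`` tempers the likelihood (0 targets the prior alone);
    it exists for sampler-calibration diagnostics, not for analysis.
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or McmcConfig()
    y = np.asarray(series.values, dtype=float)
    T = len(y)
    L = T - 1
    code = _model_code(model, priors.kt_prior)
    names, _ = _layout(code, L)
    starts, sizes, targets, steps, modes = _blocks(
        code, L, mcmc.latent_block, mcmc.target_accept_scalar, mcmc.target_accept_block
    )
    pv = priors.as_vector()
    n_scalar = _N_SCALAR[code]

    ss = np.random.SeedSequence(mcmc.seed)
    children = ss.spawn(mcmc.n_chains)
    n_kept = mcmc.n_iter // mcmc.thin
    draws = np.empty((mcmc.n_chains, n_kept, len(names)))
    rates = np.empty((mcmc.n_chains, len(starts) + 1))
    for c, child in enumerate(children):
        init_rng = np.random.default_rng(child)
        z0 = _initial_point(code, L, y, init_rng)
        kernel_seed = int(child.generate_state(1)[0]) & _SEED_MASK
        d, rt = _kernel.run_chain(
            y, code, pv, float(likelihood_scale), z0,
            starts, sizes, targets, steps, modes, n_scalar,
            mcmc.burn_in, mcmc.n_iter, mcmc.thin, kernel_seed,
        )
        draws[c] = d
        rates[c] = rt
        if np.all(np.nan_to_num(rt) < 0.005):
            raise RuntimeError(
                f"sampler diverged in chain {c}: acceptance collapsed to zero "
                f"after adaptation; last state {d[-1][: min(8, d.shape[1])]}"
            )
    return PosteriorChains(
        model=model, kt_prior=priors.kt_prior, names=names, draws=draws,
        T=T, priors=priors, mcmc=mcmc, accept_rates=rates,
    )


# ---------------------------------------------------------------------------
# convergence diagnostics


@dataclass
class ConvergenceReport:
    """Split-R-hat and effective sample size per monitored scalar."""

    table: pd.DataFrame
    rhat_max: float
    ess_min: float

    @property
    def passed(self) -> bool:
        return bool(self.table["ok"].all())

    @property
    def worst_rhat(self) -> float:
        return float(np.nanmax(self.table["rhat"]))


def check_convergence(
    chains: PosteriorChains | dict[str, np.ndarray],
    rhat_max: float = 1.1,
    ess_min: float = 200.0,
) -> ConvergenceReport:
    """Quantitative convergence gate on the scalar parameters.

    Accepts fitted chains or a bare mapping of name -> (n_chains, n_draws)
    arrays. Constant (zero-variance) chains are flagged as degenerate.
    """
    import arviz as az

    scalars = chains.scalars() if isinstance(chains, PosteriorChains) else dict(chains)
    first = next(iter(scalars.values()))
    if first.shape[0] < 2:
        raise ValueError("R-hat needs at least 2 chains")
    rows = []
    for name, arr in scalars.items():
        if np.allclose(arr, arr.ravel()[0]):
            rows.append({"parameter": name, "rhat": np.nan, "ess": np.nan, "ok": False,
                         "note": "degenerate (zero variance)"})
            continue
        ds = az.convert_to_dataset(arr)
        rhat = float(az.rhat(ds)["x"])
        ess = float(az.ess(ds)["x"])
        ok = bool(rhat <= rhat_max and (ess_min <= 0 or ess >= ess_min))
        rows.append({"parameter": name, "rhat": rhat, "ess": ess, "ok": ok, "note": ""})
    return ConvergenceReport(pd.DataFrame(rows), rhat_max, ess_min)


# ---------------------------------------------------------------------------
# conjugate toy exposed through the same sampler machinery


def sample_conjugate_normal_mean(
    y,
    lik_sd: float,
    prior_mean: float,
    prior_sd: float,
    mcmc: McmcConfig | None = None,
) -> np.ndarray:
    """Posterior draws of a normal mean with known SD via the shared kernel.

    A calibration target: the exact posterior is
    ``N((y_bar n/s^2 + m0/tau^2)/(n/s^2 + 1/tau^2), 1/(n/s^2 + 1/tau^2))``.
    Returns draws flattened over chains.
    """
    mcmc = mcmc or McmcConfig(n_chains=2, burn_in=1000, n_iter=4000, thin=2)
    y = np.asarray(y, dtype=float)
    pv = np.zeros(11)
    pv[8], pv[9], pv[10] = lik_sd, prior_mean, prior_sd
    starts = np.array([0], dtype=np.int64)
    sizes = np.array([1], dtype=np.int64)
    targets = np.array([mcmc.target_accept_scalar])
    steps = np.array([0.5])
    modes = np.array([0], dtype=np.int64)
    ss = np.random.SeedSequence(mcmc.seed)
    out = []
    for child in ss.spawn(mcmc.n_chains):
        rng = np.random.default_rng(child)
        z0 = np.array([prior_mean + rng.normal(0.0, max(prior_sd, 1.0))])
        d, _ = _kernel.run_chain(
            y, _kernel.TOY, pv, 1.0, z0, starts, sizes, targets, steps, modes, 1,
            mcmc.burn_in, mcmc.n_iter, mcmc.thin,
            int(child.generate_state(1)[0]) & _SEED_MASK,
        )
        out.append(d[:, 0])
    return np.concatenate(out)
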