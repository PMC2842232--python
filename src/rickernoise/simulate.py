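"""Generate population time series under the three stochastic Ricker models.

Process noise only: growth-rate shocks ``eps_t ~ N(0, sigma_r^2)`` and/or
log-carrying-capacity shocks ``eta_t ~ N(0, sigma_k^2)`` are drawn iid across
time and applied inside the exponential update, so every simulated abundance
is strictly positive by construction. No observation layer is added during
generation; the truncated-normal residual term exists only in the fitting
likelihood.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .types import NOISE_PRESETS, R_GRID, Model, NoisePreset, PopulationSeries, RickerParams

#: mask to keep derived seeds in the non-negative 31-bit range
_SEED_MASK = 0x7FFFFFFF


@dataclass
class LatentPath:
    """Realized shocks behind one simulated series (index aligned with t=1..T).

    ``eps[0]`` and ``eta[0]`` are zero by convention: shocks act on the
    transitions into t = 2..T.
    """

    eps: np.ndarray
    eta: np.ndarray
    K_t: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(1, len(self.eps) + 1)
        return pd.DataFrame({"time": t, "eps": self.eps, "eta": self.eta, "K_t": self.K_t})


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one simulated series bit-for-bit."""

    model: Model
    params: RickerParams
    T: int = 100
    y0: float | None = None
    seed: int = 0
    noise_level: str | None = None  # bookkeeping for grid runs
    rep: int | None = None

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if self.y0 is not None and self.y0 <= 0:
            raise ValueError("y0 must be > 0")


def simulate_series(config: SimulationConfig) -> tuple[PopulationSeries, LatentPath]:
    """Simulate one series under the configured model.

    The initial abundance, when not given, is drawn once as ``K * U(0.5, 1.5)``
    so short series start near equilibrium rather than in a long transient.
    """
    p, model, T = config.params, config.model, config.T
    rng = np.random.default_rng(config.seed)
    y0 = p.K * rng.uniform(0.5, 1.5) if config.y0 is None else float(config.y0)

    eps = np.zeros(T)
    eta = np.zeros(T)
    if model.has_eps and p.sigma_r > 0:
        eps[1:] = rng.normal(0.0, p.sigma_r, T - 1)
    if model.has_eta and p.sigma_k > 0:
        eta[1:] = rng.normal(0.0, p.sigma_k, T - 1)
    K_t = np.exp(p.k + eta)

    y = np.empty(T)
    y[0] = y0
    for t in range(1, T):
        g = p.r * (1.0 - y[t - 1] / K_t[t]) + eps[t]
        y[t] = y[t - 1] * np.exp(g)
        if not np.isfinite(y[t]) or y[t] <= 0.0:
            raise FloatingPointError(
                f"non-finite abundance at t={t + 1}: y={y[t]!r} "
                f"(eps={eps[t]:.4g}, eta={eta[t]:.4g})"
            )
    series = PopulationSeries(np.arange(1, T + 1), y)
    return series, LatentPath(eps=eps, eta=eta, K_t=K_t)


def _child_seed(master_seed: int, spawn_key: tuple[int, ...]) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=spawn_key)
    return int(ss.generate_state(1)[0]) & _SEED_MASK


def make_grid(
    reps: int,
    seed: int,
    models: tuple[Model, ...] = (Model.M1, Model.M2, Model.M3),
    r_values: tuple[float, ...] = R_GRID,
    noise_levels: tuple[str, ...] = ("low", "moderate", "high"),
    T: int = 100,
    k: float = 1.0,
) -> list[SimulationConfig]:
    """Full factorial model x r x noise-level x replicate design.

    Child seeds are derived from the master seed through ``SeedSequence``
    spawn keys indexed by the cell coordinates, so a sub-grid run reproduces
    exactly the seeds the corresponding cells get in the full grid, and no
    global random state is consumed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    all_models = (Model.M1, Model.M2, Model.M3)
    all_r = R_GRID
    all_levels = ("low", "moderate", "high")
    configs = []
    for model, r, level, rep in itertools.product(models, r_values, noise_levels, range(reps)):
        sr, sk = NOISE_PRESETS[level]
        key = (
            all_models.index(model),
            all_r.index(r) if r in all_r else hash(round(r, 9)) & 0xFFFF,
            all_levels.index(level),
            rep,
        )
        configs.append(
            SimulationConfig(
                model=model,
                params=RickerParams(r=float(r), k=k, sigma_r=sr, sigma_k=sk),
                T=T,
                seed=_child_seed(seed, key),
                noise_level=level,
                rep=rep,
            )
        )
    return configs


def zero_noise(config: SimulationConfig) -> SimulationConfig:
    """The same configuration with both environmental noises switched off."""
    p = config.params
    return replace(config, params=replace(p, sigma_r=0.0, sigma_k=0.0))
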