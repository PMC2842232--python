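"""Shared domain types: model identifiers, parameters, series, noise presets.

The three model variants differ only in where environmental noise enters the
Ricker update:

* ``M1`` — log-normal multiplicative noise in the growth rate
  (``y_t = y_{t-1} exp{r(1 - y_{t-1}/K) + eps_t}``),
* ``M2`` — noise in the carrying capacity
  (``K_t = exp(k + eta_t)``, ``y_t = y_{t-1} exp{r(1 - y_{t-1}/K_t)}``),
* ``M3`` — both shocks applied in one step.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class Model(str, enum.Enum):
    """Identifier for the placement of environmental noise."""

    M1 = "M1"  # growth-rate noise only
    M2 = "M2"  # carrying-capacity noise only
    M3 = "M3"  # both

    @property
    def has_eps(self) -> bool:
        """True when the model carries growth-rate shocks eps_t."""
        return self in (Model.M1, Model.M3)

    @property
    def has_eta(self) -> bool:
        """True when the model carries log-carrying-capacity shocks eta_t."""
        return self in (Model.M2, Model.M3)


#: intrinsic growth rates spanning stable, oscillatory and chaotic regimes
R_GRID: tuple[float, ...] = (0.5, 1.9, 3.0)

#: (sigma_r, sigma_k) per named noise magnitude
NOISE_PRESETS: dict[str, tuple[float, float]] = {
    "low": (0.0625, 0.125),
    "moderate": (0.125, 0.25),
    "high": (0.25, 0.5),
}


@dataclass(frozen=True)
class NoisePreset:
    """A named environmental-noise magnitude."""

    level: str
    sigma_r: float
    sigma_k: float

    @classmethod
    def from_level(cls, level: str) -> "NoisePreset":
        try:
            sr, sk = NOISE_PRESETS[level]
        except KeyError:
            raise ValueError(
                f"unknown noise level {level!r}; choose from {sorted(NOISE_PRESETS)}"
            ) from None
        return cls(level, sr, sk)


@dataclass(frozen=True)
class RickerParams:
    """Parameters of the (stochastic) Ricker map.

    Parameters
    ----------
    r
        Intrinsic growth rate per time step (dimensionless).
    k
        Log mean carrying capacity; ``K = exp(k)`` in abundance units.
    sigma_r
        SD of the growth-rate shocks ``eps_t``.
    sigma_k
        SD of the log-carrying-capacity shocks ``eta_t``.
    sigma_obs
        SD of the truncated-normal residual layer used only when fitting;
        ``None`` for pure process simulation.
    """

    r: float
    k: float = 1.0
    sigma_r: float = 0.0
    sigma_k: float = 0.0
    sigma_obs: float | None = None

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError(f"r must be >= 0, got {self.r}")
        if self.sigma_r < 0 or self.sigma_k < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.sigma_obs is not None and self.sigma_obs <= 0:
            raise ValueError("sigma_obs must be > 0 when supplied")
        if not math.isfinite(self.k):
            raise ValueError("k must be finite")

    @property
    def K(self) -> float:
        """Carrying capacity on the abundance scale (always positive)."""
        return math.exp(self.k)

    @classmethod
    def from_carrying_capacity(cls, r: float, K: float, **kw) -> "RickerParams":
        if K <= 0:
            raise ValueError("K must be > 0")
        return cls(r=r, k=math.log(K), **kw)


@dataclass
class PopulationSeries:
    """A strictly positive abundance time series y_1..y_T on a unit-step grid."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and equally long")
        if len(self.values) < 2:
            raise ValueError("a series needs at least two observations")
        if np.any(np.diff(self.times) != 1):
            raise ValueError("times must increase in unit steps")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("all abundances must be finite and > 0")

    @classmethod
    def from_values(cls, values, t0: int = 1) -> "PopulationSeries":
        values = np.asarray(values, dtype=float)
        return cls(np.arange(t0, t0 + len(values)), values)

    def __len__(self) -> int:
        return len(self.values)

    def head(self, n: int) -> "PopulationSeries":
        """The first ``n`` observations (the training window in cross-validation)."""
        if not 2 <= n <= len(self):
            raise ValueError(f"head length must be in [2, {len(self)}], got {n}")
        return PopulationSeries(self.times[:n], self.values[:n])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "abundance": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PopulationSeries":
        df = pd.read_csv(path)
        if not {"time", "abundance"} <= set(df.columns):
            raise ValueError("series CSV needs columns 'time' and 'abundance'")
        return cls(df["time"].to_numpy(), df["abundance"].to_numpy())


@dataclass
class RegimeLabel:
    """Dynamical-regime classification of the deterministic map."""

    label: str
    lyapunov: float | None = None

    LABELS = ("stable_monotone", "stable_oscillatory", "periodic", "chaotic")

    def __post_init__(self) -> None:
        if self.label not in self.LABELS:
            raise ValueError(f"unknown regime label {self.label!r}")
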