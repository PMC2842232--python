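"""Full factorial replicate study: simulate, fit all models, summarize.

Each replicate row records one (true model x fitted model x r x noise level)
outcome: the DIC decomposition from the training window and the held-out
one-step MSE. Summaries are paired differences against the true model's fit
on the same series (the error-bar panels) and pooled DIC-MSE correlations
per generating condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .inference import McmcConfig, PriorSpec
from .selection import PredictionConfig, fit_and_score
from .simulate import make_grid, simulate_series
from .types import R_GRID, Model

log = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "true_model", "fit_model", "r", "noise_level", "rep", "seed",
    "DIC", "D_bar", "D_hat", "p_D", "MSE", "converged", "rhat_max",
]

_SEED_MASK = 0x7FFFFFFF


@dataclass(frozen=True)
class ExperimentConfig:
    """One sweep: replication scale, grid slice, MCMC and split settings."""

    reps: int = 30
    seed: int = 0
    models: tuple[Model, ...] = (Model.M1, Model.M2, Model.M3)
    r_values: tuple[float, ...] = R_GRID
    noise_levels: tuple[str, ...] = ("low", "moderate", "high")
    T: int = 100
    n_train: int = 90
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    priors: PriorSpec = field(default_factory=PriorSpec)
    rhat_max: float = 1.1
    ess_min: float = 0.0  # the sweep excludes fits on the R-hat gate alone

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        for key in ("reps", "seed", "T", "n_train", "rhat_max", "ess_min"):
            if key in raw:
                kw[key] = raw[key]
        if "models" in raw:
            kw["models"] = tuple(Model(m) for m in raw["models"])
        if "r_values" in raw:
            kw["r_values"] = tuple(float(r) for r in raw["r_values"])
        if "noise_levels" in raw:
            kw["noise_levels"] = tuple(raw["noise_levels"])
        if "mcmc" in raw:
            kw["mcmc"] = McmcConfig(**raw["mcmc"])
        if "priors" in raw:
            kw["priors"] = PriorSpec(**raw["priors"])
        return cls(**kw)


def run_experiment(
    config: ExperimentConfig,
    out_csv=None,
    progress: bool = False,
) -> pd.DataFrame:
    """Simulate every grid cell and fit all three models to each series.

    Fit failures are logged with their seed and skipped; the sweep never
    aborts. When ``out_csv`` is given, records are flushed after every series
    so an interrupted sweep leaves a readable file.
    """
    if config.reps < 2:
        raise ValueError("reps must be >= 2")
    grid = make_grid(
        config.reps, config.seed,
        models=config.models, r_values=config.r_values,
        noise_levels=config.noise_levels, T=config.T,
    )
    records: list[dict] = []
    wrote_header = False
    iterator = grid
    if progress:
        from tqdm import tqdm  # optional nicety; plain loop otherwise

        iterator = tqdm(grid)
    for cfg in iterator:
        series, _ = simulate_series(cfg)
        pred = PredictionConfig(N=config.T, n=config.n_train)
        fit_ss = np.random.SeedSequence(cfg.seed, spawn_key=(1,))
        new = []
        for child, fit_model in zip(fit_ss.spawn(3), (Model.M1, Model.M2, Model.M3)):
            st = child.generate_state(2)
            mcmc = replace(config.mcmc, seed=int(st[0]) & _SEED_MASK)
            try:
                res = fit_and_score(
                    series, fit_model,
                    priors=config.priors, mcmc=mcmc, pred=pred,
                    predict_seed=int(st[1]) & _SEED_MASK,
                    rhat_max=config.rhat_max, ess_min=config.ess_min,
                )
            except Exception:
                log.exception(
                    "fit failed: true=%s fit=%s r=%s level=%s rep=%s seed=%s",
                    cfg.model.value, fit_model.value, cfg.params.r,
                    cfg.noise_level, cfg.rep, cfg.seed,
                )
                continue
            new.append(
                {
                    "true_model": cfg.model.value,
                    "fit_model": fit_model.value,
                    "r": cfg.params.r,
                    "noise_level": cfg.noise_level,
                    "rep": cfg.rep,
                    "seed": cfg.seed,
                    "DIC": res.dic,
                    "D_bar": res.d_bar,
                    "D_hat": res.d_hat,
                    "p_D": res.p_d,
                    "MSE": res.mse,
                    "converged": bool(res.converged),
                    "rhat_max": res.rhat_max,
                }
            )
        records.extend(new)
        if out_csv is not None and new:
            pd.DataFrame(new, columns=RECORD_COLUMNS).to_csv(
                out_csv, mode="a" if wrote_header else "w",
                header=not wrote_header, index=False,
            )
            wrote_header = True
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


GROUP_KEYS = ["true_model", "r", "noise_level"]


def delta_summaries(records: pd.DataFrame, use_converged_only: bool = True) -> pd.DataFrame:
    """Mean and SD of paired DIC/MSE differences against the true model.

    Differences are taken per replicate on the same simulated series, so the
    true-model rows are exactly zero by construction. Groups with fewer than
    two usable replicates are excluded (flagged in the log).
    """
    df = records.copy()
    if use_converged_only:
        # a pair is usable only when both the contending and the true fit converged
        conv = df.groupby(GROUP_KEYS + ["rep"])["converged"].transform("all")
        df = df[conv & df["converged"]]
    truth = df[df["fit_model"] == df["true_model"]][
        GROUP_KEYS + ["rep", "DIC", "MSE"]
    ].rename(columns={"DIC": "DIC_true", "MSE": "MSE_true"})
    merged = df.merge(truth, on=GROUP_KEYS + ["rep"], how="inner")
    merged["dDIC"] = merged["DIC"] - merged["DIC_true"]
    merged["dMSE"] = merged["MSE"] - merged["MSE_true"]
    rows = []
    for keys, grp in merged.groupby(GROUP_KEYS + ["fit_model"]):
        if len(grp) < 2:
            log.warning("group %s has < 2 usable replicates; excluded", keys)
            continue
        rows.append(
            {
                "true_model": keys[0], "r": keys[1], "noise_level": keys[2],
                "fit_model": keys[3],
                "mean_dDIC": grp["dDIC"].mean(), "sd_dDIC": grp["dDIC"].std(ddof=1),
                "mean_dMSE": grp["dMSE"].mean(), "sd_dMSE": grp["dMSE"].std(ddof=1),
                "n_reps": len(grp),
            }
        )
    return pd.DataFrame(rows)


def dic_mse_correlation(
    records: pd.DataFrame,
    method: str = "pearson",
    per_replicate: bool = False,
    use_converged_only: bool = True,
) -> pd.DataFrame:
    """DIC-MSE correlation per generating condition.

    By default (fitted model x replicate) pairs are pooled within each
    (true model, r, noise level) cell; ``per_replicate=True`` instead
    correlates the three fits within each replicate and averages.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    df = records[records["converged"]] if use_converged_only else records
    rows = []
    for keys, grp in df.groupby(GROUP_KEYS):
        if per_replicate:
            rhos = [
                g["DIC"].corr(g["MSE"], method=method)
                for _, g in grp.groupby("rep")
                if len(g) >= 2 and g["DIC"].nunique() > 1 and g["MSE"].nunique() > 1
            ]
            rho = float(np.nanmean(rhos)) if rhos else np.nan
            n = len(grp)
        elif len(grp) < 10 or grp["DIC"].nunique() == 1 or grp["MSE"].nunique() == 1:
            rho, n = np.nan, len(grp)
        else:
            rho = float(grp["DIC"].corr(grp["MSE"], method=method))
            n = len(grp)
        rows.append(
            {
                "true_model": keys[0], "r": keys[1], "noise_level": keys[2],
                "rho": rho, "n": n,
            }
        )
    out = pd.DataFrame(rows)
    bad = ~out["rho"].between(-1.0, 1.0) & out["rho"].notna()
    if bad.any():
        raise AssertionError("correlation outside [-1, 1]")
    return out
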