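# rickernoise

Where should environmental noise enter a population dynamics model — the
growth rate, the carrying capacity, or both? This package implements a
simulation study around the stochastic Ricker map that asks exactly that,
for ecologists and biostatisticians comparing state-space formulations of
density-dependent growth.

## The models

The deterministic Ricker map is

```
y_t = y_{t-1} · exp{ r (1 − y_{t-1}/K) }
```

with intrinsic growth rate `r` and carrying capacity `K = exp(k)`. Its
positive equilibrium `y* = K` is locally stable for `0 < r < 2`
(`f'(K) = 1 − r`), period-doubles beyond `r = 2`, and is chaotic by `r = 3`
(positive Lyapunov exponent). Environmental stochasticity enters as iid
normal shocks in one of three ways:

| model | update | noise placement |
|-------|--------|-----------------|
| M1 | `y_t = y_{t-1} exp{r(1 − y_{t-1}/K) + ε_t}` | growth rate, `ε_t ~ N(0, σ_r²)` |
| M2 | `y_t = y_{t-1} exp{r(1 − y_{t-1}/K_t)}`, `K_t = exp(k + η_t)` | carrying capacity, `η_t ~ N(0, σ_k²)` |
| M3 | both shocks in one step | both |

Series are simulated on the grid `r ∈ {0.5, 1.9, 3}` (stable, oscillatory,
chaotic), `k = log K = 1`, `T = 100`, at three noise magnitudes
(`(σ_r, σ_k)` = (0.0625, 0.125), (0.125, 0.25), (0.25, 0.5)).

Each model is fitted to each series by MCMC under a truncated-normal
observation layer `y_t ~ N(μ_t, σ_obs²)` on `(0, ∞)`, with `μ_t` built per
model and weakly informative priors (truncated-normal on `r`,
inverse-gamma on variances and carrying-capacity scales). The sampler is an
adaptive random-walk Metropolis within a fixed block scan, with an
adaptive-covariance joint block for the scalar parameters and non-centered
latent paths; see `docs/methods.md`.

Models are compared on

- **fit**: the deviance information criterion `DIC = D̄ + p_D`, where `D̄`
  is the posterior mean deviance (`D = −2 log L`), `D̂` the deviance at the
  posterior mean, and `p_D = D̄ − D̂` the effective number of parameters;
- **forecast accuracy**: one-step-ahead cross-validation — fit on the first
  `n = 90` points, then for each held-out `t` form the posterior predictive
  of `y_t` given the observed `y_{t−1}` (sufficient under the first-order
  Markov structure) and score the predictive mean by mean squared error.

## Worked example

```
python analysis/03_fit_single_series.py
```

simulates one growth-rate-noise (M1) series at `r = 1.9`, moderate noise,
fits all three models on the first 90 points and scores the last 10:

```
true model M1, r=1.9, moderate noise

fit     D_bar    D_hat     p_D      DIC      MSE  converged
M1       30.9    -32.4    63.3     94.2    0.069  True
M2       86.7     18.8    67.9    154.6    0.069  True
M3      104.6     29.3    75.3    179.9    0.109  True
```

The true model wins on DIC by ~60 points (better fit at comparable
effective complexity), while the one-step MSE separates the models much
less — forecasting one step ahead in an oscillatory regime is easy for any
of the three.

The other drivers: `01_map_regimes.py` (regime/Lyapunov scan),
`02_simulate_series.py` (example series for every design cell),
`04_replicate_study.py [reps] [seed]` (the full sweep, records to
`results/records.csv`), `05_summarize_study.py` (paired ΔDIC/ΔMSE
error-bar panels and DIC–MSE correlations).

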