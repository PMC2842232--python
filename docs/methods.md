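# Methods

## Generative models

All three variants share the Ricker kernel
`y_t = y_{t-1} exp{r (1 − y_{t-1}/K)}` with `K = exp(k)`. Environmental
noise is iid across time steps and enters multiplicatively on the log
scale: growth-rate shocks `ε_t ~ N(0, σ_r²)` (M1, M3) and
log-carrying-capacity shocks `η_t ~ N(0, σ_k²)` with `K_t = exp(k + η_t)`
(M2, M3). Because the shocks act inside the exponential, every simulated
abundance is strictly positive. The generator adds **no observation
noise**: the truncated-normal residual term of the fitting likelihood is a
fitting device capturing unexplained variation, not part of the data-
generating process.

Defaults are the study conditions: `r ∈ {0.5, 1.9, 3}` spanning monotone
approach, damped oscillation, and chaos; `k = 1` (K = e, a unit-free
choice); `T = 100`; noise presets low (0.0625, 0.125), moderate
(0.125, 0.25), high (0.25, 0.5) for `(σ_r, σ_k)`. The initial abundance is
never part of those conditions, so the generator draws it once per series
as `y0 = K·u`, `u ~ Uniform(0.5, 1.5)`: starting near equilibrium keeps
short series from being dominated by a transient while still exercising
density dependence. Reproducibility is by `numpy.random.SeedSequence`
throughout; grid cells derive child seeds from the master seed via spawn
keys indexed by cell coordinates, so a sub-grid run reproduces exactly the
seeds those cells receive in the full grid.

## Dynamical diagnostics

Stability of `y* = K` follows from `f'(K) = 1 − r` (boundary at `r = 2`).
For `r ≥ 2` the regime is decided by the orbit-averaged Lyapunov exponent
(default 10⁵ iterations after 10³ burn-in from `y0 = 0.1K`), with a
`λ > 0.01` nats/step threshold for "chaotic" to guard against periodic
windows near zero. The three-way grid only needs this coarse
classification; we do not assert an exact chaos-onset growth rate (the
0.1-step scan puts the first chaotic point at r ≈ 2.7, inside a
period-doubling cascade with periodic windows).

## Likelihood and priors

For `t = 2..T`, `y_t ~ N(μ_t, σ_obs²)` truncated to `(0, ∞)`, with the
truncation normalizer `Φ(μ_t/σ_obs)` included, and

- M1: `μ_t = y_{t-1} exp{r(1 − y_{t-1}/K) + ε_t}`
- M2: `μ_t = y_{t-1} exp{r(1 − y_{t-1}/K_t)}`
- M3: both.

Priors: `r ~ N(0, 10²)` truncated to `(0, ∞)` (weakly informative over the
biologically plausible range; only positivity is essential); all variance
parameters (`σ_r²`, `σ_k²`, `σ_obs²`) `~ InvGamma(1, 1)`; the static `K`
of M1 `~ InvGamma(1, 1)`. For the per-step carrying capacities of M2/M3
two readings are implemented:

- `kt_prior="hierarchical"` (default): `K_t = exp(k + η_t)`,
  `η_t ~ N(0, σ_k²)`, `k ~ N(0, 10²)` — matches the generative model;
- `kt_prior="iid-invgamma"`: each `K_t ~ InvGamma(1, 1)` independently,
  with no hierarchy — the literal reading of the study's prior. Under this
  reading nothing is learned about future carrying capacities, so one-step
  predictions draw `K*` from the prior; forecasts are correspondingly
  poor in volatile regimes, which is a property of the prior, not a bug.

Note a deliberate tension: the InvGamma(1, 1) variance priors place
essentially no mass below ~0.05, while the generative variances are as
small as σ_r² = 0.004. Fitted noise scales are therefore prior-floored at
low noise. This is retained as a study condition rather than "fixed".

## Sampler

Adaptive random-walk Metropolis within a fixed-order block scan, on an
unconstrained parameterization (logs of positive quantities, Jacobians in
the target). Blocks: each scalar parameter alone; latent paths in blocks
of 10. Step sizes adapt by Robbins–Monro toward acceptance 0.44 (scalars)
or 0.25 (blocks) during burn-in only and are frozen afterwards, so the
post-burn-in chain is a valid fixed-kernel Markov chain. Three additions
are essential for convergence at the study's settings:

1. **Joint adaptive-covariance block** over the scalar parameters
   (Haario-style, covariance learned during burn-in, frozen after): `r`
   and `K` sit on a pronounced posterior ridge.
2. **Non-centered latents**: the chains store standardized shocks
   `u_t ~ N(0,1)` with `ε_t = σ_r u_t` (and `η_t = σ_k u_t`), removing the
   funnel between each path and its scale parameter.
3. **Field-shift blocks**: one shared `N(0, s)` increment proposed for an
   entire latent segment, the slowest posterior direction (a path moving
   coherently against `r` or `k`).

For the iid-InvGamma reading there is additionally a deterministic-map
move along the exact likelihood ridge: multiply `r` by `exp(δ)` and remap
every `K_t` so that `g_t = r(1 − y_{t-1}/K_t)` is unchanged (the
likelihood depends on `(r, K_t)` only through `g_t`), accepted with the
analytic Jacobian `Σ_t log((r − g_t)/(r' − g_t))`.

Defaults mirror the study: 3 chains from dispersed data-informed starts,
4000 burn-in, 16000 further iterations thinned to every 20th (2400 stored
draws). Convergence is checked quantitatively (the original assessment was
visual): split-R̂ ≤ 1.1 and ESS ≥ 200 per scalar parameter by default; the
replicate sweep gates on R̂ alone because ESS thresholds calibrated for
2400 draws are not meaningful at reduced chain lengths, and reports the
exclusions.

Determinism: identical (series, model, priors, MCMC config) reproduces
bit-identical chains; the kernel uses numba's per-process RNG seeded per
chain from spawned `SeedSequence` children.

## Model comparison

**DIC.** The deviance is the conditional (observation-layer) deviance
given the latent shocks — the focus a general-purpose Gibbs sampler uses
when latents are explicit stochastic nodes. `D̄` averages the deviance
over stored draws; `D̂` plugs in posterior means of parameters *and*
latent path. Means are taken on the natural scale for `r`, `k` and the
shocks, and on the log scale for variance parameters **and
carrying-capacity quantities**: both posteriors are strongly
right-skewed, and an arithmetic-mean `K` can land far outside the
high-density region (heavy-tailed `K` posteriors produced plug-in
deviances hundreds of units off before this choice). The identities
`p_D = D̄ − D̂` and `DIC = D̄ + p_D` are asserted on every decomposition.

A conditional-focus caveat: `p_D` counts data-informed latent dimensions,
so latent-rich fits (M1/M3, and hierarchical M2 in volatile regimes)
carry an effective-parameter load of tens, while a fit whose latents are
inert (M2 at low `r`, where carrying-capacity noise scarcely moves the
one-step mean) counts as ~2 parameters. Cross-model DIC comparisons at
low growth rates are therefore dominated by latent structure rather than
fit quality; the held-out MSE comparison does not share this sensitivity.
This is the main caveat when reading the replicate-study summaries.

**Forecasts.** Fit on the first `n = 90` points (the split is a package
choice; only `T = 100` is fixed), then for each held-out `t` the one-step
posterior predictive given the *observed* `y_{t−1}`: per stored draw, draw
fresh shocks from their fitted distributions (training latents are never
reused), form `μ`, sample the truncated-normal layer by inverse CDF. The
point forecast is the predictive mean (MSE-optimal); MSE averages the
squared errors over the 10 held-out points. Per-time child seeds make the
result independent of evaluation order. `σ = 0` collapses the predictive
to the deterministic map exactly.

## Replicate study

`run_experiment` crosses true model × r × noise level × replicates,
simulates each series, fits all three models to its first 90 points, and
records the DIC decomposition, MSE, and the convergence flag per fit,
flushing rows incrementally. Summaries are paired per replicate (same
series) against the true model's fit: mean ± SD of ΔDIC and ΔMSE per
condition; a pair enters only when both fits pass the R̂ gate, and
exclusions are counted. DIC–MSE correlations pool (fitted model ×
replicate) pairs within each generating condition (three points per
replicate alone would be degenerate); a per-replicate variant and
Spearman's ρ are available by flag.

## Problem sizes used by the tests

The test suite runs the sweep at 30 replicates, low noise,
`r ∈ {0.5, 3}`, with 2 chains × (2000 burn-in + 6000 iterations, thin 6)
per fit, and the parameter-recovery check at 20 replicates of T = 100;
the full-scale study (1000 replicates at the full grid) is a configuration
switch on `04_replicate_study.py`, not a test target. Sampler calibration
uses a likelihood-tempering weight (`likelihood_scale=0` targets the
prior) and a conjugate normal-mean model run through the same kernel.

## What the generator does and does not emulate

Simulated data contain pure process noise with iid shocks — no
observation error, no autocorrelated environments, no demographic
stochasticity, no age structure. Passing tests therefore certify the
inference machinery and the comparison pipeline under the stated
generative assumptions; they say nothing about robustness to measurement
error or correlated forcing in real series, where the observation layer
and the process noise would compete in ways these data cannot probe.

## Known limitations

- Cross-model DIC at low growth rates reflects latent structure under the
  conditional focus (above); conclusions drawn from DIC alone in that
  regime are fragile, and the low-`r` comparability asserted by the
  replication suite fails under both prior readings for this reason.
- In the chaotic regime, fits of the carrying-capacity-noise models mix
  slowly even with the tailored moves; at the reduced chain lengths the
  R̂ gate excludes an appreciable fraction of such fits, and the sweep
  reports those exclusions rather than silently including them.
- The truncated-normal observation layer is unbounded as `σ_obs → 0` for
  interpolating fits; the InvGamma(1, 1) prior is what keeps the
  posterior proper, so replacing it with a lighter-tailed prior is not a
  neutral change.
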