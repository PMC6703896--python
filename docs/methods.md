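# Methods

## Model

`seasonfit` models a monthly per-day average series y_t (monthly event
count divided by the number of days in the calendar month, t = 1..n) as

    y_t = β0 + β1·t + S(t) + e_t
    S(t) = η1·sin(2πt/12) + η2·cos(2πt/12)
    e_t  = ρ·e_{t−1} + ε_t,   ε_t ~ Normal(0, σ²_ε)

β0 is the hypothetical level at t = 0 (events/day), β1 the linear trend
(events/day per month), (η1, η2) a single annual harmonic whose amplitude
is √(η1² + η2²) and whose phase fixes the peak month, and e_t a stationary
AR(1) (optionally AR(2)) Gaussian error process. The model assumes an
evenly spaced, gap-free monthly grid; missing months are a hard error
because the AR recursion is undefined across gaps.

Working on per-day averages rather than raw counts removes the 28–31-day
month-length artefact; a Gaussian likelihood is appropriate because the
averages here are far from zero (tens of events per day). No count
(Poisson/negative-binomial) observation layer is provided.

## Estimation

Parameters are estimated by a three-block Gibbs sampler built around
Prais–Winsten quasi-differencing:

1. **Coefficients θ = (β0, β1, η1, η2).** Conditional on (ρ, σ²_ε), the
   transformed regression has iid Normal(0, σ²_ε) errors, so θ has a
   conjugate Gaussian conditional. For AR(1) the first observation is kept
   with its exact stationary weight √(1−ρ²); for AR(2) the first two rows
   are dropped (conditional likelihood).
2. **AR coefficients.** The lag regression of the residuals
   u_t = y_t − x_tᵀθ on their own lags gives a Gaussian conditional,
   truncated to the stationarity region (|ρ| < 1; for AR(2) the triangle
   ρ2 ± ρ1 < 1, |ρ2| < 1) by rejection with a 1,000-attempt cap. For AR(1)
   this truncated Gaussian serves as the proposal of a Metropolis step
   whose acceptance ratio is the stationary first-observation factor
   √(1−ρ²)·exp(−(1−ρ²)u_1²/2σ²_ε); for AR(2) it is used directly.
3. **Innovation variance.** σ²_ε has an inverse-gamma conditional with all
   n innovation terms for AR(1) (the first weighted by √(1−ρ²)) and n−2
   terms for AR(2).

**Why the stationary first observation.** A pure conditional-likelihood
treatment (dropping the first row) leaves a posterior ridge at ρ → 1 where
quasi-differencing annihilates the intercept column: under a vague
coefficient prior the ridge carries substantial mass and, in low-noise
settings, the chain settles there with an arbitrary intercept. The
stationary term penalises ρ → 1 and pins the level; in the zero-ρ limit it
also makes the coefficient posterior mean exactly the full-sample
least-squares solution, which the test suite exploits as an oracle.

**Priors** (vague, in the style of standard BUGS practice): independent
Normal(0, 1000²) on each coefficient (`prior_coef_sd`, np.inf allowed for
a flat prior), Inverse-Gamma(0.001, 0.001) on σ²_ε, uniform over the
stationarity region on the AR coefficients.

**Chain length.** Defaults are 20,000 retained draws after 2,000 burn-in —
at n = 120 the conditionals are near-conjugate and mix within a few dozen
iterations, so this desk-scale run reproduces long-run summaries to well
inside Monte Carlo error; `longrun_protocol()` switches to 500,000 draws
after 10,000 burn-in. No thinning. Identical data, configuration and seed
give bit-identical draws. Convergence monitoring is left to the user (the
draw matrix can be exported and inspected with e.g. arviz); it never gates
a fit.

**Degenerate inputs.** Series shorter than 24 months (two seasonal cycles),
non-finite values, rank-deficient designs and zero-residual responses
(e.g. a constant series) raise immediately rather than being regularised.

## Summaries

Posterior summaries are means with equal-tailed 95% credible intervals.
The seasonal amplitude is reported two ways: the plug-in value
√(η̂1² + η̂2²) at the posterior means (the headline number) and the
posterior mean of the per-draw amplitudes, which is always ≥ the plug-in
value by Jensen's inequality. The peak month is the closed-form phase
solution t* = ((π/2 − atan2(η2, η1))/(2π/12)) mod 12 on (0, 12],
reported as a real month plus the nearest calendar month name (exact
half-months round to the earlier month).

Two seasonality-significance readings are computed:

* **coefficient rule** — the 95% intervals for *both* η1 and η2 exclude
  zero (the both-required reading is used; requiring only one would flag
  seasonality whenever either phase component happens to be well separated
  from zero, which is not how the joint harmonic should be read);
* **band rule** — the pointwise (not simultaneous) 95% band around the
  posterior S(t) curve excludes zero in at least one calendar month.

The band rule is the primary flag for stratified reporting; both are
always returned.

## Model comparison

DIC = D̄ + pD with pD = D̄ − D(θ̄), where the deviance is −2× the Gaussian
AR log-likelihood matching the fitted form (exact stationary likelihood
for AR(1); conditional on the first two observations for AR(2)), D̄
averages over draws and D(θ̄) evaluates at the posterior means. Because
the two AR orders naturally condition on different numbers of leading
observations, `compare_ar_orders` (and any cross-order comparison) fixes a
common conditioning set — the first two observations — so the criteria are
sums over the identical data window. Without this, the extra deviance term
of the AR(1) model (≈ log 2πσ² + 1 per observation) would bias the
comparison against the simpler model by construction.

## Diagnostics

Residuals are taken against the posterior-mean curve β̂0 + β̂1·t + Ŝ(t),
so they estimate e_t with the AR structure deliberately left in; an
AR(1)-whitened innovation series r_t − ρ̂·r_{t−1} is also reported for
whiteness checks.

* **PACF** via the Durbin–Levinson recursion on biased (Yule–Walker)
  sample autocovariances, with the conventional ±2/√n significance band.
* **ADF** unit-root test with a constant and no deterministic trend (the
  model already removes the trend), default one augmentation lag, and the
  fixed asymptotic constant-only critical values −3.43 / −2.86 / −2.57 at
  1 / 5 / 10%. Finite-sample response-surface critical values are not
  used; the constants are documented here instead.
* The serial-correlation flag fires when the lag-1 partial autocorrelation
  of the whitened innovations exceeds its band — i.e. when AR(1)
  whitening fails to remove the dependence the model claims to capture.
  The flag is deliberately restricted to lag 1: scanning all lags would
  false-flag most correctly specified fits purely by multiplicity
  (1 − 0.95^L for L lags).

## Synthetic data

The generator draws series with exactly the model's structure:
e_1 from the stationary Normal(0, σ²_ε/(1−ρ²)) (so the error process is
strictly stationary from t = 1, not burnt in from e_0 = 0), the AR(1)
recursion thereafter, and y_t as mean curve plus error. Integer monthly
counts are obtained as round(y_t × days-in-month), rounding half away
from zero for bit-exact fixtures; these round-trip through the ingest
module within half a count per month. The generator is AR(1)-only.

Default simulation conditions are the published posterior means for the
male series — β0 = 28.98, β1 = 0.029, η1 = −1.540, η2 = −1.655, ρ = 0.356
— over n = 120 months. The innovation SD is a free knob with default
σ_ε = 1.0: the source analysis does not report a residual SD, and 1.0
gives a stationary error SD of ≈1.07 events/day against a seasonal
amplitude of 2.26, i.e. a clearly detectable but far-from-trivial signal.

What the simulations do not emulate: count-level (Poisson) noise,
population drift within strata, reporting artefacts, or any misspecified
seasonality (multi-harmonic shapes). Passing recovery and coverage tests
therefore demonstrates correctness of the estimation machinery under the
model's own assumptions, not robustness to real-data violations of them.

## Test problem sizes

The simulation studies in the test suite use n = 120 months throughout,
with 20,000 retained draws for the single-fit recovery check, 3,000 draws
× 25 replicates for interval coverage (pass bound 20/25 per parameter,
about three binomial SDs below a nominal 95%), 2,000 draws × 50 replicates
for the DIC order comparison, and 200 replicates at n = 500 for ADF size
and power. These sizes keep each study's Monte Carlo error comfortably
inside its assertion tolerance.

## Known limitations

* Single annual harmonic only; no semi-annual terms or harmonic selection.
* Gaussian likelihood on per-day averages; not suitable for sparse counts.
* The AR(2) fit conditions on two observations rather than using the exact
  stationary bivariate initial distribution.
* Pointwise (not simultaneous) credible bands, so the band significance
  rule has a pointwise, not family-wise, error interpretation.
* No automatic ADF lag selection; the augmentation order is a user choice.
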