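# seasonfit

Bayesian detection and quantification of seasonality in monthly
hospital-admission time series — built for the classic epidemiological
question "do femoral fractures peak in winter?", but applicable to any
monthly event series with a trend and an annual cycle.

The series analysed is the monthly average number of events per day,
y_t = (monthly count) / (days in that month), modelled as

    y_t = β0 + β1·t + η1·sin(2πt/12) + η2·cos(2πt/12) + e_t,
    e_t = ρ·e_{t−1} + ε_t,    ε_t ~ N(0, σ²_ε),

a linear trend plus a single annual (cosinor) harmonic with stationary
AR(1) Gaussian errors in the Prais–Winsten tradition. Fitting is fully
Bayesian via a Gibbs sampler with vague priors. The package reports
posterior means and 95% credible intervals, the seasonal amplitude
√(η1² + η2²), the peak month from the harmonic phase, two seasonality
significance rules (coefficient intervals and the credible band around
S(t)), DIC comparison of AR(1) vs AR(2) errors, and residual stationarity
diagnostics (PACF, augmented Dickey–Fuller). A simulator with exactly the
model's structure makes every stage testable without any external data.

The core estimator `BayesianHarmonicAR` follows scikit-learn conventions
(`fit(X, y)` on the time index and per-day averages, `predict`,
`get_params`/`set_params`), so it composes with sklearn tooling; the
module-level functions (`gibbs_fit`, `seasonal_curve`, `diagnose`, …) are
thin wrappers over it.

## Worked example

Simulate ten years of monthly counts at realistic parameter values
(intercept 28.98 events/day, trend 0.029/month, harmonic (−1.540, −1.655),
ρ = 0.356, σ_ε = 1), then fit and summarise:

```bash
seasonfit simulate --seed 7 --out sim_counts.csv
seasonfit fit --counts sim_counts.csv --start 2008-01 --end 2017-12 \
              --seed 42 --out fit.json
seasonfit season --fit fit.json --out season.csv
seasonfit diagnose --fit fit.json --counts sim_counts.csv --out diag.json
```

which prints

```
wrote 120 months of simulated counts to sim_counts.csv
DIC=314.7  amplitude=2.19  peak month=7.56 -> fit.json
{
  "amplitude_plugin": 2.187053170844649,
  "amplitude_posterior": 2.1931258961104847,
  "peak_month": 7.563035624608922,
  "significant_band": true,
  "significant_coef": true
}
ADF=-6.276 (stationary) -> diag.json
```

and `fit.json` contains the parameter table (posterior mean, 95% CI):

```
beta0   28.474  (27.954, 28.992)
beta1    0.034  ( 0.026,  0.041)
eta1    -1.597  (-1.918, -1.271)
eta2    -1.495  (-1.813, -1.176)
rho      0.368  ( 0.192,  0.550)
```

Reading the output: every generating value sits inside its interval; the
seasonal amplitude ≈ 2.19 events/day means the annual cycle swings the
daily average by about ±2.2 around the trend; the peak at t ≈ 7.56 falls
in mid-winter (July–August in the Southern Hemisphere); both significance
rules flag a real seasonal effect; and the ADF statistic of −6.28 (well
below the 5% critical value −2.86) rejects a unit root in the residuals,
as a correctly specified fit should.

The same pipeline is available as library calls:

```python
from seasonfit import (ModelParams, GeneratorSpec, generate_series,
                       gibbs_fit, summarize, seasonal_curve)

params = ModelParams(beta0=28.98, beta1=0.029, eta1=-1.540,
                     eta2=-1.655, rho=0.356, sigma_eps=1.0)
series = generate_series(GeneratorSpec(params, n_months=120, seed=7))
draws = gibbs_fit(series)                 # 20,000 draws after 2,000 burn-in
summary = summarize(draws, series)        # means, CIs, amplitude, DIC
curve = seasonal_curve(draws)             # S(m) with pointwise 95% band
```

`seasonfit rates` additionally turns a counts table plus annual population
table into incidence rates per 100,000 by year, sex and age group.

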