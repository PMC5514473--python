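# Methods

## Analysis model

The outcome model is a log-link count regression estimated by iteratively
reweighted least squares:

    log μ_t = a + Σ_ι β_ι AP_{t−ι} + s(time) + s(T_t) + s(H_t) + γ·DOW_t

Point estimates are the Poisson maximum-likelihood solution; dispersion is
handled quasi-likelihood-style with the Pearson estimator
φ̂ = χ²/(n − p), which rescales the covariance to φ̂·(XᵀWX)⁻¹ without
moving the estimates. Confidence intervals and p-values are Wald (normal
reference, z = 1.959964 for 95%), so p < 0.05 holds exactly when the 95%
CI excludes 1. IRLS starts at β = 0 with the intercept at
log(ȳ + 0.5/n) and stops when the relative deviance change falls below
1e-9 (cap 100 iterations); the linear predictor is clipped at ±30 purely
as an overflow guard. Rank deficiency is detected up front and reported
with the offending column names (QR with pivoting).

Model selection uses QAIC = −2ℓ/φ̂ + 2p. AIC is undefined under
quasi-likelihood; QAIC reduces to ordinary AIC at φ̂ = 1, and `qaic()`
accepts an explicit dispersion so plain Poisson AIC is available. When
several spline df are compared (`select_df`, candidates 1–10), the same
φ̂-free comparison per candidate is used and ties break toward the
smaller df; time df and weather df are selected sequentially (time first)
when both are free.

### Exposure bases

- *single-lag*: one model per lag ι with only AP_{t−ι} included;
- *unconstrained DLM*: all lags 0–7 as free columns;
- *constrained DLM*: one column per lag stratum, each the **sum** of the
  exposure over the stratum's lags, so the stratum coefficient is the
  shared per-unit log-RR at every member lag. Default strata {0}, {1–2},
  {3–7}; with one-lag strata the basis is a full-rank reparameterization
  of the unconstrained model and reproduces its fitted values exactly,
  which the test suite asserts at 1e-8. Constrained results are reported
  at every member lag with identical values, matching the repeated-cell
  presentation convention of journal tables.

A two-pollutant model adds the co-pollutant's lag-0 concentration as one
linear column; the functional form of the co-adjustment is a design
choice, as is fixing both pollutants at lag 0.

### Splines

Natural cubic splines are built from the truncated-power representation
(basis N₁ = x, N_{k+1} = d_k − d_{K−1} with
d_k = [(x−ξ_k)₊³ − (x−ξ_K)₊³]/(ξ_K−ξ_k)) on K = df + 1 knots: boundary
knots at the observed range, interior knots at equally spaced quantiles.
The basis has exactly df columns, is linear beyond the boundary knots, and
together with an intercept spans the natural spline space; x is affinely
mapped to [0, 1] before evaluation for conditioning (the spanned space is
unchanged). df = 1 degenerates to the linear term.

The time spline is evaluated on calendar-day offsets with total
df = round(df_per_year × span/365.25) — 42 for six years at 7/year — so
panels with calendar gaps (complete-case filtering) are handled on real
time, not row index, and shifting all dates by a whole week leaves fitted
values unchanged. Temperature and humidity enter as same-day daily means
with 4-df splines. Day-of-week is six indicators with Saturday (first day
of the Iranian week) as reference; an alternative "days since the most
recent holiday" integer term is available when a holiday calendar is
supplied, since count data of this kind are sometimes adjusted that way
instead.

## Missing-data handling

City-day values are means over the stations observing that pollutant-day;
a value is missing only when all stations are. Imputation fits a
6-dimensional multivariate normal to the daily pollutant vector by EM,
treating days as independent: per missingness pattern, the E-step computes
conditional means and covariances of the missing block given the observed
one; the M-step updates the mean and covariance from the completed
sufficient statistics. The observed-data log-likelihood is tracked every
iteration and must be non-decreasing (asserted in tests); convergence is a
likelihood gain below 1e-6 with a 500-iteration cap. Initialization is
deterministic: available-case means/variances with pairwise-complete
correlations projected to the nearest positive-definite matrix. Missing
entries are replaced by conditional means at the converged parameters;
negative imputed concentrations are floored at 0 and flagged. An optional
mode removes per-pollutant harmonic seasonal means first and imputes
residuals, acknowledging that the plain model assumes stationary means.

The complete-case alternative keeps only days with all six pollutants
observed. At the default missingness rates (20–35% per pollutant) that
retains ≈ Π(1 − r_j) ≈ 12% of days, so lagged models — which need up to 8
consecutive complete days per row — are effectively not identifiable on
complete-case panels; the EM-vs-complete-case comparison therefore
contrasts lag-0 models, where complete-case analysis is feasible but pays
with markedly larger standard errors.

## Synthetic-data generator

The generator emulates a six-year (2191-day) single-city study. Defaults:
pollutant means/SDs of (CO 2.89 ± 0.76 mg/m³, SO₂ 54.8 ± 33.3, NO₂
53.5 ± 21.8, O₃ 59.6 ± 26.7, PM₂.₅ 24.3 ± 20.9, PM₁₀ 86.6 ± 44.3 μg/m³),
baseline mean daily admissions 7.13 split 57.4/42.6% by sex and 69/31% by
age, per-pollutant missingness (CO 20%, PM₁₀ 25%, PM₂.₅ 30%, NO₂ 32%, O₃
34%, SO₂ 35%), and four monitoring stations.

Mechanics and the choices behind them:

- **Seasonality** — annual + semi-annual cosine cycles per variable, with
  combustion pollutants, humidity and admissions peaking mid-winter and
  O₃/temperature mid-summer. Day-to-day noise SD is set so the total
  variance approximates the configured SD².
- **Cross-pollutant correlation** — day-to-day noise is multivariate
  normal, truncated at a 0.1-unit floor (a truncation rather than a
  log-normal keeps the configured correlation interpretable). The
  correlation matrix defaults to exchangeable ρ = 0.4, a typical magnitude
  for co-emitted urban pollutants; it is a free parameter, not an
  empirical fact about any particular city.
- **Counts** — Poisson draws when the dispersion φ is 1, otherwise a
  gamma-mixed Poisson parameterized so Var = φμ day by day. The default
  φ = 4.2 matches a daily count of ~7 with SD ~5.5 (variance/mean ≈ 4.3),
  the regime the analysis model is meant for. Sex and age strata are
  binomial thinnings of the total and always sum to it.
- **Lag effects** — the log-mean adds Σ β_ι·AP(t−ι) for one configurable
  driver pollutant (default PM₁₀), plus centred-weather terms and the
  admissions seasonal cycle. A 7-day pre-period is generated internally so
  every returned day's count reflects genuine lag-0..7 exposures; the
  analysis then drops the first 7 returned days when lagging, as usual.
- **Missingness** — MCAR per pollutant by default (matching
  station-failure missingness unrelated to concentration); an optional MAR
  mode modulates the daily masking probability with the annual cycle at
  the same marginal rate, for robustness checks.
- **Stations** — station-day values are the city value plus independent
  Gaussian noise (SD = 15% of the pollutant SD by default), so the station
  mean is unbiased for the city value.

What the generator does **not** emulate: serial correlation in counts
beyond what shared seasonality induces, influenza epidemics and holiday
surges, spatially structured station error, measurement-device drift,
hourly structure (O₃'s 8-hour-maximum construction is represented only as
a daily scalar), or missingness mechanisms tied to concentration levels.
Passing tests therefore demonstrate correctness of the estimation
machinery under the stated data-generating assumptions, not robustness to
every feature of real surveillance data.

## Simulation studies and problem sizes

The validation studies run at the sizes the package documents as its
standard conditions: imputation accuracy on 20 study-sized (2191-day)
MCAR panels; rate-ratio recovery and CI coverage over 100 study-sized
replicates with a true lag-0 RR of 1.03 per 10 μg/m³; and type-I error
over 200 replicates of a null-effect scenario with deliberately strong
shared seasonality (exposure annual amplitude 40 μg/m³, outcome log-rate
amplitude 0.4) to make the seasonal-confounding control role of the time
spline visible — with the spline the lag-0 test rejects at the nominal 5%,
without it rejection is severalfold inflated.

## Known limitations

- The EM model treats days as exchangeable draws from one multivariate
  normal; seasonally varying means are only handled by the optional
  deseasonalized mode, and time-series (state-space) imputation is out of
  scope.
- No autocorrelation-robust standard errors; the quasi-Poisson φ̂ captures
  overdispersion, not serial dependence.
- No multiple-testing adjustment across lags, pollutants or subgroups —
  estimates are reported one at a time, as is conventional for this
  design, and should be read accordingly.
- Exposure-response is linear in concentration; non-linear cross-basis
  models are not implemented.
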