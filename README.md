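# airdlm

Distributed-lag quasi-Poisson time-series models for daily air pollution
and respiratory hospital admissions, with EM imputation of missing
pollutant series and a ground-truth synthetic-panel generator.

## The problem

Ecological time-series studies relate daily city-level pollutant
concentrations (CO in mg/m³; SO₂, NO₂, O₃, PM₂.₅, PM₁₀ in μg/m³) to daily
counts of respiratory hospital admissions. The analysis must deal with

- **delayed effects** — exposure on day *t−ι* can affect admissions on day
  *t*, for lags *ι* = 0..7;
- **shared temporal structure** — both pollution and admissions cycle with
  season, so the long-term/seasonal trend is the dominant confounder;
- **overdispersed counts** — daily admission counts vary more than a
  Poisson law allows;
- **missing exposure data** — monitoring stations fail, leaving 20–35% of
  days without a value for one pollutant or another.

`airdlm` implements the full chain as a reusable, tested library: city-day
averaging over stations, multivariate-normal EM imputation, design
matrices with natural-spline confounder control, quasi-Poisson GLM fitting
by IRLS, and rate-ratio reporting across lags, sex/age subgroups, and
two-pollutant models. A synthetic-data generator with known ground truth
makes every stage verifiable without any external data.

## The model

For daily counts Y<sub>t</sub> and pollutant concentration AP:

    Y_t ~ quasiPoisson(μ_t),   Var(Y_t) = φ μ_t
    log μ_t = a + Σ_ι β_ι AP_{t−ι} + s(time; 7 df/year)
              + s(T_t; 4 df) + s(H_t; 4 df) + γ·DOW_t

where `s(·)` are natural cubic splines (time spline: 42 df over six
years), T and H are daily mean temperature and relative humidity, and DOW
are day-of-week indicators (Saturday reference). Three exposure bases are
supported: **single-lag** (one model per lag), **unconstrained DLM** (all
eight lags free), and **constrained DLM** (coefficients shared within lag
strata {0}, {1–2}, {3–7}). Effects are reported as rate ratios
RR = exp(β·Δ) with Wald 95% CIs, Δ = 10 μg/m³ (1 mg/m³ for CO). Spline
degrees of freedom can be chosen by minimizing QAIC = −2ℓ/φ̂ + 2p.

Missing pollutant entries are imputed by fitting a 6-variate normal to the
daily pollutant vector with the EM algorithm and substituting conditional
means; a complete-case filter provides the sensitivity alternative.

## Worked example

```python
import numpy as np
from airdlm import SimConfig, simulate_panel, degrade_missing, em_impute, run_single_lag_suite
from airdlm.effects import format_table

beta = float(np.log(1.03) / 10)           # true lag-0 RR 1.03 per 10 ug/m3
cfg = SimConfig(n_days=2191, seed=3, lag_log_rr=(beta, 0, 0, 0, 0, 0, 0, 0))
panel, _ = simulate_panel(cfg)
degraded, _ = degrade_missing(panel, cfg) # 20-35% missing per pollutant
imputed = em_impute(degraded).panel
print(format_table(run_single_lag_suite(imputed, "pm10")))
```

prints

```
 pm10      all        single lag 0: 1.024 (1.016-1.031), p=0.000
 pm10      all        single lag 1: 1.002 (0.995-1.009), p=0.612
 pm10      all        single lag 2: 0.993 (0.986-1.000), p=0.059
 pm10      all        single lag 3: 1.004 (0.997-1.011), p=0.306
 pm10      all        single lag 4: 0.997 (0.990-1.005), p=0.490
 pm10      all        single lag 5: 0.993 (0.985-1.000), p=0.048
 pm10      all        single lag 6: 1.001 (0.993-1.008), p=0.827
 pm10      all        single lag 7: 0.999 (0.992-1.007), p=0.835
```

Each line is one quasi-Poisson model containing the exposure at exactly
that lag plus the full confounder set. The lag-0 interval covers the true
RR of 1.030 (the point estimate sits slightly below it — the price of
imputing a quarter of the exposure days); the other lags, which truly have
no effect, stay near 1. The `examples/` directory walks through each
capability the same way, and a thin CLI (`airdlm simulate|impute|fit|
run-all|compare-imputation`) wraps the pipeline for shell use.

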