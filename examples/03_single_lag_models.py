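"""Single-lag models: one quasi-Poisson regression per lag 0..7.

Each model contains the exposure at exactly one lag plus the full
confounder set (42-df time spline, 4-df temperature and humidity splines,
day-of-week indicators).  With a true lag-0-only effect, the lag-0 RR
should sit near 1.03 and the others near 1.
"""

import numpy as np

from airdlm import SimConfig, simulate_panel, degrade_missing, em_impute, run_single_lag_suite
from airdlm.effects import format_table

beta = float(np.log(1.03) / 10)
cfg = SimConfig(n_days=2191, seed=3, lag_log_rr=(beta, 0, 0, 0, 0, 0, 0, 0))
panel, _ = simulate_panel(cfg)
degraded, _ = degrade_missing(panel, cfg)
imputed = em_impute(degraded).panel

estimates = run_single_lag_suite(imputed, "pm10")
print("PM10, RR per 10 ug/m3, one model per lag:")
print(format_table(estimates))
print("\ntrue RR: 1.030 at lag 0, 1.000 elsewhere; "
      "CIs should cover these values")
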