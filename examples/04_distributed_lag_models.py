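"""Distributed-lag models: all lags 0..7 in one regression.

The unconstrained model estimates one free coefficient per lag; the
constrained model shares a coefficient within the lag strata {0}, {1-2},
{3-7}, trading a smoothness assumption for lower variance.  Constrained
estimates are reported at every member lag with identical values.
"""

import numpy as np

from airdlm import SimConfig, simulate_panel, run_dlm_suite
from airdlm.effects import format_table

beta = float(np.log(1.03) / 10)
cfg = SimConfig(n_days=2191, seed=4, lag_log_rr=(beta, 0, 0, 0, 0, 0, 0, 0))
panel, _ = simulate_panel(cfg)

print("unconstrained DLM (free coefficient per lag):")
print(format_table(run_dlm_suite(panel, "pm10", structure="unconstrained")))
print("\nconstrained DLM (strata {0}, {1-2}, {3-7}; repeated within strata):")
print(format_table(run_dlm_suite(panel, "pm10", structure="constrained")))
print("\nnote the identical RRs at lags 1-2 and at lags 3-7 of the "
      "constrained model, and its narrower intervals")
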