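"""Select the prenatal exposure window of a monthly covariate by AIC.

The outcome is generated with a drought-index (SPEI-like) effect acting 3
months before birth.  The scan refits the model once per candidate lag
1..12 — each lag tested on its own, because neighboring lags are
correlated — and picks the lag with the lowest AIC.
"""

import geofalter as gf
from geofalter.covariates import build_lagged_column

cfg = gf.SimulationConfig(n_clusters=400, individuals_per_cluster=(5, 15), seed=3)
survey = gf.simulate_survey(cfg)  # true SPEI lag is 3
d = survey.data
xy = d.individual_xy

series = survey.stack.extract_monthly("spei", xy[:, 0], xy[:, 1])
cols = {
    lag: build_lagged_column(series, d.birth_month, lag) for lag in range(1, 13)
}
scan = gf.scan_lags(
    d.z("haz"), survey.design, d.cluster_xy, d.cluster_index, "spei", cols
)

print(scan.table[["lag", "aic", "beta"]].round(3).to_string(index=False))
print(f"\nselected lag: {scan.selected_lag} months before birth (truth: 3)")
print("lower AIC = better fit; the coefficient is per 1 SD of the covariate")
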