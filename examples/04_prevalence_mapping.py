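"""Map growth-faltering prevalence and expected case counts on a grid.

Fits the model, kriges the latent spatial field onto the covariate grid,
converts the predictive z-score distribution to prevalence of z < -2 via
the closed-form exceedance probability, and multiplies by the under-5
population to get expected cases per cell.
"""

import numpy as np
import pandas as pd

import geofalter as gf
from geofalter.grids import extract_at_points

cfg = gf.SimulationConfig(n_clusters=300, individuals_per_cluster=(5, 15), seed=4)
survey = gf.simulate_survey(cfg)
d = survey.data

fit = gf.fit_mle(
    d.z("haz"), survey.design.values, d.cluster_xy, d.cluster_index,
    column_names=survey.design.columns, check_identifiability=False,
)

geom = survey.stack.geometry
gx, gy = geom.center_mesh()
# grid design: constant covariates at cell values, monthly ones at their
# temporal mean, transformed with the TRAINING standardization record
raw = {
    "aridity": survey.stack.extract_constant("aridity", gx, gy),
    "spei": extract_at_points(survey.stack.monthly_mean_raster("spei"), gx, gy)[0],
}
grid_design = survey.design.record.apply(pd.DataFrame(raw))[survey.design.columns]

latent = gf.krige_latent(
    fit, d.z("haz"), survey.design.values, d.cluster_xy, d.cluster_index,
    np.column_stack([gx, gy]),
)
prev = gf.prevalence_surface(fit, latent, grid_design, threshold=-2.0)
cases = gf.counts_surface(prev, survey.population)

print(f"grid: {geom.ny} x {geom.nx} cells of {geom.dx:.0f} km")
print(f"prevalence of z < -2: min {np.nanmin(prev):.3f}, "
      f"mean {np.nanmean(prev):.3f}, max {np.nanmax(prev):.3f}")
print(f"total under-5 population: {survey.population.values.sum():,.0f}")
print(f"total expected cases:     {np.nansum(cases):,.0f}")
print("each cell's prevalence is P(new child's z-score < -2) given the "
      "fitted surface; cases = prevalence x population")
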