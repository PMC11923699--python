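"""Simulate a synthetic cluster survey of child anthropometry.

Draws survey cluster locations, environmental covariate fields, an
under-5 population raster, and height-for-age z-scores from the linear
geostatistical model at known parameters, then prints the survey's shape
and the truth it was generated from.
"""

import numpy as np

import geofalter as gf

cfg = gf.SimulationConfig(n_clusters=100, individuals_per_cluster=(5, 15), seed=1)
survey = gf.simulate_survey(cfg)

d = survey.data
print(f"clusters:            {d.n_clusters}")
print(f"children measured:   {d.n_individuals}")
print(f"mean HAZ:            {d.z('haz').mean():.2f}")
print(f"under-5 population:  {survey.population.values.sum():,.0f}")
tp = survey.true_params
print(f"truth: alpha={tp.alpha}, beta={tp.beta}, sigma2={tp.sigma2}, "
      f"phi={tp.phi} km, omega2={tp.omega2}")

# The mean HAZ should sit near alpha (covariates are standardized, so the
# average linear predictor is alpha); the spread mixes the spatial field
# (sigma2), the nugget (omega2) and the covariate effects.
print(f"empirical SD of HAZ: {d.z('haz').std():.2f} "
      f"(model: sqrt(sigma2 + omega2 + beta'beta) = "
      f"{np.sqrt(tp.sigma2 + tp.omega2 + tp.beta @ tp.beta):.2f})")
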