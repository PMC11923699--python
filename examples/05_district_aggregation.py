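"""Aggregate a prevalence surface to administrative districts.

Cells are assigned to the polygon containing their center; district
prevalence is the population-weighted mean and district cases are the sum
of cellwise prevalence x population — so the national total is conserved
under any partition.
"""

import numpy as np
import shapely

import geofalter as gf
from geofalter.grids import GridGeometry, Raster

rng = np.random.default_rng(5)
geom = GridGeometry(x0=0.0, ytop=200.0, dx=10.0, dy=10.0, nx=20, ny=20)
population = Raster(geom, rng.integers(0, 20_000, (20, 20)).astype(float))
prevalence = rng.uniform(0.1, 0.5, 400)  # stands in for a fitted surface

districts = {
    "west": shapely.box(0, 0, 100, 200),
    "northeast": shapely.box(100, 100, 200, 200),
    "southeast": shapely.box(100, 0, 200, 100),
}
summary = gf.aggregate_polygons(prevalence, population, districts)

print(summary.table.round(3).to_string(index=False))
total = float(prevalence @ population.values.ravel())
print(f"\nsum of district cases: {summary.table['cases'].sum():,.1f}")
print(f"cellwise total:        {total:,.1f}  (conserved exactly)")
print(f"cells outside all districts: {summary.n_unassigned_cells}")
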