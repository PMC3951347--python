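# killzones

Spatial analysis of where predators kill prey, for landscape ecologists
studying predator–prey systems with distinct prey life-history classes
(e.g. prime-aged vs senescent ungulates). Given kill-site coordinates
with a class label, habitat rasters, and a study-region polygon, the
package answers two questions per class:

1. **Are kill sites spatially clustered?** Ripley's K, presented in its
   linear form L(t) = √(K(t)/π) − t, with Monte-Carlo envelopes from
   complete-spatial-randomness (CSR) simulations in the irregular island
   window (99 simulations ⇒ pointwise α = 0.01 rank envelopes; isotropic
   edge correction).
2. **Where, and in what habitat?** A Gaussian-kernel density surface of
   kill sites (bandwidth by least-squares cross-validation) is read as
   the probability of kill occurrence; a Monte-Carlo test against CSR
   identifies the density percentile dividing the core "kill zone" from
   the rest; habitat covariates are averaged in a 100 m buffer (0.79 ha)
   around each site, standardized, and regressed on the site's KDE
   percentile,

   Y_i = β₀ + Σ_j β_j x_ij + ε_i,  ε ~ N(0, τ²I + σ²·exp(−d/φ)),

   a linear model with spatially autocorrelated (exponential covariogram)
   errors fitted by REML, with residual diagnostics and a reduced refit
   after removing terms whose standard error overlaps zero.

Because real kill-site data of this kind are rarely public, the package
ships a fully synthetic study system with known ground truth: an
elongated 544 km² island with interior lakes, six spatially
autocorrelated 30 m habitat rasters (elevation, slope, canopy, conifer,
distance-to-shore, distance-to-inland-lake), and two planted kill-site
processes — one spread in many small near-shore clusters, one
concentrated in a single inland high-elevation/high-conifer zone. Every
estimator in the chain is tested for recovery of that planted structure.

## Worked example

```python
from killzones import RunConfig, run_pipeline

cfg = RunConfig(seed=1)           # synthetic mode, study-condition defaults
bundle = run_pipeline(cfg)        # ~30 s on one core

print(bundle.zone_table[["display", "n_points", "core_percentile",
                         "area_km2", "n_polygons", "points_inside"]])
print({k: round(v, 2) for k, v in bundle.enrichment["pooled"].items()})
b = bundle.classes["class_b"].fit_full
print(b.params.round(2).to_dict())
```

prints (seed 1):

```
     display  n_points  core_percentile  area_km2  n_polygons  points_inside
0      prime       106             42.0     88.05           7             67
1  senescent       109             42.0      1.17           2             62
{'chi2': 298.1, 'p': 0.0, 'area_fraction': 0.16, 'n_in': 129, 'n_total': 215}
{'const': 46.2, 'elevation': 8.2, 'slope': 0.41, 'canopy': 2.58,
 'conifer': 12.94, 'dist_shore': 0.79, 'dist_lake': 72.34}
```

Reading: both classes are significantly clustered; the senescent-like
class's kill zone is far more concentrated (1–3 km² in 1–2 polygons vs
~90 km² in 7–8 polygons for the prime-like class at the same isopleth);
129 of 215 kills (60%) fall inside zones covering 16% of the island
(χ² = 298, p ≈ 10⁻⁶⁷); and the senescent-like probability of kill
occurrence rises with elevation and conifer cover (standardized β of
+8.2 and +12.9), recovering the planted ground truth. The distance
covariates carry very large standard errors for this class (they are
nearly constant across its single concentrated zone; e.g. dist_lake
β = 72 ± 60), which is what the se-overlaps-zero reduction step is for
— see `bundle.classes["class_b"].fit_reduced`. The same
`analyze` entry point accepts user data:

```sh
killzones simulate --seed 1 --out demo/            # write synthetic inputs
killzones analyze --points demo/points.csv --rasters demo/rasters \
                  --region demo/region.geojson --out demo/results
```

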