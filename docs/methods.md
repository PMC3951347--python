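# Methods

This note documents the statistical machinery, the synthetic study
system, the numerical choices, and the limitations of the `killzones`
pipeline. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Clustering: Ripley's K/L with CSR rank envelopes

For a pattern of n points in a window of area A,

    K̂(t) = A / (n(n−1)) · Σ_{i≠j} w_ij · 1[d_ij ≤ t],
    L̂(t) = √(K̂(t)/π) − t,

on a 1 km-spaced distance grid up to half the window diameter
(configurable). Under CSR, L ≡ 0; positive values indicate clustering.
Distance band edges are closed (d ≤ t), so K̂ is non-decreasing by
construction.

*Edge correction.* The default isotropic (Ripley) weight w_ij is the
reciprocal of the proportion of the circle centred at i with radius
d_ij lying inside the window. For an irregular island polygon that
proportion has no closed form; it is computed by sampling 64 directions
per circle against a rasterized window mask (~1/512 of the window
extent). The proportion is floored at half an angular step so weights
stay finite. The uncorrected estimator (`correction="none"`) is retained
and is the one checked against a brute-force pair-count oracle.

*Envelopes.* n_sims CSR patterns of the same n are simulated in the same
window; the k-th extreme pointwise bounds with k = ⌈α(n_sims+1)⌉ give a
one-sided rank test at level α per distance. The defaults (99
simulations, α = 0.01) make the bounds the simulation min/max. Envelope
tests are pointwise, not global: the "clustered up to X km" summaries
read off the largest significant band.

## Kill-occurrence surfaces

The KDE uses an isotropic Gaussian kernel with a single scalar
bandwidth per class, evaluated exactly at cell centres (default 100 m
cells, coarser than the 30 m habitat grid, for desk-scale runtimes),
truncated to the window and renormalized to unit mass. Surfaces warn
when the grid is coarser than h/2.

*Bandwidth.* Least-squares cross-validation,

    LSCV(h) = ∫f̂² − (2/n) Σ_i f̂_{−i}(x_i),

with both terms in closed form (Gaussian kernels convolve to a Gaussian
of variance 2h²). The default candidate grid is 25 log-spaced values
spanning up to [0.05, 5]× the normal-reference bandwidth σ·n^{−1/6},
floored at twice the mean nearest-neighbour spacing — below that scale
LSCV is rewarded for resolving individual points rather than density
structure, its well-known degeneracy with (near-)repeat locations. The
grid argmin is refined by bounded golden-section search; a boundary
argmin is returned with a warning. Exactly coincident points trigger a
warning; the pipeline jitters them by a tenth of a cell before
selection.

*Percentile transform.* percentile(cell) = 100 × (probability mass in
cells with density ≤ that cell's density); tied densities share a
percentile and the maximal cell is 100. The "top p%" region is the
highest-density set of cells holding p% of the mass (the home-range
volume-isopleth convention, not an area percentile). For isopleth
extraction a strict total order (density descending, ties by cell
index) makes the top-p% set nested and minimal, which also gives the
uniform-density surface a top-30% region of 30% area rather than a
degenerate all-or-nothing set.

## Core ("kill zone") identification

The divide between core and non-core is found by Monte-Carlo comparison
against CSR. For each candidate isopleth p ∈ {1,…,99} define the
concentration excess

    e(p) = f(p) − p/100,

where f(p) is the fraction of points whose *leave-self-out* smoothed
density (binned KDE at the class bandwidth, minus the point's own
kernel contribution) reaches the density cutoff of the top-p% mass set.
This is the classic utilization-curve core-area construction: the
containment curve f is compared with the 1:1 line of probability mass,
so e necessarily peaks at an interior isopleth. Removing the
self-contribution is essential at LSCV bandwidths — with small h every
point sits on its own density spike, and a self-inclusive f saturates
for *any* point set, CSR included, destroying both power and the
interior peak.

The same operator is applied to the observed points and to n_iter
(default 10,000) simulated CSR point sets of the same size, making the
comparison exchangeable under CSR. Inference then proceeds in three
steps:

1. **Global gate.** The Monte-Carlo p-value of max_p e(p) against the
   null distribution of the same maximum controls the familywise error
   of scanning 99 candidates; if it is ≥ α (default 0.05) the no-core
   sentinel is returned. A per-candidate test alone would return
   spurious cores under CSR far more often than its nominal level.
2. **Pointwise screening.** Candidates with Monte-Carlo exceedance
   probability < α are marked significant.
3. **Convergence point.** Among significant candidates, the returned
   percentile is the largest one whose excess lies within one null
   standard deviation of the maximum — the upper edge of the
   statistically indistinguishable plateau around the argmax, i.e. the
   most inclusive isopleth still showing maximal concentration excess.
   The argmax itself is unstable across the plateau; its lower edge
   systematically under-covers a planted core.

This concrete rule is this package's operationalization of
Monte-Carlo core estimation and is flagged as such in all outputs
(`provenance.json: core_rule`). By default the percentile is estimated
on the concentrated reference class and borrowed for the other class
for comparability; estimating per class, or falling back to a fixed
default isopleth (30%) when the sentinel is returned, are configuration
options.

Core polygons are the 8-connected components of the top-p% cell set,
polygonized as unions of cell squares; the reported area is the cell
count × cell area, which the polygon union reproduces exactly.

## Habitat extraction and regression

Covariates are means of each raster layer over masked-in cells whose
centres lie within a 50 m radius of the site (100 m diameter ≈ 0.79 ha,
the scale of daily prey movement); buffers clipped by the coast use
only inside cells, and a buffer narrower than the raster cell diagonal
is widened to it with a logged warning. Columns are z-scored with the
sample (n−1) standard deviation on the pooled two-class site set, so
standardized coefficients are comparable between the per-class models;
means and SDs are stored for back-transformation and for translating
standardized effects into natural units
(Δpercentile = β_std · δ / column_sd).

The per-class response is the class's own KDE percentile at its sites.
The error covariance is Σ = τ²I + σ²ρ(d/φ) with exponential correlation
by default (spherical and Gaussian available). Estimation is REML with
the overall scale and the coefficients profiled out, leaving a bounded
2-D optimization over the nugget proportion α = τ²/(τ²+σ²) ∈ [0,1] and
log φ (L-BFGS-B, four starts over a log-spaced range grid, likelihood
tolerance 1e-12). Two identifiability guards matter in practice:

* φ is capped at half the maximum pair distance (the classical
  variogram half-lag rule); longer ranges are not estimable and act as
  trend absorbers that swallow fixed effects.
* α = 1 is on the boundary, so independent errors are exactly nested;
  when the restricted likelihood of the independent model ties the
  optimum within 1e-8 the independent solution is preferred, making
  the ordinary-least-squares reduction exact.

Standard errors come from s²(XᵀV⁻¹X)⁻¹ at the optimum. Diagnostics are
computed on whitened (Cholesky-decorrelated) residuals: Shapiro–Wilk
for normality and a Breusch–Pagan score test of squared residuals on
fitted values for heteroscedasticity. Model reduction removes every
non-intercept term whose interval β ± se contains zero and refits (the
literal "standard error overlaps zero" rule; a z-based rule at 1.96 is
a configuration switch). The intercept is always retained.

The percentile response (0–100) is treated as Gaussian; no logit
transform is applied. This is a known limitation: predictions are not
range-constrained, and heteroscedasticity near the range ends is
possible.

## The synthetic study system

The generator's defaults are the package's study conditions and are
fixed; they emulate an elongated island predator–prey system.

* **Island**: smoothed random radial perturbation of a 5:1 ellipse
  (star-shaped, hence simple), rescaled so the net area equals the
  544 km² target exactly; 1–3 interior lakes. Planar metres, no
  geodesy; rasters use centre-of-cell registration with row 0 at the
  north edge.
* **Habitat fields** (30 m default): elevation (mean 220 m, SD 60 m,
  practical range 9 km) and latent canopy/conifer fields (logit scale,
  practical ranges 3 km and 6 km) are Gaussian random fields with
  exponential correlation, synthesized spectrally on a padded grid and
  empirically calibrated so masked-in sample moments match the
  specification exactly; proportions are logistic transforms of the
  latent fields. `corr_range` is the *practical* range (correlation
  ≈ 0.05, three e-folding scales). Slope is the finite-difference
  gradient magnitude of elevation; shore and lake distances are
  Euclidean distance transforms of the region geometry.
* **Kill processes**: log-linear intensity exp(Σβ_j z_j) over the
  standardized layers, sampled by thinning with envelope 1.001 × max
  intensity. Thomas-style clustering draws parent locations from the
  same intensity (with optional Matérn-II minimum separation so
  clusters spread across the island instead of clumping into one
  pocket) and offspring from an isotropic Gaussian around each parent,
  thinned by the same intensity — so the planted covariate effects
  hold for every point, clustered or not. Class defaults: the
  prime-like class (n = 106) has canopy +0.8, conifer −2.5,
  dist_shore −1.0 with 25 parents × ~4 offspring (σ = 1.8 km, 3.5 km
  separation); the senescent-like class (n = 109) has elevation +2.5,
  conifer +1.5, dist_shore +0.5 in a single cluster (σ = 2.2 km).
  Magnitudes were chosen so the planted structure — many small
  spread-out near-shore zones vs one inland high-elevation/high-conifer
  zone — is realized reliably at these sample sizes.

What the generator does **not** emulate: real coastline geometry,
terrain-correlated vegetation (fields are mutually independent),
observation error in carcass locations, year structure or serial
correlation across winters, and prey behavioural responses beyond what
the planted coefficients encode. Passing tests therefore demonstrate
that the estimators recover known structure of this generating family
at realistic sizes — not that any particular field system follows this
model.

## Problem sizes and determinism

Monte-Carlo sizes used by the test suite are desk-scale choices: 99
envelope simulations (the inferential default), 200–400 core-test
iterations in tests (10,000 in the pipeline default and the acceptance
script), 100–500 replicates for calibration and recovery checks, 20-seed
batteries for end-to-end structure recovery, and 60 m habitat / 200 m
KDE grids in the end-to-end battery (30 m / 100 m at the pipeline
defaults). Every operation is a pure function of its inputs including
the seed; pipeline stages draw from per-stage streams spawned from the
configuration seed, and rerunning a configuration reproduces every
numeric table bit for bit.

## Known limitations

* Pointwise (not global) envelope tests; no inhomogeneous-K,
  pair-correlation, or cross-K statistics.
* A single scalar bandwidth per class; no adaptive or anisotropic
  kernels.
* The core rule is one defensible operationalization of Monte-Carlo
  core estimation; other published core-area procedures will return
  different percentiles on the same data.
* The isotropic-correction weights are numerical (64 directions against
  a rasterized mask), adequate for envelope inference but not exact.
* REML with four starts is robust in the tested regimes but a global
  optimum is not guaranteed; the likelihood-vs-truth property is
  asserted only on simulated fits.
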