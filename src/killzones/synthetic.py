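"""Synthetic island landscapes and kill-site point processes.

This module generates the three ingredients the analysis chain consumes,
with known ground truth so that every downstream estimator can be tested
for recovery:

* an elongated island polygon (~544 km² by default, the size of the
  island study system the pipeline emulates) with a few interior lakes;
* spatially autocorrelated habitat rasters at 30 m resolution (elevation,
  slope, canopy, conifer, distance-to-shore, distance-to-inland-lake);
* class-structured kill-site point patterns drawn from a log-linear
  inhomogeneous intensity over the standardized habitat layers, optionally
  with Thomas-style parent--offspring clustering.

Random fields use FFT spectral synthesis with an exponential correlation
model.  ``corr_range`` is the *practical* range: the distance at which
correlation has decayed to ~5% (three e-folding scales).  Proportion
layers (canopy, conifer) are logistic transforms of a latent Gaussian
field, so their ``mean``/``sd`` parameters are on the latent (logit)
scale.  Every operation is a pure function of its arguments including the
seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Point, Polygon

from .errors import DegenerateRegionError, SamplingFailureError
from .point_pattern import PointPattern
from .raster import LAYER_NAMES, NODATA, Grid, RasterStack
from .region import StudyRegion

__all__ = [
    "FieldParams",
    "ClusterParams",
    "SimTruth",
    "generate_island",
    "generate_habitat_fields",
    "simulate_kill_sites",
    "DEFAULT_FIELD_PARAMS",
]


@dataclass(frozen=True)
class FieldParams:
    """Gaussian random-field specification for one habitat layer.

    ``corr_range`` is the practical range in metres (correlation ~0.05);
    for proportion layers ``mean``/``sd`` are on the latent logit scale.
    """

    mean: float
    sd: float
    corr_range: float

    def __post_init__(self) -> None:
        if self.corr_range <= 0:
            raise ValueError("correlation range must be positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


#: study-condition defaults: broad smooth relief, patchier canopy/conifer
DEFAULT_FIELD_PARAMS: dict[str, FieldParams] = {
    "elevation": FieldParams(mean=220.0, sd=60.0, corr_range=9000.0),
    "canopy": FieldParams(mean=1.2, sd=1.0, corr_range=3000.0),
    "conifer": FieldParams(mean=-0.4, sd=1.2, corr_range=6000.0),
}


@dataclass(frozen=True)
class ClusterParams:
    """Thomas-style clustering: ``n_parents`` parent locations drawn from
    the habitat intensity, offspring displaced by an isotropic Gaussian of
    scale ``sigma`` (metres) with mean ``offspring_mean`` per parent.
    Offspring are thinned by the same habitat intensity, so the planted
    log-linear covariate effects hold for every point, clustered or not.
    ``parent_min_separation`` (metres) applies Matern-II-style inhibition
    to the parent draw, spreading clusters across the window instead of
    letting them clump in a single high-intensity pocket."""

    n_parents: int
    offspring_mean: float
    sigma: float
    parent_min_separation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_parents < 1:
            raise ValueError("n_parents must be >= 1")
        if self.sigma <= 0:
            raise ValueError("offspring dispersion sigma must be positive")
        if self.parent_min_separation < 0:
            raise ValueError("parent_min_separation must be non-negative")


@dataclass
class SimTruth:
    """Ground truth of the simulated kill-site processes.

    ``intensity_coefficients`` maps class label -> length-6 vector of
    log-linear coefficients over the standardized habitat layers, in the
    canonical order :data:`~killzones.raster.LAYER_NAMES`.
    """

    intensity_coefficients: dict[str, np.ndarray]
    n_points: dict[str, int]
    cluster_params: dict[str, ClusterParams | None] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for label, coefs in self.intensity_coefficients.items():
            coefs = np.asarray(coefs, dtype=float)
            if coefs.shape != (len(LAYER_NAMES),):
                raise ValueError(
                    f"class {label!r}: need {len(LAYER_NAMES)} coefficients, got {coefs.shape}"
                )
            self.intensity_coefficients[label] = coefs
        for label, n in self.n_points.items():
            if n < 1:
                raise ValueError(f"class {label!r}: n_points must be >= 1")

    def rng_for(self, class_label: str) -> np.random.Generator:
        """Deterministic per-class stream derived from the truth seed."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(class_label.encode())])
        )


# ---------------------------------------------------------------------------
# island geometry


def generate_island(seed: int, target_area: float) -> StudyRegion:
    """Generate an elongated island polygon of approximately ``target_area``.

    The boundary is a smoothed random radial perturbation of a 5:1 ellipse
    (a star-shaped, hence simple, ring), rescaled so the net area (boundary
    minus lakes) matches ``target_area``; 1-3 small interior lakes are
    carved out.  Deterministic given ``seed``.
    """
    if target_area <= 0:
        raise ValueError("target_area must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x15, 0x1A]))

    # base ellipse with 4:1 aspect; radius modulated by a low-order
    # Fourier series so the coastline is irregular but star-shaped
    n_vert = 256
    theta = np.linspace(0, 2 * np.pi, n_vert, endpoint=False)
    mod = np.ones(n_vert)
    for k in range(2, 9):
        amp = 0.18 / k
        mod += rng.normal(0, amp) * np.cos(k * theta) + rng.normal(0, amp) * np.sin(k * theta)
    mod = np.clip(mod, 0.45, 1.55)
    b = np.sqrt(target_area / (5 * np.pi))  # semi-minor of 5:1 ellipse of target area
    x = 5 * b * mod * np.cos(theta)
    y = b * mod * np.sin(theta)
    boundary = np.column_stack([x, y])

    outer = Polygon(boundary)
    lakes: list[np.ndarray] = []
    n_lakes = int(rng.integers(1, 4))
    lake_theta = np.linspace(0, 2 * np.pi, 48, endpoint=False)
    for _ in range(n_lakes):
        # polar placement well inside the coastline, radius ~0.6-1.1 km
        th = rng.uniform(0, 2 * np.pi)
        u = rng.uniform(0.25, 0.55)
        idx = int(np.round(th / (2 * np.pi) * n_vert)) % n_vert
        cx, cy = 4 * b * mod[idx] * u * np.cos(th), b * mod[idx] * u * np.sin(th)
        r = rng.uniform(0.008, 0.015) * 4 * b
        wobble = 1 + 0.15 * np.sin(3 * lake_theta + rng.uniform(0, 2 * np.pi))
        ring = np.column_stack(
            [cx + r * wobble * np.cos(lake_theta), cy + r * wobble * np.sin(lake_theta)]
        )
        lake = Polygon(ring)
        if outer.buffer(-r).contains(lake) and all(
            not Polygon(other).intersects(lake) for other in lakes
        ):
            lakes.append(ring)

    net_area = outer.area - sum(Polygon(r).area for r in lakes)
    scale = np.sqrt(target_area / net_area)
    boundary *= scale
    lakes = [r * scale for r in lakes]
    return StudyRegion(boundary=boundary, inner_lakes=lakes)


# ---------------------------------------------------------------------------
# random fields


def _gaussian_field(
    shape: tuple[int, int], cell_size: float, practical_range: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-scale stationary Gaussian field with exponential correlation
    (2-D Matern, nu = 1/2) synthesized spectrally; ``practical_range`` is
    converted to the e-folding scale rho = range / 3.  The grid is padded
    before the FFT so periodic wrap-around does not leak correlation."""
    rho = practical_range / 3.0
    pad = int(np.ceil(2 * rho / cell_size))
    ny, nx = shape[0] + 2 * pad, shape[1] + 2 * pad
    fy = np.fft.fftfreq(ny, d=cell_size)
    fx = np.fft.rfftfreq(nx, d=cell_size)
    k2 = (2 * np.pi * rho) ** 2 * (fy[:, None] ** 2 + fx[None, :] ** 2)
    amp = (1.0 + k2) ** -0.75  # sqrt of the 2-D exponential spectral density
    noise = rng.standard_normal((ny, nx))
    f = np.fft.irfft2(np.fft.rfft2(noise) * amp, s=(ny, nx))
    return f[pad : pad + shape[0], pad : pad + shape[1]]


def generate_habitat_fields(
    region: StudyRegion,
    cell_size: float = 30.0,
    field_params: dict[str, FieldParams] | None = None,
    seed: int = 0,
) -> RasterStack:
    """Build the six-layer habitat raster stack for a region.

    Elevation and the latent canopy/conifer fields are spatially
    autocorrelated Gaussian fields (empirically calibrated so the sample
    mean/sd over masked-in cells match the specification exactly); slope
    is the finite-difference gradient magnitude of elevation in degrees;
    shore and lake distances are Euclidean distance transforms of the
    region geometry.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    params = dict(DEFAULT_FIELD_PARAMS)
    if field_params:
        params.update(field_params)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF1E1D]))

    grid = Grid.covering(region, cell_size)
    X, Y = grid.center_mesh()
    outer_poly = Polygon(region.boundary)
    shapely.prepare(outer_poly)
    inside_outer = shapely.contains_xy(outer_poly, X.ravel(), Y.ravel()).reshape(X.shape)
    mask = region.contains(X.ravel(), Y.ravel()).reshape(X.shape)
    if not mask.any():
        raise DegenerateRegionError("region contains no raster cells at this resolution")

    def calibrated(p: FieldParams) -> np.ndarray:
        f = _gaussian_field(mask.shape, cell_size, p.corr_range, rng)
        v = f[mask]
        f = (f - v.mean()) / (v.std() if v.std() > 0 else 1.0)
        return p.mean + p.sd * f

    elevation = calibrated(params["elevation"])
    canopy = 1.0 / (1.0 + np.exp(-calibrated(params["canopy"])))
    conifer = 1.0 / (1.0 + np.exp(-calibrated(params["conifer"])))

    gy, gx = np.gradient(elevation, cell_size)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))

    # distance to shore: to the nearest cell outside the outer coastline
    dist_shore = ndimage.distance_transform_edt(inside_outer, sampling=cell_size)
    # distance to inland lakes: to the nearest lake-interior cell
    in_lake = inside_outer & ~mask
    if in_lake.any():
        dist_lake = ndimage.distance_transform_edt(~in_lake, sampling=cell_size)
    elif region.inner_lakes:
        # lakes smaller than a cell: exact distance to lake rings
        rings = shapely.union_all([Polygon(r).exterior for r in region.inner_lakes])
        pts = shapely.points(np.column_stack([X.ravel(), Y.ravel()]))
        dist_lake = shapely.distance(pts, rings).reshape(X.shape)
    else:
        dist_lake = np.full(mask.shape, region.diameter)

    layers = {
        "elevation": elevation,
        "slope": slope,
        "canopy": canopy,
        "conifer": conifer,
        "dist_shore": dist_shore,
        "dist_lake": dist_lake,
    }
    for name in layers:
        layer = np.asarray(layers[name], dtype=float)
        layer[~mask] = NODATA
        layers[name] = layer
    return RasterStack(grid=grid, layers=layers, mask=mask, region=region)


# ---------------------------------------------------------------------------
# point processes


def intensity_surface(fields: RasterStack, coefficients: np.ndarray) -> np.ndarray:
    """Unnormalized log-linear intensity exp(sum beta_j z_j) over the
    standardized habitat layers; 0 outside the region."""
    coefs = np.asarray(coefficients, dtype=float)
    z = fields.standardized_layers()
    log_lam = np.zeros(fields.mask.shape)
    for beta, name in zip(coefs, LAYER_NAMES):
        if beta != 0.0:
            log_lam += beta * z[name]
    lam = np.zeros_like(log_lam)
    lam[fields.mask] = np.exp(log_lam[fields.mask])
    return lam


def _thin_sample(
    n: int,
    fields: RasterStack,
    lam: np.ndarray,
    rng: np.random.Generator,
    lam_max: float,
) -> np.ndarray:
    """Rejection (thinning) sampler for the inhomogeneous intensity: draw
    uniform candidates in the region and accept with probability
    lam / (max lam * 1.001)."""
    region = fields.region
    out = np.empty((n, 2))
    filled = 0
    guard = 0
    while filled < n:
        m = max(2 * (n - filled), 32)
        cand = region.sample_uniform(m, rng)
        row, col = fields.grid.index_of(cand[:, 0], cand[:, 1])
        ok = fields.grid.inside(row, col)
        lam_c = np.zeros(m)
        lam_c[ok] = lam[row[ok], col[ok]]
        accept = rng.uniform(0, lam_max, m) < lam_c
        k = min(int(accept.sum()), n - filled)
        out[filled : filled + k] = cand[accept][:k]
        filled += k
        guard += 1
        if guard > 10_000:  # pragma: no cover - pathological intensity
            raise SamplingFailureError("thinning sampler failed to accept points")
    return out


def simulate_kill_sites(
    fields: RasterStack, truth: SimTruth, class_label: str
) -> PointPattern:
    """Draw one class of kill sites from the planted process.

    Points follow a log-linear inhomogeneous intensity over the
    standardized habitat covariates (sampled by thinning with envelope
    ``1.001 * max intensity``); when :class:`ClusterParams` are given for
    the class, parent locations are drawn from that intensity and
    offspring are displaced by an isotropic Gaussian, rejected outside the
    region, until ``n_points`` accumulate.  Deterministic given the truth
    seed and class label.
    """
    if class_label not in truth.intensity_coefficients:
        raise KeyError(f"no ground truth for class {class_label!r}")
    if fields.region is None:
        raise ValueError("raster stack must carry its region")
    rng = truth.rng_for(class_label)
    n = truth.n_points[class_label]
    lam = intensity_surface(fields, truth.intensity_coefficients[class_label])
    lam_max = float(lam.max())
    if not np.isfinite(lam_max) or lam_max <= 0:
        raise SamplingFailureError("intensity is numerically zero everywhere")
    lam_max *= 1.001  # thinning envelope safety factor

    cluster = truth.cluster_params.get(class_label)
    if cluster is None:
        pts = _thin_sample(n, fields, lam, rng, lam_max)
    else:
        if cluster.parent_min_separation > 0:
            sep2 = cluster.parent_min_separation**2
            accepted: list[np.ndarray] = []
            tries = 0
            while len(accepted) < cluster.n_parents and tries < 200:
                cand = _thin_sample(cluster.n_parents, fields, lam, rng, lam_max)
                for c in cand:
                    if len(accepted) >= cluster.n_parents:
                        break
                    if all(((c - a) ** 2).sum() >= sep2 for a in accepted):
                        accepted.append(c)
                tries += 1
            parents = np.asarray(accepted)  # may be < n_parents in tiny windows
        else:
            parents = _thin_sample(cluster.n_parents, fields, lam, rng, lam_max)
        region = fields.region
        grid = fields.grid
        chunks: list[np.ndarray] = []
        total = 0
        guard = 0
        while total < n:
            for par in parents:
                m = rng.poisson(cluster.offspring_mean)
                placed = 0
                while placed < m:
                    batch = max(2 * (m - placed), 8)
                    cand = par[None, :] + rng.normal(0, cluster.sigma, size=(batch, 2))
                    ok = region.contains(cand[:, 0], cand[:, 1])
                    row, col = grid.index_of(cand[:, 0], cand[:, 1])
                    inb = grid.inside(row, col)
                    lam_c = np.zeros(batch)
                    lam_c[inb] = lam[row[inb], col[inb]]
                    ok &= rng.uniform(0, lam_max, batch) < lam_c
                    keep = cand[ok][: m - placed]
                    if keep.size:
                        chunks.append(keep)
                        placed += keep.shape[0]
                        total += keep.shape[0]
                    guard += 1
                    if guard > 100_000:  # pragma: no cover
                        raise SamplingFailureError("offspring sampler failed to place points")
                if total >= n:
                    break
        pts = np.concatenate(chunks)[:n]

    return PointPattern(pts, np.full(n, class_label, dtype=object), fields.region)
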