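"""Buffer-based habitat covariate extraction and standardization.

Covariates are summarized as the mean of each raster layer over the cells
whose centres fall within a circular buffer around each kill site
(default 100 m diameter, 0.785 ha — the scale of daily prey movement and
of the final chase).  Buffers clipped by the coastline use only
inside-region cells.  Columns are z-scored (sample sd, n-1 denominator)
on the pooled site set of both prey classes so that standardized
coefficients are comparable between the per-class regression models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DegenerateCovariateError, ExtractionError
from .point_pattern import PointPattern
from .raster import LAYER_NAMES, RasterStack

__all__ = ["HabitatMatrix", "buffer_stats", "extract_matrix", "standardize", "unstandardize"]


@dataclass
class HabitatMatrix:
    """Site-by-covariate table with optional pooled standardization."""

    data: pd.DataFrame  # columns = LAYER_NAMES, index = site ids
    standardized: bool = False
    column_means: pd.Series | None = None
    column_sds: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("habitat matrix contains missing values")
        if self.standardized:
            if self.column_means is None or self.column_sds is None:
                raise ValueError("standardized matrix must carry means and sds")

    @property
    def site_ids(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def buffer_stats(
    site: tuple[float, float], stack: RasterStack, diameter: float = 100.0
) -> pd.Series:
    """Mean of each layer over masked-in cells whose centres lie within
    ``diameter / 2`` of the site (center-in-circle inclusion rule)."""
    if diameter <= 0:
        raise ValueError("buffer diameter must be positive")
    x, y = float(site[0]), float(site[1])
    r = diameter / 2.0
    grid = stack.grid
    # candidate index window around the site
    row_c, col_c = grid.index_of(np.array([x]), np.array([y]))
    halo = int(np.ceil(r / grid.cell_size)) + 1
    r0 = max(row_c[0] - halo, 0)
    r1 = min(row_c[0] + halo + 1, grid.nrows)
    c0 = max(col_c[0] - halo, 0)
    c1 = min(col_c[0] + halo + 1, grid.ncols)
    if r0 >= r1 or c0 >= c1:
        raise ExtractionError(f"buffer at ({x:.1f}, {y:.1f}) lies outside the raster")
    xs = grid.x_centers()[c0:c1]
    ys = grid.y_centers()[r0:r1]
    XX, YY = np.meshgrid(xs, ys)
    sel = ((XX - x) ** 2 + (YY - y) ** 2 <= r * r) & stack.mask[r0:r1, c0:c1]
    if not sel.any():
        raise ExtractionError(
            f"buffer at ({x:.1f}, {y:.1f}) contains no inside-region cells"
        )
    return pd.Series(
        {name: float(stack.layers[name][r0:r1, c0:c1][sel].mean()) for name in LAYER_NAMES}
    )


def extract_matrix(
    points: PointPattern, stack: RasterStack, diameter: float = 100.0
) -> HabitatMatrix:
    """Buffer statistics for every site of a pattern (unstandardized)."""
    rows = [buffer_stats(p, stack, diameter) for p in points.points]
    data = pd.DataFrame(rows, index=pd.RangeIndex(points.n, name="site"))
    meta = {
        "buffer_diameter_m": diameter,
        "buffer_area_ha": round(np.pi * (diameter / 2.0) ** 2 / 1e4, 2),
        "cell_inclusion": "center-in-circle",
    }
    return HabitatMatrix(data=data, meta=meta)


def standardize(matrix: HabitatMatrix) -> HabitatMatrix:
    """Z-score every column (mean 0, sample sd 1) storing the statistics
    for back-transformation.  Standardization is computed on whatever
    rows are present — callers pool both prey classes before calling so
    per-class models share one scale."""
    if matrix.standardized:
        return matrix
    if len(matrix.data) < 2:
        raise ValueError("standardization needs at least 2 rows")
    means = matrix.data.mean()
    sds = matrix.data.std(ddof=1)
    bad = sds[sds == 0]
    if len(bad):
        raise DegenerateCovariateError(
            f"constant covariate column(s): {', '.join(bad.index)}"
        )
    z = (matrix.data - means) / sds
    meta = dict(matrix.meta, standardization="pooled, sample sd (n-1)")
    return HabitatMatrix(
        data=z, standardized=True, column_means=means, column_sds=sds, meta=meta
    )


def unstandardize(matrix: HabitatMatrix) -> HabitatMatrix:
    """Invert :func:`standardize`."""
    if not matrix.standardized:
        return matrix
    data = matrix.data * matrix.column_sds + matrix.column_means
    return HabitatMatrix(data=data, standardized=False, meta=dict(matrix.meta))


def subset_rows(matrix: HabitatMatrix, keep: np.ndarray) -> HabitatMatrix:
    """Row subset preserving standardization metadata (used to split the
    pooled matrix back into per-class design matrices)."""
    return replace(matrix, data=matrix.data.loc[keep])
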