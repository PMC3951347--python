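"""Aligned raster grids for habitat covariates.

A :class:`Grid` describes an axis-aligned lattice of square cells with
centre-of-cell registration and row 0 at the north (top) edge, the usual
raster convention.  A :class:`RasterStack` bundles the six habitat layers
used throughout the package on a shared grid, together with an
inside-region mask.  Masked-out cells carry the ``NODATA`` sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .region import StudyRegion

__all__ = ["Grid", "RasterStack", "NODATA", "LAYER_NAMES"]

NODATA = -9999.0

#: canonical layer order used everywhere (tables, design matrices, reports)
LAYER_NAMES = ("elevation", "slope", "canopy", "conifer", "dist_shore", "dist_lake")


@dataclass(frozen=True)
class Grid:
    """Square-cell lattice: ``origin`` is the outer corner of the
    top-left (north-west) cell; rows run south, columns run east."""

    origin: tuple[float, float]  # (x at west edge, y at north edge)
    cell_size: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def x_centers(self) -> np.ndarray:
        x0 = self.origin[0] + self.cell_size / 2
        return x0 + self.cell_size * np.arange(self.ncols)

    def y_centers(self) -> np.ndarray:
        """Centre y per row, row 0 northernmost (descending)."""
        y0 = self.origin[1] - self.cell_size / 2
        return y0 - self.cell_size * np.arange(self.nrows)

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of shape (nrows, ncols) of cell-centre coordinates."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each point; may fall outside
        the lattice — callers clip or reject as appropriate."""
        col = np.floor((np.asarray(x, float) - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((self.origin[1] - np.asarray(y, float)) / self.cell_size).astype(int)
        return row, col

    def inside(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    @classmethod
    def covering(cls, region: StudyRegion, cell_size: float, pad_cells: int = 1) -> "Grid":
        """Smallest grid of the given resolution covering ``region`` with a
        margin of ``pad_cells`` cells on every side."""
        xmin, ymin, xmax, ymax = region.bounds
        ncols = int(np.ceil((xmax - xmin) / cell_size)) + 2 * pad_cells
        nrows = int(np.ceil((ymax - ymin) / cell_size)) + 2 * pad_cells
        origin = (xmin - pad_cells * cell_size, ymax + pad_cells * cell_size)
        return cls(origin=origin, cell_size=cell_size, nrows=nrows, ncols=ncols)


@dataclass
class RasterStack:
    """Aligned habitat layers on one grid with an inside-region mask.

    Layers (units): elevation (m), slope (degrees), canopy (proportion),
    conifer (proportion), dist_shore (m), dist_lake (m).  ``mask`` is True
    on cells whose centre lies inside the study region; every layer carries
    :data:`NODATA` on masked-out cells.
    """

    grid: Grid
    layers: dict[str, np.ndarray]
    mask: np.ndarray
    region: StudyRegion | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        shape = (self.grid.nrows, self.grid.ncols)
        if self.mask.shape != shape:
            raise ValueError("mask shape does not match grid")
        for name, layer in self.layers.items():
            if layer.shape != shape:
                raise ValueError(f"layer {name!r} shape does not match grid")

    @property
    def n_inside(self) -> int:
        return int(self.mask.sum())

    def masked(self, name: str) -> np.ndarray:
        """Values of one layer over masked-in cells (1-D)."""
        return self.layers[name][self.mask]

    def standardized_layers(self, names=LAYER_NAMES) -> dict[str, np.ndarray]:
        """Z-scored copies of the layers (statistics over masked-in cells);
        masked-out cells are 0.  Used by the log-linear intensity model."""
        out = {}
        for name in names:
            vals = self.masked(name)
            sd = vals.std()
            if sd == 0:
                raise ValueError(f"layer {name!r} is constant; cannot standardize")
            z = np.zeros_like(self.layers[name])
            z[self.mask] = (vals - vals.mean()) / sd
            out[name] = z
        return out

    def value_at(self, name: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell lookup of one layer at point coordinates."""
        row, col = self.grid.index_of(x, y)
        ok = self.grid.inside(row, col)
        vals = np.full(np.shape(row), NODATA, dtype=float)
        vals[ok] = self.layers[name][row[ok], col[ok]]
        return vals
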