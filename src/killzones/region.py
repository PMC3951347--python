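"""Planar study region: the bounded observation window for all analyses.

A :class:`StudyRegion` is an island-like polygon in planar metric
coordinates, optionally with interior lakes that are excluded from the
observation window.  All point patterns, rasters and density surfaces in
this package live inside one of these windows.  No geodesy is performed:
coordinates are metres on an arbitrary planar datum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

__all__ = ["StudyRegion"]


@dataclass
class StudyRegion:
    """Bounded planar observation window (outer ring minus inner lakes).

    Parameters
    ----------
    boundary
        Outer ring as an ``(m, 2)`` array of vertices in metres.  The ring
        must be simple (non-self-intersecting); it need not be explicitly
        closed.
    inner_lakes
        Zero or more interior rings, each strictly inside the boundary.
        Lake interiors are outside the observation window.
    """

    boundary: np.ndarray
    inner_lakes: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=float)
        self.inner_lakes = [np.asarray(r, dtype=float) for r in self.inner_lakes]
        poly = Polygon(self.boundary, holes=[r for r in self.inner_lakes])
        if not poly.is_valid:
            raise ValueError("region rings are not simple or lakes overlap the boundary")
        if poly.area <= 0:
            raise ValueError("region has non-positive area")
        outer = Polygon(self.boundary)
        for r in self.inner_lakes:
            if not outer.contains(Polygon(r)):
                raise ValueError("inner lake not strictly inside the boundary")
        self._polygon = poly
        shapely.prepare(self._polygon)

    @property
    def polygon(self) -> Polygon:
        """Shapely polygon (outer ring with lake holes)."""
        return self._polygon

    @property
    def area(self) -> float:
        """Window area in m² (boundary area minus lake areas)."""
        return float(self._polygon.area)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer ring."""
        return self._polygon.bounds

    @property
    def diameter(self) -> float:
        """Diagonal of the bounding box — an upper bound on pair distances."""
        xmin, ymin, xmax, ymax = self.bounds
        return float(np.hypot(xmax - xmin, ymax - ymin))

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized point-in-window test (lake interiors are outside)."""
        return shapely.contains_xy(self._polygon, np.asarray(x, float), np.asarray(y, float))

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` uniform points in the window by bounding-box rejection.

        This is the CSR (homogeneous Poisson, conditioned on n) generator
        used by every Monte-Carlo null in the package.
        """
        xmin, ymin, xmax, ymax = self.bounds
        out = np.empty((n, 2))
        filled = 0
        # acceptance rate = area / bbox area; batch accordingly
        rate = max(self.area / ((xmax - xmin) * (ymax - ymin)), 1e-3)
        while filled < n:
            m = int((n - filled) / rate * 1.2) + 8
            xs = rng.uniform(xmin, xmax, m)
            ys = rng.uniform(ymin, ymax, m)
            ok = self.contains(xs, ys)
            k = min(int(ok.sum()), n - filled)
            out[filled : filled + k, 0] = xs[ok][:k]
            out[filled : filled + k, 1] = ys[ok][:k]
            filled += k
        return out

    def __geo_interface__(self):  # pragma: no cover - convenience
        return self._polygon.__geo_interface__
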