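"""Tests of the synthetic landscape and point-process generators."""

import warnings

import numpy as np
import pytest

from killzones import (
    ClusterParams,
    FieldParams,
    PointPattern,
    SimTruth,
    generate_habitat_fields,
    generate_island,
    simulate_kill_sites,
)
from killzones.errors import SamplingFailureError
from killzones.raster import LAYER_NAMES, NODATA


def segments_cross(p1, p2, q1, q2) -> bool:
    """Proper-intersection test for two segments (shared endpoints allowed)."""

    def orient(a, b, c):
        return np.sign((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))

    o1, o2 = orient(p1, p2, q1), orient(p1, p2, q2)
    o3, o4 = orient(q1, q2, p1), orient(q1, q2, p2)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


class TestIsland:
    def test_area_within_five_percent_of_target(self):
        for seed in range(6):
            region = generate_island(seed, 544e6)
            assert 516.8e6 <= region.area <= 571.2e6

    def test_deterministic_vertices(self):
        a = generate_island(1, 544e6)
        b = generate_island(1, 544e6)
        assert np.array_equal(a.boundary, b.boundary)
        assert len(a.inner_lakes) == len(b.inner_lakes)
        for ra, rb in zip(a.inner_lakes, b.inner_lakes):
            assert np.array_equal(ra, rb)

    def test_boundary_is_simple_by_brute_force(self):
        """All-pairs segment-intersection oracle finds zero crossings."""
        region = generate_island(2, 544e6)
        ring = np.vstack([region.boundary, region.boundary[0]])
        segs = [(ring[i], ring[i + 1]) for i in range(len(ring) - 1)]
        crossings = sum(
            segments_cross(*segs[i], *segs[j])
            for i in range(len(segs))
            for j in range(i + 2, len(segs))
            if not (i == 0 and j == len(segs) - 1)
        )
        assert crossings == 0

    def test_elongated_with_interior_lakes(self):
        region = generate_island(5, 544e6)
        xmin, ymin, xmax, ymax = region.bounds
        assert (xmax - xmin) / (ymax - ymin) >= 3.0
        assert 0 <= len(region.inner_lakes) <= 3

    def test_rejects_nonpositive_area(self):
        with pytest.raises(ValueError):
            generate_island(0, -1.0)


class TestHabitatFields:
    def test_proportion_layers_bounded(self, island_fields):
        for name in ("canopy", "conifer"):
            vals = island_fields.masked(name)
            assert vals.min() >= 0 and vals.max() <= 1

    def test_boundary_cells_close_to_shore(self, island_fields):
        """Masked-in cells adjacent to masked-out ones are within one
        cell diagonal of the shoreline distance origin."""
        import shapely
        from shapely.geometry import Polygon

        mask = island_fields.mask
        ds = island_fields.layers["dist_shore"]
        cs = island_fields.grid.cell_size
        X, Y = island_fields.grid.center_mesh()
        outer = Polygon(island_fields.region.boundary)
        inside_outer = shapely.contains_xy(outer, X.ravel(), Y.ravel()).reshape(mask.shape)
        # coastline-adjacent: inside the outer ring, southern neighbour outside
        south_out = ~np.pad(inside_outer, 1)[2:, 1:-1]
        edge = mask & inside_outer & south_out
        assert edge.any()
        assert np.all(ds[edge] <= cs * np.sqrt(2) + 1e-9)

    def test_nonnegative_distances_and_slope(self, island_fields):
        for name in ("dist_shore", "dist_lake", "slope"):
            assert island_fields.masked(name).min() >= 0

    def test_nodata_outside_region(self, island_fields):
        for name in LAYER_NAMES:
            assert np.all(island_fields.layers[name][~island_fields.mask] == NODATA)

    def test_field_calibration_mean_and_variance(self, full_island):
        """Sample moments over masked-in cells match the specification
        (elevation is the untransformed Gaussian layer)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack = generate_habitat_fields(full_island, cell_size=120.0, seed=9)
        assert stack.mask.sum() >= 200 * 200 / 2
        elev = stack.masked("elevation")
        assert abs(elev.mean() - 220.0) <= 0.1 * 220.0
        assert abs(elev.std() - 60.0) <= 0.1 * 60.0

    def test_variogram_reaches_sill_within_twice_range(self, full_island):
        """Empirical elevation variogram hits ~95% of its sill inside 2x
        the specified (practical) correlation range."""
        rng_range = 6000.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack = generate_habitat_fields(
                full_island, 120.0,
                {"elevation": FieldParams(0.0, 1.0, rng_range)}, seed=4,
            )
        elev = stack.layers["elevation"]
        mask = stack.mask
        cs = stack.grid.cell_size
        sill = stack.masked("elevation").var()
        # semivariance along rows at lag = 2x range
        lag = int(round(2 * rng_range / cs))
        a, b = elev[:, :-lag], elev[:, lag:]
        ok = mask[:, :-lag] & mask[:, lag:]
        gamma = 0.5 * np.mean((a[ok] - b[ok]) ** 2)
        # expectation is ~99.8% of the sill at twice the practical range;
        # 88% distinguishes the practical-range convention from an
        # e-folding-scale misreading (which would give ~86% at this lag)
        assert gamma >= 0.88 * sill

    def test_degenerate_region_raises(self):
        tiny = np.array([[0, 0], [1.0, 0], [1.0, 1.0], [0, 1.0]])
        from killzones import StudyRegion
        from killzones.errors import DegenerateRegionError

        with pytest.raises(DegenerateRegionError):
            generate_habitat_fields(StudyRegion(tiny), cell_size=30.0, seed=0)


def _csr_truth(n, seed, label="generic"):
    return SimTruth(
        intensity_coefficients={label: np.zeros(6)},
        n_points={label: n},
        cluster_params={label: None},
        seed=seed,
    )


class TestKillSiteSimulator:
    def test_points_inside_region(self, island_fields):
        truth = _csr_truth(200, 7)
        pat = simulate_kill_sites(island_fields, truth, "generic")
        assert pat.n == 200
        assert island_fields.region.contains(pat.points[:, 0], pat.points[:, 1]).all()

    def test_deterministic_given_truth(self, island_fields):
        truth = _csr_truth(50, 11)
        p1 = simulate_kill_sites(island_fields, truth, "generic")
        p2 = simulate_kill_sites(island_fields, truth, "generic")
        assert np.array_equal(p1.points, p2.points)

    def test_csr_nearest_neighbour_closed_form(self, island_fields):
        """With all coefficients zero the process is CSR: the mean
        nearest-neighbour distance of interior points (border-corrected)
        matches 0.5 / sqrt(intensity) within 3 Monte-Carlo SEs."""
        from scipy.spatial import cKDTree

        region = island_fields.region
        n = 300
        lam = n / region.area
        expect = 0.5 / np.sqrt(lam)
        margin = 3.0 * expect  # P(NN > margin) ~ 1e-3: truncation bias negligible
        boundary_line = region.polygon.boundary
        means = []
        for rep in range(200):
            truth = _csr_truth(n, 100_000 + rep)
            pts = simulate_kill_sites(island_fields, truth, "generic").points
            d, _ = cKDTree(pts).query(pts, k=2)
            nn = d[:, 1]
            import shapely

            interior = shapely.distance(
                shapely.points(pts), boundary_line
            ) > margin
            if interior.sum() >= 10:
                means.append(nn[interior].mean())
        grand = np.mean(means)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(grand - expect) <= 3 * se

    def test_positive_conifer_coefficient_enriches_conifer(self, island_fields):
        """Strong conifer affinity puts points on above-average conifer in
        >= 95% of seeded replicates (brute-force resampling check)."""
        base = island_fields.masked("conifer").mean()
        coefs = np.zeros(6)
        coefs[LAYER_NAMES.index("conifer")] = 2.0
        hits = 0
        for rep in range(100):
            truth = SimTruth(
                intensity_coefficients={"c": coefs},
                n_points={"c": 100},
                cluster_params={"c": None},
                seed=50_000 + rep,
            )
            pat = simulate_kill_sites(island_fields, truth, "c")
            at_points = island_fields.value_at("conifer", pat.points[:, 0], pat.points[:, 1])
            hits += at_points.mean() > base
        assert hits >= 95

    def test_clustered_points_respect_region(self, island_fields):
        truth = SimTruth(
            intensity_coefficients={"k": np.zeros(6)},
            n_points={"k": 150},
            cluster_params={"k": ClusterParams(5, 30.0, 500.0)},
            seed=21,
        )
        pat = simulate_kill_sites(island_fields, truth, "k")
        assert pat.n == 150
        assert island_fields.region.contains(pat.points[:, 0], pat.points[:, 1]).all()

    def test_zero_intensity_everywhere_raises(self, island_fields):
        coefs = np.zeros(6)
        coefs[0] = -1e4  # exp underflows to zero across the island
        truth = SimTruth(
            intensity_coefficients={"z": coefs},
            n_points={"z": 10},
            cluster_params={"z": None},
            seed=0,
        )
        with pytest.raises(SamplingFailureError):
            simulate_kill_sites(island_fields, truth, "z")
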