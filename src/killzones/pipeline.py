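"""End-to-end two-class kill-zone analysis.

Stages per prey class: Ripley L clustering test with CSR envelope ->
LSCV bandwidth -> KDE surface -> core (kill-zone) delineation -> buffer
habitat extraction -> full spatial GLS fit -> residual diagnostics ->
reduced refit.  Cross-class products: pooled standardization, the zone
summary table, and the pooled enrichment chi-square comparing the kill
fraction inside the zones with their area fraction.

Everything is deterministic given the configuration seed: per-stage
random streams are spawned from it and recorded in the report bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as kio
from .config import DISPLAY_ALIASES, RunConfig
from .habitat import HabitatMatrix, extract_matrix, standardize, subset_rows
from .kde import (CoreArea, core_percentile, extract_core, kde_surface,
                  percentile_transform, select_bandwidth)
from .point_pattern import Envelope, KEstimate, PointPattern, csr_envelope, estimate_k
from .raster import RasterStack
from .region import StudyRegion
from .regression import (DiagnosticsReport, RegressionResult, diagnostics,
                         drop_and_refit, fit_gls)
from .synthetic import SimTruth, generate_habitat_fields, generate_island, simulate_kill_sites

__all__ = ["ClassReport", "ReportBundle", "enrichment_chisq", "run_pipeline"]

log = logging.getLogger("killzones")


def enrichment_chisq(n_in: int, n_total: int, area_fraction: float) -> tuple[float, float]:
    """One-degree-of-freedom goodness-of-fit test of kill counts inside
    the kill zones against the zones' share of the island's area:

        chi2 = (n_in - e)^2 / e + ((n_total - n_in) - (n_total - e))^2 / (n_total - e)

    with expectation e = area_fraction * n_total; p from the upper tail
    of chi-square with 1 df.
    """
    if not 0 <= n_in <= n_total:
        raise ValueError("need 0 <= n_in <= n_total")
    if not 0 < area_fraction < 1:
        raise ValueError("area_fraction must be strictly between 0 and 1")
    if n_total == 0:
        raise ValueError("n_total must be positive")
    e = area_fraction * n_total
    chi2 = (n_in - e) ** 2 / e + (n_in - e) ** 2 / (n_total - e)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class ClassReport:
    """All per-class products of one pipeline run."""

    label: str
    pattern: PointPattern
    k_estimate: KEstimate
    envelope: Envelope
    bandwidth: float
    core: CoreArea
    core_source: str  # "estimated" | "borrowed" | "default"
    y_percentile: np.ndarray
    habitat: HabitatMatrix
    fit_full: RegressionResult
    fit_reduced: RegressionResult
    residual_diagnostics: DiagnosticsReport

    def zone_summary(self) -> dict:
        inside = int(
            self.core.contains_points(
                self.pattern.points[:, 0], self.pattern.points[:, 1],
                grid=self._grid,
            ).sum()
        )
        return {
            "class": self.label,
            "display": DISPLAY_ALIASES.get(self.label, self.label),
            "n_points": self.pattern.n,
            "core_percentile": self.core.percentile,
            "core_source": self.core_source,
            "area_km2": self.core.total_area / 1e6,
            "n_polygons": self.core.n_polygons,
            "points_inside": inside,
        }

    _grid: object = field(default=None, repr=False)


@dataclass
class ReportBundle:
    """Full result set of one pipeline run plus provenance."""

    config: dict
    seed: int
    region: StudyRegion
    classes: dict[str, ClassReport]
    zone_table: pd.DataFrame
    enrichment: dict
    fields: RasterStack | None = None
    truth: SimTruth | None = None

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def write(self, out_dir: str | Path, rasters: bool = False, plots: bool = True) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        prov = {"config": self.config, "seed": self.seed, "config_hash": self.config_hash,
                "core_rule": "max enrichment among MC-significant isopleths "
                             "(package operationalization)"}
        (out / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))
        kio.write_region_geojson(self.region, out / "region.geojson")
        all_pts = None
        for label, rep in self.classes.items():
            kio.write_points_csv(rep.pattern, out / f"points_{label}.csv")
            ktab = pd.DataFrame({
                "t_m": rep.envelope.t_grid,
                "K": rep.k_estimate.k_hat,
                "L": rep.k_estimate.l_hat,
                "lower": rep.envelope.lower,
                "upper": rep.envelope.upper,
                "classification": rep.envelope.classification,
            })
            ktab.to_csv(out / f"ripley_{label}.csv", index=False)
            kio.write_core_geojson(
                rep.core.polygons, out / f"core_{label}.geojson",
                {"class": label, "percentile": rep.core.percentile,
                 "source": rep.core_source, "config_hash": self.config_hash},
            )
            for tag, fit in (("full", rep.fit_full), ("reduced", rep.fit_reduced)):
                tab = pd.DataFrame({
                    "term": fit.terms,
                    "beta": fit.params.to_numpy(),
                    "se": fit.se.to_numpy(),
                    "removed": [t in fit.removed for t in fit.terms],
                })
                tab.to_csv(out / f"model_{label}_{tag}.csv", index=False)
            rep.habitat.data.to_csv(out / f"habitat_{label}.csv")
            all_pts = rep.pattern if all_pts is None else all_pts
        self.zone_table.to_csv(out / "zones.csv", index=False)
        (out / "enrichment.json").write_text(json.dumps(self.enrichment, indent=2))
        if rasters and self.fields is not None:
            kio.write_raster_stack(self.fields, out / "rasters")
        if plots:
            from . import plots as kplots

            for label, rep in self.classes.items():
                kplots.envelope_plot(rep.envelope, out / f"envelope_{label}.png",
                                     title=DISPLAY_ALIASES.get(label, label))
            kplots.coefficient_plot(
                {DISPLAY_ALIASES.get(l, l): r.fit_full for l, r in self.classes.items()},
                out / "coefficients.png",
            )


def _seed_for(base: int, *tags: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(base), *tags])


def _load_user_data(config: RunConfig):
    for name, path in (("points", config.points_path), ("region", config.region_path),
                       ("rasters", config.rasters_dir)):
        if path is None or not Path(path).exists():
            raise ValueError(f"user-data mode: {name} input missing ({path})")
    region = kio.read_region_geojson(config.region_path)
    fields = kio.read_raster_stack(config.rasters_dir, region)
    pattern = kio.read_points_csv(config.points_path, region)
    return region, fields, pattern, None


def _build_synthetic(config: RunConfig):
    syn = config.synthetic
    region = generate_island(config.seed, syn.target_area_km2 * 1e6)
    fields = generate_habitat_fields(region, syn.cell_size_m, syn.fields, seed=config.seed)
    truth = SimTruth(
        intensity_coefficients={l: np.asarray(c.coef_vector())
                                for l, c in syn.classes.items()},
        n_points={l: c.n_points for l, c in syn.classes.items()},
        cluster_params={l: c.cluster for l, c in syn.classes.items()},
        seed=config.seed,
    )
    pats = [simulate_kill_sites(fields, truth, label) for label in syn.classes]
    pattern = PointPattern(
        np.concatenate([p.points for p in pats]),
        np.concatenate([p.labels for p in pats]),
        region,
    )
    return region, fields, pattern, truth


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> ReportBundle:
    """Execute the full two-class analysis and return the report bundle.

    Any stage failure aborts with the stage name attached to the raised
    error.  With ``out_dir`` given, all External-Interface files (tables,
    GeoJSON, JSON report, plots) are written there.
    """
    t0 = time.time()
    stage = "input"
    try:
        if config.mode == "synthetic":
            region, fields, pattern, truth = _build_synthetic(config)
        elif config.mode == "user-data":
            region, fields, pattern, truth = _load_user_data(config)
        else:
            raise ValueError(f"unknown mode {config.mode!r}")
        labels = pattern.class_labels
        ana = config.analysis
        log.info("inputs ready (%d classes, %d points) in %.1fs",
                 len(labels), pattern.n, time.time() - t0)

        # --- clustering tests -------------------------------------------
        stage = "point_pattern"
        if ana.t_max_m is not None:
            t_grid = np.arange(ana.t_spacing_m, ana.t_max_m + ana.t_spacing_m / 2,
                               ana.t_spacing_m)
        else:
            t_grid = None
        envs: dict[str, Envelope] = {}
        kests: dict[str, KEstimate] = {}
        for i, label in enumerate(labels):
            sub = pattern.subset(label)
            kests[label] = estimate_k(sub, t_grid, correction=ana.correction)
            envs[label] = csr_envelope(
                sub, n_sims=ana.n_sims, alpha=ana.alpha,
                seed=_seed_for(config.seed, 1, i), t_grid=t_grid,
                correction=ana.correction,
            )
            log.info("envelope %s: clustered up to %.0f m", label,
                     envs[label].max_clustered_distance())

        # --- KDE surfaces -----------------------------------------------
        stage = "kde"
        surfaces, psurfs, bands = {}, {}, {}
        for label in labels:
            sub = pattern.subset(label)
            h = select_bandwidth(sub)
            bands[label] = h
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # coarse-grid warning at desk scale
                surfaces[label] = kde_surface(sub, h, cell_size=ana.kde_cell_size_m)
            psurfs[label] = percentile_transform(surfaces[label])
            log.info("KDE %s: LSCV bandwidth %.0f m", label, h)

        # --- core delineation -------------------------------------------
        stage = "core"
        ref = ana.core_reference_class if ana.core_reference_class in labels else labels[-1]
        p_ref = core_percentile(
            pattern.subset(ref), surfaces[ref], n_iter=ana.n_iter,
            seed=_seed_for(config.seed, 2), alpha=ana.core_alpha,
        )
        cores, core_src = {}, {}
        if p_ref is None:
            log.warning("no significant core for %s; falling back to the default "
                        "%.0f%% isopleth", ref, ana.default_core_percentile)
            p_ref, src_ref = ana.default_core_percentile, "default"
        else:
            src_ref = "estimated"
        for label in labels:
            cores[label] = extract_core(psurfs[label], p_ref)
            core_src[label] = src_ref if label == ref else "borrowed"

        # --- habitat + regression ---------------------------------------
        stage = "habitat"
        # a buffer narrower than the cell diagonal can contain no cell
        # centres; widen it to the raster's resolution limit if needed
        buffer_d = ana.buffer_diameter_m
        min_d = fields.grid.cell_size * np.sqrt(2.0) * 1.01
        if buffer_d < min_d:
            log.warning("buffer diameter %.0f m below raster resolution; using %.0f m",
                        buffer_d, min_d)
            buffer_d = min_d
        pooled = extract_matrix(pattern, fields, buffer_d)
        pooled_std = standardize(pooled)

        stage = "regression"
        reports: dict[str, ClassReport] = {}
        for i, label in enumerate(labels):
            keep = pattern.labels == label
            sub = pattern.subset(label)
            X = subset_rows(pooled_std, keep)
            y = psurfs[label].value_at(sub.points[:, 0], sub.points[:, 1])
            fit = fit_gls(y, X, sub.points, seed=config.seed + i,
                          family=ana.covariance_family, class_label=label)
            diag = diagnostics(fit, sub.points)
            reduced = drop_and_refit(fit, y, X, sub.points, rule=ana.refit_rule)
            reports[label] = ClassReport(
                label=label, pattern=sub, k_estimate=kests[label],
                envelope=envs[label], bandwidth=bands[label], core=cores[label],
                core_source=core_src[label], y_percentile=y, habitat=X,
                fit_full=fit, fit_reduced=reduced, residual_diagnostics=diag,
                _grid=psurfs[label].grid,
            )

        # --- zone summary + enrichment ----------------------------------
        stage = "report"
        zone_rows = [reports[label].zone_summary() for label in labels]
        zone_table = pd.DataFrame(zone_rows)
        union_cells = np.zeros_like(next(iter(cores.values())).cell_mask)
        for label in labels:
            union_cells |= cores[label].cell_mask
        n_region_cells = int(psurfs[labels[0]].mask.sum())
        area_fraction = float(union_cells.sum()) / n_region_cells
        n_in = int(zone_table["points_inside"].sum())
        n_total = int(zone_table["n_points"].sum())
        chi2, pval = enrichment_chisq(n_in, n_total, area_fraction)
        per_class = {}
        for label in labels:
            af = float(cores[label].cell_mask.sum()) / n_region_cells
            row = reports[label].zone_summary()
            c2, pp = enrichment_chisq(row["points_inside"], row["n_points"], af)
            per_class[label] = {"chi2": c2, "p": pp, "area_fraction": af,
                                "n_in": row["points_inside"], "n_total": row["n_points"]}
        enrichment = {
            "pooled": {"chi2": chi2, "p": pval, "area_fraction": area_fraction,
                       "n_in": n_in, "n_total": n_total},
            "per_class": per_class,
            "construction": "pooled union of per-class zones; per-class variants included",
        }

        bundle = ReportBundle(
            config=config.to_dict(), seed=config.seed, region=region,
            classes=reports, zone_table=zone_table, enrichment=enrichment,
            fields=fields, truth=truth,
        )
        if out_dir is not None:
            bundle.write(out_dir)
        log.info("pipeline done in %.1fs", time.time() - t0)
        return bundle
    except Exception as exc:
        try:
            wrapped = type(exc)(f"[stage: {stage}] {exc}")
        except Exception:  # exception types with exotic constructors
            wrapped = RuntimeError(f"[stage: {stage}] {exc}")
        raise wrapped from exc
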