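"""Run configuration: study conditions for the synthetic landscape and
settings for every analysis stage, loadable from YAML.

The synthetic defaults are the package's study conditions: a 544 km²
elongated island, 30 m habitat rasters, and two kill-site processes of
106 and 109 points — one ("class_a", displayed as *prime*) spread in many
small near-shore clusters with positive canopy and negative conifer
affinity, one ("class_b", displayed as *senescent*) concentrated in a
single inland high-elevation / high-conifer zone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .raster import LAYER_NAMES
from .synthetic import DEFAULT_FIELD_PARAMS, ClusterParams, FieldParams

__all__ = ["ClassProcess", "SyntheticConfig", "AnalysisConfig", "RunConfig"]

DISPLAY_ALIASES = {"class_a": "prime", "class_b": "senescent"}


@dataclass
class ClassProcess:
    """Ground-truth process for one prey class (coefficients over the
    standardized layers in canonical order)."""

    n_points: int
    coefficients: dict[str, float]
    cluster: ClusterParams | None = None

    def coef_vector(self):
        return [float(self.coefficients.get(name, 0.0)) for name in LAYER_NAMES]


def _default_classes() -> dict[str, ClassProcess]:
    return {
        "class_a": ClassProcess(
            n_points=106,
            coefficients={"canopy": 0.8, "conifer": -2.5, "dist_shore": -1.0},
            cluster=ClusterParams(n_parents=25, offspring_mean=4.2, sigma=1800.0,
                                  parent_min_separation=3500.0),
        ),
        "class_b": ClassProcess(
            n_points=109,
            coefficients={"elevation": 2.5, "conifer": 1.5, "dist_shore": 0.5},
            cluster=ClusterParams(n_parents=1, offspring_mean=109.0, sigma=2200.0),
        ),
    }


@dataclass
class SyntheticConfig:
    target_area_km2: float = 544.0
    cell_size_m: float = 30.0
    fields: dict[str, FieldParams] = field(
        default_factory=lambda: dict(DEFAULT_FIELD_PARAMS)
    )
    classes: dict[str, ClassProcess] = field(default_factory=_default_classes)


@dataclass
class AnalysisConfig:
    t_spacing_m: float = 1000.0
    t_max_m: float | None = None  # None -> half the window diameter
    n_sims: int = 99
    alpha: float = 0.01
    correction: str = "isotropic"
    kde_cell_size_m: float = 100.0
    n_iter: int = 10_000
    core_alpha: float = 0.05
    core_reference_class: str = "class_b"
    default_core_percentile: float = 30.0
    buffer_diameter_m: float = 100.0
    covariance_family: str = "exponential"
    refit_rule: str = "se"


@dataclass
class RunConfig:
    mode: str = "synthetic"  # "synthetic" | "user-data"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    # user-data mode inputs
    points_path: str | None = None
    region_path: str | None = None
    rasters_dir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls()
        cfg.mode = raw.get("mode", cfg.mode)
        cfg.seed = int(raw.get("seed", cfg.seed))
        cfg.points_path = raw.get("points")
        cfg.region_path = raw.get("region")
        cfg.rasters_dir = raw.get("rasters")
        syn = raw.get("synthetic", {})
        if "target_area_km2" in syn:
            cfg.synthetic.target_area_km2 = float(syn["target_area_km2"])
        if "cell_size_m" in syn:
            cfg.synthetic.cell_size_m = float(syn["cell_size_m"])
        for name, fp in syn.get("fields", {}).items():
            cfg.synthetic.fields[name] = FieldParams(**fp)
        if "classes" in syn:
            cfg.synthetic.classes = {}
            for label, spec in syn["classes"].items():
                cluster = spec.get("cluster")
                cfg.synthetic.classes[label] = ClassProcess(
                    n_points=int(spec["n_points"]),
                    coefficients=dict(spec.get("coefficients", {})),
                    cluster=ClusterParams(**cluster) if cluster else None,
                )
        ana = raw.get("analysis", {})
        for key, val in ana.items():
            attr = key if hasattr(cfg.analysis, key) else None
            if attr is None:
                raise ValueError(f"unknown analysis setting {key!r}")
            setattr(cfg.analysis, attr, val)
        return cfg
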