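"""Configuration types for gating, QC, simulation and pipeline runs.

All spatial coordinates and scale parameters are in micrometres (µm);
areas derived from them are reported in mm². Intensity-model parameters
live on the natural-log scale of the fluorescence intensity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

MARKERS = ("PanCK", "CD8", "CD103", "PD1", "CD69", "TCF1")

#: required-positive markers per ground-truth phenotype label
PHENOTYPE_PROFILES: dict[str, frozenset[str]] = {
    "tumor": frozenset({"PanCK"}),
    "naive_trm": frozenset({"CD8", "CD103"}),
    "exhausted_trm": frozenset({"CD8", "CD103", "PD1"}),
    "pd1_cd8": frozenset({"CD8", "PD1"}),
    "cd8": frozenset({"CD8"}),
    "other": frozenset(),
}


class ConfigurationError(ValueError):
    """Raised when a configuration violates a documented precondition."""


class SchemaError(KeyError):
    """Raised when an input table is missing a required column."""


@dataclass(frozen=True)
class PhenotypeRule:
    """One entry of the gating hierarchy: required-positive and required-negative markers."""

    name: str
    positive: tuple[str, ...]
    negative: tuple[str, ...] = ()

    def markers(self) -> set[str]:
        return set(self.positive) | set(self.negative)


#: Hierarchical gating order. PanCK is evaluated first so the tumor label
#: excludes every immune label; within CD8+ cells the CD103/PD-1 splits
#: define the exhausted (PD-1+CD103+) and naive (PD-1−CD103+) resident
#: subsets before the residual CD8 labels.
DEFAULT_HIERARCHY: tuple[PhenotypeRule, ...] = (
    PhenotypeRule("tumor", positive=("PanCK",)),
    PhenotypeRule("exhausted_trm", positive=("CD8", "CD103", "PD1"), negative=("PanCK",)),
    PhenotypeRule("naive_trm", positive=("CD8", "CD103"), negative=("PanCK", "PD1")),
    PhenotypeRule("pd1_cd8", positive=("CD8", "PD1"), negative=("PanCK", "CD103")),
    PhenotypeRule("cd8", positive=("CD8",), negative=("PanCK", "CD103", "PD1")),
)

OTHER_LABEL = "other"


@dataclass
class GatingConfig:
    """Marker intensity thresholds plus the ordered phenotype hierarchy.

    Thresholds are required inputs: positivity cuts are calibrated against
    negative controls on real panels, so no numeric defaults ship. Use
    :func:`trmspatial.phenotyping.estimate_thresholds` to derive data-driven
    cuts from a bimodal intensity distribution.
    """

    thresholds: dict[str, float]
    hierarchy: tuple[PhenotypeRule, ...] = DEFAULT_HIERARCHY

    def __post_init__(self) -> None:
        if isinstance(self.hierarchy, list):
            self.hierarchy = tuple(
                r if isinstance(r, PhenotypeRule) else PhenotypeRule(**r) for r in self.hierarchy
            )
        referenced = set().union(*(r.markers() for r in self.hierarchy)) if self.hierarchy else set()
        missing = referenced - set(self.thresholds)
        if missing:
            raise ConfigurationError(
                f"hierarchy references markers without thresholds: {sorted(missing)}"
            )
        for m, t in self.thresholds.items():
            if not (t > 0 and math.isfinite(t)):
                raise ConfigurationError(f"threshold for {m!r} must be a positive finite number")

    @property
    def vocabulary(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.hierarchy)

    def to_dict(self) -> dict:
        return {
            "thresholds": dict(self.thresholds),
            "hierarchy": [asdict(r) for r in self.hierarchy],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GatingConfig":
        hierarchy = tuple(
            PhenotypeRule(r["name"], tuple(r["positive"]), tuple(r.get("negative", ())))
            for r in d.get("hierarchy", [])
        ) or DEFAULT_HIERARCHY
        return cls(thresholds=dict(d["thresholds"]), hierarchy=hierarchy)


@dataclass(frozen=True)
class QCThresholds:
    """Single-cell RNA quality-control cuts.

    Feature bounds are inclusive ("between 200 and 3000"); the fraction
    bounds are strict upper bounds.
    """

    min_features: int = 200
    max_features: int = 3000
    max_mito_fraction: float = 0.10
    max_erythroid_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.min_features > self.max_features:
            raise ConfigurationError("min_features must not exceed max_features")
        for f in (self.max_mito_fraction, self.max_erythroid_fraction):
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError("fraction thresholds must lie in [0, 1]")


@dataclass(frozen=True)
class MarkerMixture:
    """Two-component truncated log-normal intensity model for one marker.

    ``mu_neg``/``mu_pos`` are component means on the log-intensity scale,
    ``sigma`` the shared spread, ``trunc_sd`` the truncation radius in units
    of sigma. Truncation keeps the two populations disjoint whenever the
    separation exceeds ``2 * trunc_sd * sigma``, mirroring the clean
    bimodality of a well-unmixed panel.
    """

    mu_neg: float = 2.0
    mu_pos: float = 4.4
    sigma: float = 0.4
    trunc_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.trunc_sd <= 0:
            raise ConfigurationError("sigma and trunc_sd must be strictly positive")
        if self.mu_pos <= self.mu_neg:
            raise ConfigurationError("mu_pos must exceed mu_neg")

    @property
    def midpoint_intensity(self) -> float:
        """Intensity at the midpoint of the two log-scale component means."""
        return math.exp(0.5 * (self.mu_neg + self.mu_pos))


def default_intensity_model() -> dict[str, MarkerMixture]:
    return {m: MarkerMixture() for m in MARKERS}


@dataclass(frozen=True)
class SurvivalModel:
    """Proportional-hazards linkage for the synthetic cohort.

    ``beta`` maps spatial-feature names (``"<phenotype>_gcross_score"``) to
    log hazard ratios applied to the cohort-standardized feature; event
    times are exponential with rate ``baseline_hazard * exp(beta . z)`` and
    censoring is uniform on ``(0, censor_time_max)``. Time unit: months.
    """

    baseline_hazard: float = 0.05
    beta: Mapping[str, float] = field(default_factory=lambda: {"naive_trm_gcross_score": math.log(0.5)})
    censor_time_max: float = 60.0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if self.censor_time_max <= 0:
            raise ConfigurationError("censor_time_max must be > 0")


@dataclass
class SimulationConfig:
    """Ground-truth generative model for one mIHC-like cohort.

    Tumor cells follow a Thomas (Neyman–Scott) cluster process: ``n_islets``
    fixed parent locations, Poisson(``tumor_per_islet``) Gaussian offspring
    with spread ``islet_sd_um``, restricted to the window. Each immune cell
    of phenotype p is attracted to the tumor with probability
    ``proximity_rho[p]``: placed at an Exponential(``attract_scale_um``)
    distance from a random tumor cell; otherwise uniform on the window.
    """

    seed: int = 0
    window: tuple[float, float] = (1000.0, 1000.0)
    n_islets: int = 8
    islet_sd_um: float = 60.0
    tumor_per_islet: float = 250.0
    immune_counts: dict[str, int] = field(
        default_factory=lambda: {
            "naive_trm": 150,
            "exhausted_trm": 150,
            "pd1_cd8": 100,
            "cd8": 200,
            "other": 250,
        }
    )
    proximity_rho: dict[str, float] = field(default_factory=dict)
    default_rho: float = 0.3
    attract_scale_um: float = 15.0
    intensity_model: dict[str, MarkerMixture] = field(default_factory=default_intensity_model)
    p_cd69: float = 0.3
    p_tcf1: float = 0.2
    survival: SurvivalModel = field(default_factory=SurvivalModel)
    n_patients: int = 60

    def __post_init__(self) -> None:
        w, h = self.window
        if not (w > 0 and h > 0):
            raise ConfigurationError("window dimensions must be strictly positive")
        if self.n_islets < 0:
            raise ConfigurationError("n_islets must be >= 0")
        if self.islet_sd_um <= 0 or self.attract_scale_um <= 0 or self.tumor_per_islet <= 0:
            raise ConfigurationError("scale parameters must be strictly positive")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        for p, n in self.immune_counts.items():
            if n < 0:
                raise ConfigurationError(f"immune count for {p!r} must be >= 0")
            if p not in PHENOTYPE_PROFILES:
                raise ConfigurationError(f"unknown immune phenotype {p!r}")
        for p, rho in self.proximity_rho.items():
            if not 0.0 <= rho <= 1.0:
                raise ConfigurationError(f"proximity_rho[{p!r}] must lie in [0, 1]")
        if not 0.0 <= self.default_rho <= 1.0:
            raise ConfigurationError("default_rho must lie in [0, 1]")

    def rho_for(self, phenotype: str) -> float:
        return float(self.proximity_rho.get(phenotype, self.default_rho))

    def midpoint_thresholds(self) -> dict[str, float]:
        """Gating thresholds at each marker's mixture midpoint (known-truth gating)."""
        return {m: mm.midpoint_intensity for m, mm in self.intensity_model.items()}

    def gating_config(self) -> GatingConfig:
        return GatingConfig(thresholds=self.midpoint_thresholds())


@dataclass
class SpatialParams:
    """Spatial-statistic parameters; defaults follow the analysis protocol."""

    r_max_um: float = 30.0
    n_r: int = 61
    band_width_um: float = 10.0
    max_band_dist_um: float = 100.0
    interaction_radius_um: float = 10.0
    min_combined: int = 1500
    border_correction: bool = False

    def __post_init__(self) -> None:
        if self.r_max_um <= 0:
            raise ConfigurationError("r_max_um must be > 0")
        if self.interaction_radius_um <= 0 or self.band_width_um <= 0:
            raise ConfigurationError("radii must be > 0")


@dataclass
class CompartmentParams:
    dilation_radius_um: float = 15.0
    min_component: int = 5

    def __post_init__(self) -> None:
        if self.dilation_radius_um <= 0:
            raise ConfigurationError("dilation_radius_um must be > 0")
        if self.min_component < 1:
            raise ConfigurationError("min_component must be >= 1")


def _to_plain(obj):
    if isinstance(obj, (SimulationConfig, SpatialParams, CompartmentParams, MarkerMixture, SurvivalModel, QCThresholds)):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, GatingConfig):
        return obj.to_dict()
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(obj, path: str | Path) -> None:
    """Serialize any config dataclass to YAML (.yaml/.yml) or JSON (.json)."""
    path = Path(path)
    plain = _to_plain(obj)
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(plain, sort_keys=True))
    else:
        path.write_text(json.dumps(plain, indent=2, sort_keys=True))


def load_config_dict(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    return json.loads(text)


def simulation_config_from_dict(d: Mapping) -> SimulationConfig:
    d = dict(d)
    if "window" in d:
        d["window"] = tuple(d["window"])
    if "intensity_model" in d:
        d["intensity_model"] = {m: MarkerMixture(**v) for m, v in d["intensity_model"].items()}
    if "survival" in d:
        d["survival"] = SurvivalModel(**d["survival"])
    return SimulationConfig(**d)
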