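"""Pipeline configuration.

Every tunable threshold used downstream lives in :class:`PipelineConfig` so a
run is fully described by one object: the dive-detection threshold, the
single-dive foraging-trip depth rule (18.1 m), the 5-minute post-dive
interval defining bouts, the 130 km environmental radius, the 800 m kernel
grid, the four activity-specific energy rates and the collinearity and
component-retention thresholds.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, asdict, replace


DEFAULT_ENERGY_RATES = {"COLONY": 32.0, "FLY": 532.8, "SWIM": 100.8, "DIVE": 97.2}

STATES = ("COLONY", "FLY", "SWIM", "DIVE")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Run-wide parameters with field-standard defaults.

    Attributes
    ----------
    colony_lon_lat : (float, float)
        Colony longitude, latitude in decimal degrees (default Coats
        Island, Nunavut).
    dive_depth_threshold_m : float
        Minimum depth for a wet excursion to count as a dive (10x the
        0.1 m sensor resolution).
    single_dive_trip_threshold_m : float
        A trip with exactly one dive is foraging only if the dive exceeds
        this depth; filters preening dips near the colony.
    bout_pdi_min : float
        Post-dive interval (minutes): a surface gap longer than this starts
        a new dive bout; a gap exactly equal stays in-bout.
    env_radius_km : float
        Radius around the colony over which ice/SST rasters are averaged.
    kde_grid_m : float
        Cell size for kernel utilization distributions.
    ud_isopleths : tuple of float
        Isopleth fractions reported for each UD (core and overall range).
    energy_rates_kj_per_h : dict
        Activity-specific energy expenditure, kJ per hour of activity.
    vif_threshold, gvif_threshold : float
        Collinearity screening cut-offs (VIF for single-df terms,
        GVIF^(1/2df) for multi-df terms).
    kaiser_eigenvalue : float
        Retain principal components with eigenvalue strictly above this.
    attendance_consistency : float
        Fraction of in-window fixes that must be at the colony on every
        observed night/day for the behavioural sexing rule.
    rng_seed : int
        Seed for any stochastic step (EM restarts etc.).
    """

    colony_lon_lat: tuple[float, float] = (-82.01, 62.95)
    dive_depth_threshold_m: float = 1.0
    single_dive_trip_threshold_m: float = 18.1
    bout_pdi_min: float = 5.0
    env_radius_km: float = 130.0
    kde_grid_m: float = 800.0
    ud_isopleths: tuple[float, ...] = (0.50, 0.95)
    energy_rates_kj_per_h: dict = field(default_factory=lambda: dict(DEFAULT_ENERGY_RATES))
    vif_threshold: float = 5.0
    gvif_threshold: float = 2.2
    kaiser_eigenvalue: float = 1.0
    attendance_consistency: float = 0.8
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("dive_depth_threshold_m", "single_dive_trip_threshold_m",
                     "bout_pdi_min", "env_radius_km", "kde_grid_m",
                     "vif_threshold", "gvif_threshold", "kaiser_eigenvalue"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not all(0.0 < f < 1.0 for f in self.ud_isopleths):
            raise ConfigError("ud_isopleths fractions must lie in (0, 1)")
        if set(self.energy_rates_kj_per_h) != set(STATES):
            raise ConfigError(
                f"energy_rates_kj_per_h must have exactly the activities {STATES}")
        if any(v < 0 for v in self.energy_rates_kj_per_h.values()):
            raise ConfigError("energy rates must be non-negative")
        if not 0.0 < self.attendance_consistency <= 1.0:
            raise ConfigError("attendance_consistency must be in (0, 1]")

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "colony_lon_lat" in d:
            d["colony_lon_lat"] = tuple(d["colony_lon_lat"])
        if "ud_isopleths" in d:
            d["ud_isopleths"] = tuple(d["ud_isopleths"])
        return cls(**d)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))
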