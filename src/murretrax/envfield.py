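"""Colony-radius, deployment-window averaging of environmental rasters.

Sea-ice concentration (%) and SST (degC) arrive as daily lon/lat grids
(xarray Dataset with dims time, lat, lon).  Each bird's covariate is the
unweighted mean over all cells within the configured great-circle radius
of the colony (130 km, the maximum foraging range) and all calendar days
intersecting its deployment window; missing cells are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .geodesy import haversine_km

VARIABLES = {"ICE_PCT": "%", "SST_C": "degC"}


@dataclass
class EnvField:
    """One environmental variable as a daily raster stack."""

    variable: str               # ICE_PCT or SST_C
    data: xr.DataArray          # dims (time, lat, lon); time as datetime64[D]

    def __post_init__(self):
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        if tuple(self.data.dims) != ("time", "lat", "lon"):
            raise ValueError("raster must have dims (time, lat, lon)")
        if self.variable == "ICE_PCT":
            v = self.data.values
            v = v[np.isfinite(v)]
            if v.size and (v.min() < 0 or v.max() > 100):
                raise ValueError("ICE_PCT outside [0, 100]")

    @property
    def units(self) -> str:
        return VARIABLES[self.variable]


def radius_mask(field: EnvField, center_lon_lat: tuple, radius_km: float) -> np.ndarray:
    """Boolean (lat, lon) mask of cells whose centre lies within the radius.

    A cell exactly at the radius is included.
    """
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    lon = field.data["lon"].values
    lat = field.data["lat"].values
    LON, LAT = np.meshgrid(lon, lat)
    d = haversine_km(LON, LAT, center_lon_lat[0], center_lon_lat[1])
    mask = d <= radius_km
    if not mask.any():
        # fall back to the single nearest cell rather than an empty average
        mask = d == d.min()
    return mask


def deployment_mean(field: EnvField, mask: np.ndarray,
                    start_t: float, end_t: float,
                    area_weight: bool = False) -> float:
    """Mean of masked cells over calendar days intersecting [start_t, end_t].

    Times are UTC epoch seconds; any day whose date range overlaps the
    window counts.  Missing cells are excluded; NaN is returned when every
    masked cell is missing.  ``area_weight`` applies cos-latitude cell
    weights (negligible at the 130 km scale, off by default).
    """
    d0 = pd.Timestamp(start_t, unit="s").normalize()
    d1 = pd.Timestamp(end_t, unit="s").normalize()
    times = pd.DatetimeIndex(field.data["time"].values).normalize()
    sel = (times >= d0) & (times <= d1)
    if not sel.any():
        raise ValueError("deployment window does not overlap the raster time axis")
    vals = field.data.values[sel][:, mask]
    if area_weight:
        lat = field.data["lat"].values
        w = np.cos(np.radians(np.broadcast_to(lat[:, None], mask.shape)))[mask]
        w = np.broadcast_to(w, vals.shape)
    else:
        w = np.ones_like(vals)
    ok = np.isfinite(vals)
    if not ok.any():
        return float("nan")
    return float((vals[ok] * w[ok]).sum() / w[ok].sum())


def assign_env_covariates(deployments, ice: EnvField | None, sst: EnvField | None,
                          config) -> pd.DataFrame:
    """Per-bird mean_ice_pct / mean_sst_c over each deployment window."""
    rows = []
    for d in deployments:
        row = {"bird_id": d.bird_id}
        for name, field in (("mean_ice_pct", ice), ("mean_sst_c", sst)):
            if field is None:
                row[name] = np.nan
            else:
                m = radius_mask(field, config.colony_lon_lat, config.env_radius_km)
                row[name] = deployment_mean(field, m, d.start_t, d.end_t)
        rows.append(row)
    return pd.DataFrame(rows)
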