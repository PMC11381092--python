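"""Tabular I/O for biologger deployments and summary tables.

A deployment is one bird-logger record: an ordered table of fixes (time,
position, per-interval maximum depth, wing-beat frequency, pitch) plus
metadata (sex, breeding stage, chick age, body masses).  Fix tables travel
as plain CSV; timestamps are UTC epoch seconds in memory and ISO-8601 on
disk.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .geodesy import haversine_km

FIX_COLUMNS = ("bird_id", "t", "lon", "lat", "depth")
OPTIONAL_FIX_COLUMNS = ("wingbeat_hz", "pitch")


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


class EmptyDeploymentError(ValueError):
    """A deployment contains no fixes."""


@dataclass
class Deployment:
    """One bird-deployment: metadata plus the per-fix observation table.

    ``fixes`` columns: t (UTC s), lon, lat, depth (per-interval max, m),
    wingbeat_hz, pitch, dist_colony_km.  ``depth_trace`` optionally carries
    the 1 Hz depth stream as (t, depth) for dive detection.
    """

    bird_id: str
    fixes: pd.DataFrame
    sex: str = "UNKNOWN"
    stage: str = "CHICK_REARING"
    chick_age_d: float | None = None
    mass_pre_g: float | None = None
    mass_post_g: float | None = None
    time_at_colony_before_sample_h: float | None = None
    depth_trace: pd.DataFrame | None = None

    def __post_init__(self):
        if len(self.fixes) == 0:
            raise EmptyDeploymentError(f"deployment {self.bird_id} has no fixes")
        t = self.fixes["t"].to_numpy(dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"deployment {self.bird_id}: fix times not strictly increasing")
        if (self.fixes["depth"].dropna() < 0).any():
            raise ValueError(f"deployment {self.bird_id}: negative depth")
        if self.stage == "INCUBATION" and self.chick_age_d is not None:
            raise ValueError("chick_age_d must be absent during incubation")

    @property
    def start_t(self) -> float:
        return float(self.fixes["t"].iloc[0])

    @property
    def end_t(self) -> float:
        return float(self.fixes["t"].iloc[-1])

    @property
    def duration_h(self) -> float:
        return (self.end_t - self.start_t) / 3600.0

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)


def _parse_times(col: pd.Series) -> np.ndarray:
    if np.issubdtype(col.dtype, np.number):
        return col.to_numpy(dtype=float)
    t = pd.to_datetime(col, utc=True, format="ISO8601")
    return t.astype("int64").to_numpy() / 1e9


def read_deployments(path, config: PipelineConfig, meta_path=None) -> list[Deployment]:
    """Read one fixes CSV (or a directory of them) into Deployments.

    Required columns: bird_id, t, lon, lat, depth; optional wingbeat_hz and
    pitch.  ``t`` may be ISO-8601 or epoch seconds.  Rows that break the
    strictly-increasing time order within a bird are dropped.  Distance to
    the configured colony is recomputed on read.
    """
    path = Path(path)
    files = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    frames = [pd.read_csv(f) for f in files]
    df = pd.concat(frames, ignore_index=True) if len(frames) > 1 else frames[0]
    for col in FIX_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col}")
    if len(df) == 0:
        raise EmptyDeploymentError("fix table has zero rows")
    df = df.copy()
    df["t"] = _parse_times(df["t"])
    for col in OPTIONAL_FIX_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan

    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path).set_index("bird_id")

    lon0, lat0 = config.colony_lon_lat
    out = []
    for bird_id, g in df.groupby("bird_id", sort=True):
        g = g.sort_values("t", kind="mergesort").reset_index(drop=True)
        keep = np.concatenate([[True], np.diff(g["t"].to_numpy(dtype=float)) > 0])
        g = g.loc[keep].drop(columns=["bird_id"]).reset_index(drop=True)
        g["dist_colony_km"] = haversine_km(g["lon"], g["lat"], lon0, lat0)
        kw = {}
        if meta is not None and bird_id in meta.index:
            row = meta.loc[bird_id]
            for f in ("sex", "stage", "chick_age_d", "mass_pre_g", "mass_post_g",
                      "time_at_colony_before_sample_h"):
                if f in row.index and pd.notna(row[f]):
                    kw[f] = row[f]
        out.append(Deployment(bird_id=str(bird_id), fixes=g, **kw))
    out.sort(key=lambda d: (d.bird_id, d.start_t))
    return out


def write_table(rows, path) -> None:
    """Write a homogeneous sequence of dataclasses/dicts (or a DataFrame) as CSV.

    Round-trips losslessly for finite values (full float repr is kept).
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        records = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
                   for r in rows]
        df = pd.DataFrame.from_records(records)
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_deployments(deployments: list[Deployment], fixes_path, meta_path=None) -> None:
    """Write deployments back out as a fixes CSV (+ optional metadata CSV)."""
    parts = []
    metas = []
    for d in deployments:
        g = d.fixes.copy()
        g.insert(0, "bird_id", d.bird_id)
        parts.append(g)
        metas.append({
            "bird_id": d.bird_id, "sex": d.sex, "stage": d.stage,
            "chick_age_d": d.chick_age_d, "mass_pre_g": d.mass_pre_g,
            "mass_post_g": d.mass_post_g,
            "time_at_colony_before_sample_h": d.time_at_colony_before_sample_h,
        })
    pd.concat(parts, ignore_index=True).to_csv(fixes_path, index=False)
    if meta_path is not None:
        pd.DataFrame(metas).to_csv(meta_path, index=False)
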