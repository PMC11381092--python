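"""Dive detection, bout grouping, trip segmentation and deployment metrics.

The segmentation hierarchy is dive < bout < trip < deployment.  Dives are
maximal runs of the 1 Hz depth trace at or below the detection threshold
depth; bouts group consecutive dives whose surface gap does not exceed the
post-dive-interval criterion (5 min; a gap exactly equal stays in-bout);
trips are maximal away-from-colony intervals of the decoded behaviour
sequence.  A trip is a *foraging* trip if it contains more than one dive,
or a single dive deeper than the single-dive threshold (18.1 m, the
all-years median maximum dive depth) — the latter rule keeps single
prey-delivery dives while dropping near-colony preening dips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .geodesy import haversine_km, solar_hour
from .hmm import BehaviorSequence
from .io import Deployment


@dataclass
class Dive:
    start_t: float
    end_t: float
    max_depth_m: float

    @property
    def duration_min(self) -> float:
        return (self.end_t - self.start_t) / 60.0


@dataclass
class DiveBout:
    dives: list

    @property
    def n_dives(self) -> int:
        return len(self.dives)


@dataclass
class Trip:
    depart_t: float
    return_t: float
    max_dist_km: float
    total_dist_km: float
    truncated: bool = False
    dives: list = field(default_factory=list)
    bouts: list = field(default_factory=list)
    is_foraging: bool = False

    @property
    def duration_h(self) -> float:
        return (self.return_t - self.depart_t) / 3600.0

    @property
    def n_dives(self) -> int:
        return len(self.dives)


@dataclass
class DeploymentSummary:
    bird_id: str
    # foraging metrics
    max_dist_km: float = np.nan
    mean_daily_dist_km: float = np.nan
    mean_trip_dist_km: float = np.nan
    mean_trip_dur_h: float = np.nan
    trips_per_day: float = 0.0
    # diving metrics
    max_dive_depth_m: float = np.nan
    mean_dive_depth_m: float = np.nan
    max_dive_dur_min: float = np.nan
    mean_dive_dur_min: float = np.nan
    mean_dives_per_bout: float = np.nan
    dives_per_day: float = np.nan
    bouts_per_day: float = np.nan
    time_diving_per_day_h: float = np.nan
    dee_kj_per_day: float = np.nan
    # covariates
    sex: str = "UNKNOWN"
    stage: str = "CHICK_REARING"
    chick_age_d: float = np.nan
    deployment_dur_h: float = np.nan
    mean_ice_pct: float = np.nan
    mean_sst_c: float = np.nan

FORAGING_METRICS = ("max_dist_km", "mean_daily_dist_km", "mean_trip_dist_km",
                    "mean_trip_dur_h", "trips_per_day")
DIVING_METRICS = ("max_dive_depth_m", "mean_dive_depth_m", "max_dive_dur_min",
                  "mean_dive_dur_min", "mean_dives_per_bout", "dives_per_day",
                  "bouts_per_day", "time_diving_per_day_h")


def detect_dives(t: np.ndarray, depth: np.ndarray, min_depth_m: float = 1.0) -> list[Dive]:
    """Maximal runs with depth >= min_depth_m in a 1 Hz trace.

    ``t`` in UTC seconds; runs separated by at least one surface sample (or
    a break in the trace) are distinct dives.  Duration counts one sample
    interval per submerged sample.
    """
    t = np.asarray(t, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if np.any(depth < 0):
        raise ValueError("negative depth in trace")
    wet = depth >= min_depth_m
    if not wet.any():
        return []
    dt = 1.0
    # run boundaries: state change or a gap in the 1 Hz trace
    contiguous = np.concatenate([[True], np.diff(t) <= dt * 1.5])
    new_run = wet & (~np.concatenate([[False], wet[:-1]]) | ~contiguous)
    run_id = np.cumsum(new_run)
    run_id[~wet] = 0
    dives = []
    for rid in np.unique(run_id):
        if rid == 0:
            continue
        idx = np.nonzero(run_id == rid)[0]
        dives.append(Dive(start_t=t[idx[0]], end_t=t[idx[-1]] + dt,
                          max_depth_m=float(depth[idx].max())))
    return dives


def group_bouts(dives: list[Dive], pdi_min: float = 5.0) -> list[DiveBout]:
    """Group time-ordered dives into bouts by the post-dive interval rule."""
    if not dives:
        return []
    bouts = [[dives[0]]]
    for prev, nxt in zip(dives[:-1], dives[1:]):
        gap_min = (nxt.start_t - prev.end_t) / 60.0
        if gap_min < 0:
            raise ValueError("overlapping dives")
        if gap_min > pdi_min:
            bouts.append([nxt])
        else:
            bouts[-1].append(nxt)
    return [DiveBout(dives=b) for b in bouts]


def segment_trips(sequence: BehaviorSequence, deployment: Deployment,
                  dives: list[Dive] | None = None,
                  config: PipelineConfig | None = None) -> list[Trip]:
    """Cut a decoded deployment into away-from-colony trips.

    A trip runs from the last COLONY fix before a non-COLONY block to the
    first COLONY fix after it; blocks touching a deployment edge are
    flagged truncated.  Per-trip distances are great-circle over the GPS
    fixes of the block (including the bounding colony fixes when present).
    When ``dives`` is given, dives falling inside the trip window are
    attached, grouped into bouts, and the trip is foraging-classified.
    """
    config = config or PipelineConfig()
    states = np.asarray(sequence.states)
    fixes = deployment.fixes
    t = fixes["t"].to_numpy(dtype=float)
    if len(states) != len(fixes):
        raise ValueError("sequence length does not match fix count")
    away = states != "COLONY"
    if not away.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], away.astype(int), [0]])))
    trips = []
    for i0, i1 in zip(edges[::2], edges[1::2] - 1):
        j0 = max(i0 - 1, 0)
        j1 = min(i1 + 1, len(states) - 1)
        truncated = (i0 == 0) or (i1 == len(states) - 1)
        lon = fixes["lon"].to_numpy(dtype=float)[j0:j1 + 1]
        lat = fixes["lat"].to_numpy(dtype=float)[j0:j1 + 1]
        step = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:]) if len(lon) > 1 else np.zeros(0)
        dist = fixes["dist_colony_km"].to_numpy(dtype=float)[i0:i1 + 1]
        trip = Trip(depart_t=float(t[j0]), return_t=float(t[j1]),
                    max_dist_km=float(np.nanmax(dist)) if len(dist) else 0.0,
                    total_dist_km=float(np.nansum(step)), truncated=truncated)
        if dives is not None:
            trip.dives = [d for d in dives
                          if trip.depart_t <= d.start_t < trip.return_t]
            trip.bouts = group_bouts(trip.dives, config.bout_pdi_min)
            trip.is_foraging = classify_foraging(trip, config)
        trips.append(trip)
    return trips


def classify_foraging(trip: Trip, config: PipelineConfig | None = None) -> bool:
    """More than one dive, or one dive deeper than the single-dive threshold."""
    config = config or PipelineConfig()
    n = trip.n_dives
    if n > 1:
        return True
    if n == 1:
        return trip.dives[0].max_depth_m > config.single_dive_trip_threshold_m
    return False


def summarize_deployment(deployment: Deployment, trips: list[Trip],
                         dee_kj_per_day: float = np.nan,
                         mean_ice_pct: float = np.nan,
                         mean_sst_c: float = np.nan,
                         diving_over: str = "foraging") -> DeploymentSummary:
    """Roll per-trip results up to one row per bird-deployment.

    Foraging metrics are computed over foraging trips only; diving metrics
    over the dives of foraging trips (``diving_over="all"`` switches to
    every trip's dives); rates are per deployment day.  Duration-based
    means exclude trips truncated by deployment edges.  Metrics stay
    missing (NaN) when there is nothing to average.
    """
    dur_h = deployment.duration_h
    if dur_h <= 0:
        raise ValueError("zero-duration deployment")
    days = dur_h / 24.0
    s = DeploymentSummary(bird_id=deployment.bird_id, sex=deployment.sex,
                          stage=deployment.stage,
                          chick_age_d=(np.nan if deployment.chick_age_d is None
                                       else deployment.chick_age_d),
                          deployment_dur_h=dur_h, dee_kj_per_day=dee_kj_per_day,
                          mean_ice_pct=mean_ice_pct, mean_sst_c=mean_sst_c)
    if diving_over not in ("foraging", "all"):
        raise ValueError("diving_over must be 'foraging' or 'all'")
    ftrips = [tr for tr in trips if tr.is_foraging]
    s.trips_per_day = len(ftrips) / days
    if ftrips:
        s.max_dist_km = max(tr.max_dist_km for tr in ftrips)
        s.mean_daily_dist_km = sum(tr.total_dist_km for tr in ftrips) / days
        s.mean_trip_dist_km = float(np.mean([tr.total_dist_km for tr in ftrips]))
        whole = [tr for tr in ftrips if not tr.truncated]
        if whole:
            s.mean_trip_dur_h = float(np.mean([tr.duration_h for tr in whole]))
        dtrips = trips if diving_over == "all" else ftrips
        dives = [d for tr in dtrips for d in tr.dives]
        bouts = [b for tr in dtrips for b in tr.bouts]
        if dives:
            depths = np.array([d.max_depth_m for d in dives])
            durs = np.array([d.duration_min for d in dives])
            s.max_dive_depth_m = float(depths.max())
            s.mean_dive_depth_m = float(depths.mean())
            s.max_dive_dur_min = float(durs.max())
            s.mean_dive_dur_min = float(durs.mean())
            s.dives_per_day = len(dives) / days
            s.bouts_per_day = len(bouts) / days
            s.mean_dives_per_bout = float(np.mean([b.n_dives for b in bouts]))
            s.time_diving_per_day_h = float(durs.sum() / 60.0 / days)
    return s


def sex_from_attendance(sequence: BehaviorSequence, deployment: Deployment,
                        config: PipelineConfig | None = None) -> str:
    """Behavioural sexing from diel nest attendance.

    Females attend the nest consistently 23:30-03:30, males 11:30-15:30
    (local solar time).  "Consistently" means >= the configured fraction of
    in-window fixes decoded COLONY on *every* observed night/day.  Birds
    satisfying both windows (e.g. always at the colony) or neither are
    UNDETERMINED, as are deployments shorter than 24 h.
    """
    config = config or PipelineConfig()
    if deployment.duration_h < 24.0:
        warnings.warn(f"{deployment.bird_id}: <24 h of data, sex undetermined")
        return "UNDETERMINED"
    t = deployment.fixes["t"].to_numpy(dtype=float)
    lon = deployment.fixes["lon"].to_numpy(dtype=float)
    sh = solar_hour(t, lon)
    at_colony = np.asarray(sequence.states) == "COLONY"
    solar_s = t + lon / 15.0 * 3600.0

    def window_ok(lo, hi):
        if lo < hi:
            in_w = (sh >= lo) & (sh < hi)
            day = np.floor(solar_s / 86400.0)
        else:                      # wraps midnight: shift so the window is one block
            in_w = (sh >= lo) | (sh < hi)
            day = np.floor((solar_s - hi * 3600.0) / 86400.0)
        if not in_w.any():
            return False
        ok = True
        for d in np.unique(day[in_w]):
            sel = in_w & (day == d)
            ok &= at_colony[sel].mean() >= config.attendance_consistency
        return ok

    f_ok = window_ok(23.5, 3.5)
    m_ok = window_ok(11.5, 15.5)
    if f_ok and not m_ok:
        return "F"
    if m_ok and not f_ok:
        return "M"
    return "UNDETERMINED"
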