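"""Seeded generator of biologger deployments, environmental rasters and
biomarker panels.

The generator mirrors the data-generating process the analyses assume: each
bird alternates colony attendance with central-place foraging trips from
the Coats Island colony (62.95N, 82.01W); within a trip, behaviour evolves
as a first-order Markov chain over FLY/SWIM/DIVE at the fix interval;
DIVE runs contain bouts of V-shaped 1 Hz dive excursions whose maximum
depths are lognormal (log-location set so the median equals
``dive_depth_mean_m``), with surface gaps shorter than the post-dive
interval inside a bout and longer between bouts; females attend the nest
23:30-03:30 and males 11:30-15:30 local solar time.  Per-bird standardized
covariates (sea-ice anomaly, SST anomaly, sex, chick age) carry planted
effects into trip rate, trip duration, dive depth and the log-ratio
biomarker change scores, so every downstream stage has recoverable ground
truth.  Everything is a pure function of the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .config import ConfigError, STATES
from .envfield import EnvField
from .geodesy import aeqd_unproject, solar_hour
from .hmm import BehaviorSequence, Gaussian, HMMSpec, ZeroInflatedGamma
from .io import Deployment

SEASON_START = pd.Timestamp("2018-06-15", tz="UTC")

FLIGHT_SPEED_KM_H = 75.0


@dataclass
class SimScenario:
    """Study conditions for one synthetic dataset."""

    n_birds: int = 20
    sex_ratio: float = 0.5               # fraction male
    stage: str = "CHICK_REARING"
    days: float = 2.0                    # deployment length
    fix_interval_s: int = 180
    depth_hz: float = 1.0
    hmm_truth: HMMSpec | None = None
    colony_lon_lat: tuple = (-82.01, 62.95)
    trip_rate_per_day: float = 4.0
    trip_duration_h: float = 2.5
    dive_depth_mean_m: float = 18.0      # lognormal median of max dive depth
    dive_depth_sd_m: float = 9.0         # spread; log-sd = sd/mean
    bout_size_mean: float = 5.0
    bout_pdi_min: float = 5.0
    ice_effect: float = 0.0
    sst_effect: float = 0.0
    sex_effect: float = 0.0
    chickage_effect: float = 0.0
    noise_sd: float = 0.3                # biomarker log-scale residual SD
    seed: int = 0
    env_days: int = 62
    env_cell_deg: float = 0.25

    def __post_init__(self):
        if self.fix_interval_s not in (60, 180):
            raise ConfigError("fix_interval_s must be 60 or 180")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigError("sex_ratio must lie in [0, 1]")
        for name in ("days", "trip_rate_per_day", "trip_duration_h",
                     "dive_depth_mean_m", "dive_depth_sd_m", "bout_size_mean",
                     "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.hmm_truth is None:
            self.hmm_truth = default_truth_spec()


def default_truth_spec() -> HMMSpec:
    """Well-separated four-state truth parameters for the simulator."""
    zg = ZeroInflatedGamma
    emissions = {
        "COLONY": {"wingbeat_hz": zg(0.97, 2.0, 2.0), "pitch": Gaussian(0.0, 8.0),
                   "depth": zg(0.999, 2.0, 0.5), "dist_colony_km": zg(0.98, 2.0, 2.0)},
        "FLY": {"wingbeat_hz": zg(0.01, 64.0, 8.0), "pitch": Gaussian(0.0, 5.0),
                "depth": zg(0.999, 2.0, 0.5), "dist_colony_km": zg(0.02, 2.0, 0.15)},
        "SWIM": {"wingbeat_hz": zg(0.95, 2.0, 2.0), "pitch": Gaussian(15.0, 8.0),
                 "depth": zg(0.995, 2.0, 0.5), "dist_colony_km": zg(0.02, 2.0, 0.15)},
        "DIVE": {"wingbeat_hz": zg(0.95, 2.0, 2.0), "pitch": Gaussian(-40.0, 10.0),
                 "depth": zg(0.05, 4.0, 0.25), "dist_colony_km": zg(0.02, 2.0, 0.15)},
    }
    trans = np.array([
        [0.95, 0.05, 0.00, 0.00],
        [0.03, 0.80, 0.12, 0.05],
        [0.01, 0.10, 0.70, 0.19],
        [0.01, 0.04, 0.25, 0.70],
    ])
    init = np.array([0.85, 0.05, 0.05, 0.05])
    return HMMSpec(states=STATES, init=init, trans=trans, emissions=emissions)


def sample_hmm(spec: HMMSpec, n: int, rng: np.random.Generator):
    """Sample a state path and all observation channels directly from a spec.

    Returns (obs DataFrame with the spec's channels, state-label array).
    Used for parameter-recovery and decoding tests where the data must
    follow the model class exactly.
    """
    S = len(spec.states)
    states = np.empty(n, dtype=np.intp)
    states[0] = rng.choice(S, p=spec.init)
    for t in range(1, n):
        states[t] = rng.choice(S, p=spec.trans[states[t - 1]])
    cols = {}
    for ch in spec.channels:
        x = np.empty(n)
        for j, s in enumerate(spec.states):
            m = states == j
            k = int(m.sum())
            if k == 0:
                continue
            d = spec.emissions[s][ch]
            if isinstance(d, Gaussian):
                x[m] = rng.normal(d.mu, d.sigma, k)
            else:
                pos = rng.random(k) >= d.pi0
                v = np.zeros(k)
                v[pos] = rng.gamma(d.shape, 1.0 / d.rate, int(pos.sum()))
                x[m] = v
        cols[ch] = x
    labels = np.asarray(spec.states, dtype=object)[states]
    return pd.DataFrame(cols), labels


@dataclass
class SimResult:
    deployments: list
    truth: list                       # BehaviorSequence per deployment
    covariates: pd.DataFrame          # per-bird standardized covariates
    scenario: SimScenario = field(repr=False, default=None)


def _bird_covariates(scenario: SimScenario, rng) -> pd.DataFrame:
    n = scenario.n_birds
    n_male = int(round(n * scenario.sex_ratio))
    sex = np.array(["M"] * n_male + ["F"] * (n - n_male), dtype=object)
    chick_z = rng.normal(0.0, 1.0, n)
    rows = pd.DataFrame({
        "bird_id": [f"bird{i:03d}" for i in range(n)],
        "sex": sex,
        "sex_m": (sex == "M").astype(float),
        "ice_z": rng.normal(0.0, 1.0, n),
        "sst_z": rng.normal(0.0, 1.0, n),
        "chickage_z": chick_z,
        "chick_age_d": np.clip(10.0 + 5.0 * chick_z, 0.0, None),
    })
    return rows


def simulate_deployments(scenario: SimScenario) -> SimResult:
    """Generate one deployment per bird with ground-truth behaviour labels."""
    rng = np.random.default_rng(scenario.seed)
    cov = _bird_covariates(scenario, rng)
    spec = scenario.hmm_truth
    lon0, lat0 = scenario.colony_lon_lat
    dt = float(scenario.fix_interval_s)
    T = int(round(scenario.days * 86400.0 / dt))
    # within-trip chain over FLY/SWIM/DIVE
    sub = spec.trans[1:, 1:].copy()
    sub /= sub.sum(axis=1, keepdims=True)

    deployments, truths = [], []
    for _, bird in cov.iterrows():
        t0 = float(SEASON_START.timestamp()) + float(rng.uniform(5, 40)) * 86400.0
        t0 = np.floor(t0 / dt) * dt
        t = t0 + np.arange(T) * dt

        rate = scenario.trip_rate_per_day * np.exp(-scenario.ice_effect * bird.ice_z)
        dur_h = scenario.trip_duration_h * np.exp(scenario.ice_effect * bird.ice_z)
        depth_med = scenario.dive_depth_mean_m * np.exp(
            0.3 * scenario.ice_effect * bird.ice_z)

        states = _schedule_states(scenario, rng, t, bird.sex, rate, dur_h, sub)
        x, y, dives = _kinematics_and_dives(scenario, rng, t, states, depth_med)
        lon, lat = aeqd_unproject(x * 1000.0, y * 1000.0, lon0, lat0)
        depth_fix = _per_fix_max_depth(t, dt, dives)
        obs = _emit_channels(spec, rng, states, depth_fix)

        trace = _dive_trace(dives)
        dist = np.hypot(x, y)
        fixes = pd.DataFrame({
            "t": t, "lon": lon, "lat": lat, "depth": depth_fix,
            "wingbeat_hz": obs["wingbeat_hz"], "pitch": obs["pitch"],
            "dist_colony_km": dist,
        })
        dep = Deployment(
            bird_id=bird.bird_id, fixes=fixes, sex=bird.sex, stage=scenario.stage,
            chick_age_d=(float(bird.chick_age_d)
                         if scenario.stage == "CHICK_REARING" else None),
            depth_trace=trace)
        labels = np.asarray(STATES, dtype=object)[states]
        truths.append(BehaviorSequence(deployment_id=bird.bird_id, states=labels,
                                       log_likelihood=np.nan, spec=spec))
        deployments.append(dep)
    return SimResult(deployments=deployments, truth=truths, covariates=cov,
                     scenario=scenario)


def _schedule_states(scenario, rng, t, sex, rate_per_day, trip_dur_h, sub_trans):
    """Per-fix state indices: colony attendance alternating with trips."""
    dt = t[1] - t[0] if len(t) > 1 else float(scenario.fix_interval_s)
    T = len(t)
    states = np.zeros(T, dtype=np.intp)      # COLONY
    if rate_per_day <= 0:
        return states
    mean_cycle_h = 24.0 / rate_per_day
    mean_colony_h = max(mean_cycle_h - trip_dur_h, 0.25)
    lon0 = scenario.colony_lon_lat[0]
    window = (23.5, 3.5) if sex == "F" else (11.5, 15.5)

    def in_window(ts):
        h = solar_hour(ts, lon0)
        lo, hi = window
        return (h >= lo) | (h < hi) if lo > hi else (h >= lo) & (h < hi)

    now = t[0] + rng.exponential(mean_colony_h) * 3600.0
    while now < t[-1]:
        dur_s = max(rng.lognormal(np.log(trip_dur_h), 0.35), 0.5) * 3600.0
        if in_window(now) or in_window(now + dur_s):
            now += 900.0                      # wait out the attendance window
            continue
        i0 = int(np.searchsorted(t, now))
        i1 = min(int(np.searchsorted(t, now + dur_s)), T)
        if i1 - i0 >= 2:
            # within-trip Markov chain over FLY/SWIM/DIVE; commute legs fly
            n = i1 - i0
            chain = np.empty(n, dtype=np.intp)
            chain[0] = 0
            for k in range(1, n):
                chain[k] = rng.choice(3, p=sub_trans[chain[k - 1]])
            chain[-1] = 0
            states[i0:i1] = chain + 1
        now += dur_s + rng.exponential(mean_colony_h) * 3600.0
    return states


def _kinematics_and_dives(scenario, rng, t, states, depth_med):
    """Track (km east/north of colony) and the dive event list."""
    dt = t[1] - t[0] if len(t) > 1 else float(scenario.fix_interval_s)
    step_fly = FLIGHT_SPEED_KM_H * dt / 3600.0
    x = np.zeros(len(t))
    y = np.zeros(len(t))
    dives = []
    sigma_log = (scenario.dive_depth_sd_m / scenario.dive_depth_mean_m
                 if scenario.dive_depth_mean_m > 0 else 0.3)

    away = states != 0
    edges = np.flatnonzero(np.diff(np.concatenate([[0], away.astype(int), [0]])))
    for i0, i1 in zip(edges[::2], edges[1::2]):
        theta = rng.uniform(0, 2 * np.pi)
        reach = step_fly * (i1 - i0) / 2.2
        target = np.array([np.cos(theta), np.sin(theta)]) * rng.uniform(0.3, 1.0) * reach
        pos = np.zeros(2)
        for i in range(i0, i1):
            remaining = i1 - 1 - i
            d_home = np.hypot(*pos)
            if d_home >= (remaining - 1) * step_fly * 0.95:
                states[i] = 1                              # forced return flight
                pos = pos * max(1.0 - step_fly / max(d_home, 1e-9), 0.0)
            elif states[i] == 1:                           # FLY toward target
                v = target - pos
                d = np.hypot(*v)
                pos = target if d <= step_fly else pos + v / d * step_fly
            else:                                          # SWIM/DIVE drift
                pos = pos + rng.normal(0.0, 0.05, 2)
            x[i], y[i] = pos
        # dive events inside DIVE runs of this trip
        run = states[i0:i1] == 3
        redges = np.flatnonzero(np.diff(np.concatenate([[0], run.astype(int), [0]])))
        for r0, r1 in zip(redges[::2], redges[1::2]):
            ta = t[i0 + r0]
            tb = t[i0 + r1 - 1] + dt
            dives.extend(_bout_dives(scenario, rng, ta, tb, depth_med, sigma_log))
    return x, y, dives


def _bout_dives(scenario, rng, ta, tb, depth_med, sigma_log):
    """Sequential dives in [ta, tb): short gaps within a bout, a gap longer
    than the post-dive interval between bouts."""
    out = []
    now = ta
    bout_target = max(1, int(rng.poisson(max(scenario.bout_size_mean - 1.0, 0.0)) + 1))
    in_bout = 0
    while True:
        depth = float(rng.lognormal(np.log(max(depth_med, 0.1)), sigma_log))
        depth = max(depth, 1.5)
        dur = 20.0 + 1.5 * depth
        if now + dur > tb:
            break
        out.append((now, now + dur, depth))
        in_bout += 1
        if in_bout >= bout_target:
            gap = scenario.bout_pdi_min * 60.0 + rng.uniform(60.0, 300.0)
            bout_target = max(1, int(rng.poisson(max(scenario.bout_size_mean - 1.0, 0.0)) + 1))
            in_bout = 0
        else:
            gap = rng.uniform(30.0, 90.0)
        now += dur + gap
    return out


def _dive_trace(dives) -> pd.DataFrame:
    """1 Hz V-shaped depth samples for every dive event."""
    ts, ds = [], []
    for (a, b, depth) in dives:
        n = max(int(round(b - a)), 3)
        k = np.arange(n)
        profile = depth * (1.0 - np.abs(2.0 * k / (n - 1) - 1.0))
        ts.append(a + k)
        ds.append(profile)
    if not ts:
        return pd.DataFrame({"t": [], "depth": []})
    return pd.DataFrame({"t": np.concatenate(ts), "depth": np.concatenate(ds)})


def _per_fix_max_depth(t, dt, dives) -> np.ndarray:
    depth = np.zeros(len(t))
    for (a, b, d) in dives:
        i0 = int(np.searchsorted(t, a, side="right") - 1)
        i1 = int(np.searchsorted(t, b, side="right") - 1)
        for i in range(max(i0, 0), min(i1, len(t) - 1) + 1):
            depth[i] = max(depth[i], d)
    return depth


def _emit_channels(spec, rng, states, depth_fix):
    """Wing-beat and pitch drawn from the truth emissions given the state."""
    n = len(states)
    out = {}
    for ch in ("wingbeat_hz", "pitch"):
        x = np.empty(n)
        for j, s in enumerate(spec.states):
            m = states == j
            k = int(m.sum())
            if k == 0:
                continue
            d = spec.emissions[s][ch]
            if isinstance(d, Gaussian):
                x[m] = rng.normal(d.mu, d.sigma, k)
            else:
                pos = rng.random(k) >= d.pi0
                v = np.zeros(k)
                v[pos] = rng.gamma(d.shape, 1.0 / d.rate, int(pos.sum()))
                x[m] = v
        out[ch] = x
    return out


# ---------------------------------------------------------------------------
# environmental rasters

def simulate_env(scenario: SimScenario, constant: float | None = None):
    """Daily ice (%) and SST (degC) rasters over the colony region.

    Ice declines linearly from 90% to 0 over the season with a smooth
    seeded spatial anomaly; SST rises from -1 to 8 degC.  ``constant``
    short-circuits both fields to that value (range permitting) for tests.
    Extent covers > 130 km beyond the colony.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    lon0, lat0 = scenario.colony_lon_lat
    dlat = 1.6
    dlon = 3.6
    lats = np.arange(lat0 - dlat, lat0 + dlat + 1e-9, scenario.env_cell_deg)
    lons = np.arange(lon0 - dlon, lon0 + dlon + 1e-9, scenario.env_cell_deg)
    times = SEASON_START.tz_localize(None) + pd.to_timedelta(
        np.arange(scenario.env_days), unit="D")
    frac = np.arange(scenario.env_days) / max(scenario.env_days - 1, 1)

    def smooth_field():
        f = rng.normal(0, 1, (len(lats), len(lons)))
        for _ in range(4):      # crude smoothing by neighbour averaging
            f = 0.2 * (np.roll(f, 1, 0) + np.roll(f, -1, 0)
                       + np.roll(f, 1, 1) + np.roll(f, -1, 1)) + 0.2 * f
        return f / max(f.std(), 1e-9)

    if constant is not None:
        ice = np.full((scenario.env_days, len(lats), len(lons)), float(constant))
        sst = np.full_like(ice, float(constant))
    else:
        anom = smooth_field()
        lat_grad = (lats[:, None] - lat0) / dlat      # more ice to the north
        ice = (90.0 * (1.0 - frac)[:, None, None]
               + 12.0 * lat_grad[None, :, :] + 8.0 * anom[None, :, :])
        ice = np.clip(ice, 0.0, 100.0)
        anom2 = smooth_field()
        sst = (-1.0 + 9.0 * frac[:, None, None]
               - 1.0 * lat_grad[None, :, :] + 0.5 * anom2[None, :, :])
    coords = {"time": times, "lat": lats, "lon": lons}
    ice_f = EnvField("ICE_PCT", xr.DataArray(ice, coords=coords,
                                             dims=("time", "lat", "lon")))
    sst_f = EnvField("SST_C", xr.DataArray(sst, coords=coords,
                                           dims=("time", "lat", "lon")))
    return ice_f, sst_f


# ---------------------------------------------------------------------------
# biomarker panels

BASELINES = {"MASS": 975.0, "TRIG": 1.5, "BCORT": 10.0, "BOH": 0.5, "NEFA": 0.6}
BASELINE_LOG_SD = {"MASS": 0.05, "TRIG": 0.3, "BCORT": 0.4, "BOH": 0.4, "NEFA": 0.3}


def simulate_biomarkers(deployments, scenario: SimScenario,
                        covariates: pd.DataFrame) -> pd.DataFrame:
    """Pre/post panels with planted log-scale covariate effects.

    log(post) = log(pre) + ice_effect*ice_z + sst_effect*sst_z
                + sex_effect*sex_m + chickage_effect*chickage_z
                + Normal(0, noise_sd), identically for every analyte.
    """
    rng = np.random.default_rng(scenario.seed + 2)
    cov = covariates.set_index("bird_id")
    rows = []
    for d in deployments:
        if d.bird_id not in cov.index:
            raise KeyError(f"no covariate row for bird {d.bird_id}")
        c = cov.loc[d.bird_id]
        shift = (scenario.ice_effect * c.ice_z + scenario.sst_effect * c.sst_z
                 + scenario.sex_effect * c.sex_m
                 + scenario.chickage_effect * c.chickage_z)
        for analyte in ANALYTES_ORDER:
            pre = float(np.exp(rng.normal(np.log(BASELINES[analyte]),
                                          BASELINE_LOG_SD[analyte])))
            eps = rng.normal(0.0, scenario.noise_sd) if scenario.noise_sd > 0 else 0.0
            post = float(pre * np.exp(shift + eps))
            rows.append({"bird_id": d.bird_id, "analyte": analyte,
                         "pre": pre, "post": post,
                         "delta": float(np.log(post) - np.log(pre))})
    return pd.DataFrame(rows)


ANALYTES_ORDER = ("MASS", "TRIG", "BCORT", "BOH", "NEFA")
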