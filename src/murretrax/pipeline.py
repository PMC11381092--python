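"""End-to-end orchestration: decoded states -> trips -> metric tables.

Thin glue used by the CLI and analysis scripts; every step is a call into
the stage modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .divetrip import detect_dives, segment_trips, summarize_deployment
from .energetics import activity_budget, dee
from .hmm import decode


def decode_all(deployments, spec):
    return [decode(d, spec) for d in deployments]


def summarize_all(deployments, sequences, config: PipelineConfig | None = None,
                  env_covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """One DeploymentSummary row per bird from decoded behaviour sequences.

    Dives come from the 1 Hz depth trace when the deployment carries one,
    otherwise from the per-fix depth channel.
    """
    config = config or PipelineConfig()
    env = (env_covariates.set_index("bird_id")
           if env_covariates is not None else None)
    rows = []
    for d, s in zip(deployments, sequences):
        if d.depth_trace is not None and len(d.depth_trace):
            dives = detect_dives(d.depth_trace["t"].to_numpy(),
                                 d.depth_trace["depth"].to_numpy(),
                                 config.dive_depth_threshold_m)
        else:
            dives = detect_dives(d.fixes["t"].to_numpy(),
                                 d.fixes["depth"].to_numpy(dtype=float),
                                 config.dive_depth_threshold_m)
        trips = segment_trips(s, d, dives=dives, config=config)
        energy = dee(activity_budget(s, d), config.energy_rates_kj_per_h)
        kw = {}
        if env is not None and d.bird_id in env.index:
            kw = {"mean_ice_pct": float(env.loc[d.bird_id].get("mean_ice_pct", np.nan)),
                  "mean_sst_c": float(env.loc[d.bird_id].get("mean_sst_c", np.nan))}
        rows.append(summarize_deployment(d, trips, dee_kj_per_day=energy, **kw))
    return pd.DataFrame([vars(r) for r in rows])
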