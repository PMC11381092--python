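# murretrax

A biologging analysis pipeline for central-place foraging seabirds,
built around thick-billed murres (*Uria lomvia*) breeding at an Arctic
colony.  It turns raw biologger streams (GPS fixes, 1 Hz depth, movement
features) into behavioural, energetic, spatial and physiological summaries,
and supplies a seeded synthetic-data generator so the entire chain runs and
is testable without any field data.

## What it computes

1. **Behaviour classification.**  A four-state hidden Markov model assigns
   each fix to COLONY, FLY, SWIM or DIVE from wing-beat frequency, pitch,
   per-interval maximum depth and distance from the colony.  Channels are
   conditionally independent given the state; exactly-zero channels
   (depth out of water, wing-beat while not flying) use zero-inflated gamma
   emissions.  Fitting is Baum–Welch EM, decoding is Viterbi.
2. **Segmentation and metrics.**  Dives are runs of the 1 Hz depth trace at
   ≥ 1 m; bouts group dives whose surface gap is ≤ 5 min (post-dive
   interval); trips are away-from-colony intervals.  A trip is *foraging*
   if it has > 1 dive, or a single dive > 18.1 m (the all-years median
   maximum dive depth, which filters near-colony preening dips).  Five
   foraging and eight diving metrics summarize each deployment.
3. **Energetics.**  Activity-budget daily energy expenditure
   `DEE = (32·T_colony + 532.8·T_fly + 100.8·T_swim + 97.2·T_dive)
   / deployment_duration × 24` (kJ/day).
4. **Space use.**  Kernel utilization distributions of diving locations on
   an 800 m grid (href bandwidth `h = (sd_x+sd_y)/2 · n^(−1/6)`), 50%/95%
   isopleth areas, and Bhattacharyya affinity
   `BA = Σ √(p₁p₂)·cell²` ∈ [0, 1] between UDs.
5. **Dimension reduction.**  Correlation PCA of the metric tables with
   Kaiser retention (eigenvalue > 1) and varimax rotation, giving rotated
   component scores (fRC1/fRC2, dRC1/dRC2 in the field's usual naming).
6. **Foraging success and model selection.**  Log-ratio change scores
   `∆ = log(post) − log(pre)` for mass and plasma biomarkers (TRIG, bCORT,
   B-OH, NEFA), assay CVs, VIF/GVIF collinearity screening (thresholds 5
   and 2.2), AICc-ranked linear (mixed) models with a bird-level random
   intercept, likelihood-ratio comparison to the null, REML refits with
   t-statistics, and marginal/conditional R².
7. **Environmental covariates.**  Sea-ice concentration and SST rasters
   averaged within 130 km of the colony over each deployment window.

## Worked example

```python
import numpy as np
import murretrax as mt
from murretrax.pipeline import decode_all, summarize_all

scen = mt.SimScenario(seed=1, n_birds=20, ice_effect=0.4)
sim  = mt.simulate_deployments(scen)             # deployments + ground truth
seqs = decode_all(sim.deployments, scen.hmm_truth)
summ = summarize_all(sim.deployments, seqs)      # one row per bird

print(summ[["bird_id", "trips_per_day", "mean_trip_dur_h",
            "max_dive_depth_m", "dee_kj_per_day"]].head(3).round(2))

res = mt.pca_kaiser(summ[list(mt.FORAGING_METRICS)].dropna())
print("eigenvalues:", np.round(res.eigenvalues_, 2))
print("retained:", res.n_retained_, f"({res.var_explained_pct_:.1f}% of variance)")

pts = mt.foraging_points(seqs, sim.deployments)
ud  = mt.kde_ud(pts, h=mt.href_bandwidth(pts), cell_m=800.0)
print(f"95% foraging area: {mt.isopleth_area(ud, 0.95):.0f} km^2")
print(f"BA(self) = {mt.bhattacharyya(ud, ud):.3f}")
```

Output:

```
bird_id  trips_per_day  mean_trip_dur_h  max_dive_depth_m  dee_kj_per_day
bird000           3.50             2.92             46.11         3666.75
bird001           5.01             2.30             48.73         3901.09
bird002           3.00             4.04             97.80         4561.68
eigenvalues: [3.62 1.11 0.15 0.07 0.03]
retained: 2 (94.7% of variance)
95% foraging area: 13767 km^2
BA(self) = 1.000
```

Each row is one bird-deployment: a bird making ~3.5 foraging trips/day of
~3 h each, diving to at most 46 m, spends ~3700 kJ/day.  Two principal
components of the five foraging metrics pass the Kaiser criterion and are
varimax-rotated; the pooled diving locations give a 95% kernel foraging
range, and a UD's affinity with itself is exactly 1.

A command-line interface mirrors the library
(`murretrax simulate|classify|summarize|ud|overlap|pca|biomarkers|models`);
run `murretrax --help` for the formats each command reads and writes.

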