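# dielcam

Diel activity, temporal overlap and spatial co-occurrence analysis for
camera-trap detection data, built around the community of six forest duiker
species (*Cephalophus* spp. and *Philantomba congica*) surveyed across
Central African rainforests.

Camera traps produce time-stamped photo records at fixed stations. From
those records, ecologists ask three questions this package answers:

1. **When is each species active?** Detection times are treated as a
   circular random variable θ = 2π·(hour/24). Repeat photos of a species at
   a station within 1 h collapse to one *independent event*; events are
   classified diurnal/nocturnal/twilight against the solar schedule, and
   each species' schedule is summarised by a von Mises kernel density
   f̂(θ) = n⁻¹ Σᵢ vM(θ; tᵢ, κ) with a concentration plug-in bandwidth, a
   trigonometric-sum cross-check, the Hermans–Rasson uniformity test, the
   circular median, and the Rowcliffe activity level 1/(2π·max f̂).
2. **Do two species partition the day?** The overlap coefficient
   Δ̂ = ∫ min(f̂, ĝ) dθ ∈ [0, 1], estimated by Δ̂₁ (grid integral, small
   samples) or Δ̂₄ (density-ratio form at the data points, both n ≥ 75),
   with smoothed-bootstrap percentile intervals, strength bands
   (low ≤ 0.5 < moderate ≤ 0.75 < strong) and a permutation test of
   distribution equality.
3. **Do two species share stations?** With margins N₁, N₂ of N stations
   fixed, the number of shared stations is hypergeometric:
   P_j = C(N₁,j)·C(N−N₁,N₂−j)/C(N,N₂); small p_gt = Σ_{j>Q_obs} P_j flags
   positive association, small p_lt negative, otherwise random; the
   standardised effect size is (Q_obs − N₁N₂/N)/N. A Mantel permutation
   test (exact for ≤ 7 species) relates the overlap matrix to the effect
   size matrix.

A calibrated synthetic-data generator (`dielcam.simulate`) reproduces the
survey's statistical structure — 12 sites, 432 stations, von Mises mixture
schedules, station occupancy with specified pairwise odds ratios — so the
whole pipeline is testable without field data. The published census tallies
ship as package data in `dielcam.duikerdata`.

## Worked example

```python
from dielcam.pipeline import RunConfig, run_pipeline
from dielcam.simulate import simulate_detections, study_replica_config

cfg = study_replica_config()           # bundled six-duiker replica, seed 7
records = simulate_detections(cfg)     # 4682 photo records
bundle = run_pipeline(RunConfig(records=records, seed=7, n_boot=1000,
                                deployed_stations=cfg.n_stations))
print(bundle["density"][["species", "n", "median_hour", "activity_level"]])
```

prints (about a minute):

```
       species    n  median_hour  activity_level
 C. callipygus  945       12.650           0.446
  C. castaneus  469        0.133           0.418
C. leucogaster   61       12.983           0.423
 C. nigrifrons   42       10.117           0.520
C. silvicultor  278       23.950           0.433
    P. congica 2562       11.100           0.401
```

The two nocturnal species (*C. castaneus*, *C. silvicultor*) have medians
at midnight, the diurnal guild between 10:00 and 13:00; activity levels say
each species is active roughly 40–50% of the 24-h cycle.
`bundle["overlap"]` holds the ten pairwise Δ̂ values (four strong pairs
within the diurnal guild and the nocturnal pair, weak overlap across),
`bundle["cooccurrence"]` the hypergeometric tests (four positive pairs, all
involving *C. callipygus*), and `bundle["mantel"]` the matrix association.

The `examples/` directory has one short script per capability; a thin CLI
(`dielcam simulate|events|density|overlap|cooccur|mantel|run`) wraps the
same functions for shell use.

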