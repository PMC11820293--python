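# thermotype

A tested pipeline for canopy-temperature (CT) phenotyping of field-grown
wheat lines, built around thermal infrared imaging of a replicated plot
trial.

Breeders use canopy temperature as a fast, non-destructive proxy for
stomatal behaviour and stress response: a line whose canopy runs cooler
than its neighbors is transpiring more. But raw CT is dominated by weather
and camera conditions, so the useful quantity is *relative* CT — a plot's
mean temperature minus the mean of its adjacent plots. `thermotype`
implements that whole chain on single-band temperature rasters:

1. **extract** — per-plot mean CT from float32 TIFF rasters via
   rectangular ROIs, with NaN handling and threshold-based soil masking
   (soil reads several °C hotter than canopy);
2. **normalize** — relative CT per plot,
   `rel_ct(p) = ct(p) − mean{ct(q) : q adjacent to p}`, using the six
   nearest plots in the planting grid; a global per-date or per-season
   offset cancels exactly;
3. **classify** — cold/warm/mediate thermal types from two seasons of
   relative-CT trajectories: *cold* iff the OLS trend slope is below −ε
   and the mean relative CT is below 0 in **every** season, *warm* the
   mirror image, *mediate* otherwise;
4. **fit** — the logistic grain-filling model for thousand-grain weight
   `y(t) = k / (1 + a·e^(−b·t))` (t in days, t = 0 at 27 days after
   flowering), with the filling rate `V(t) = k·a·b·e^(−bt)/(1+a·e^(−bt))²`
   and the derived parameters
   `C₀ = k/(1+a)`, `Vmax = kb/4`, `Vmean = kb/6`, `D = 6/b`,
   `T = −ln[(100/96 − 1)/a]/b` (the time at which y reaches 96 % of k),
   `V = V(T)` and `Y = y(T)`; fits with R² ≤ 0.95 are flagged inadequate;
5. **associate** — Pearson correlation panels with significance stars
   (\*\*\* p<0.001, \*\* p<0.01, \* p<0.05), cold-vs-warm Welch contrasts
   with percent differences and compact-letter displays, dry-matter deltas
   between sampling dates, and rainfall window summaries;
6. **simulate** — a synthetic-data generator that produces every input
   above (rasters, layouts, filling series, trait tables, weather) with
   known ground truth, so each stage is testable end to end.

## Worked example

```python
from thermotype import synthgen, thermal, normct, cttyping

# Plant a 12-line, 3-replicate trial: 3 cold, 3 warm, 6 mediate lines
offsets, slopes, truth = synthgen.plant_line_effects(3, 3, 6, seed=11)
spec = synthgen.FieldSpec(n_lines=12, plots_per_line=3, grid_shape=(6, 6),
                          line_offset=offsets, trend_slope=slopes,
                          noise_sd=0.2, seed=11)
layout = synthgen.build_layout(spec)

rel = []
for season in spec.seasons:          # "S1", then "S2" (+1.5 °C ambient)
    frames, _, _ = synthgen.make_thermal_frames(spec, [0, 6, 12, 18, 23],
                                                season, layout)
    ct = thermal.extract_ct_frames(frames, layout)
    rel.append(normct.normalize(ct, layout.adjacency))

import pandas as pd
calls = cttyping.classify_table(pd.concat(rel, ignore_index=True))
print(calls[["line", "call", "slope_S1", "slope_S2"]].head(4))
print("recovered:", (calls["call"] == calls["line"].map(truth)).mean())
```

```
  line     call  slope_S1  slope_S2
0  L01     warm  0.059073  0.135555
1  L02     cold -0.095343 -0.099773
2  L03  mediate -0.100695  0.144245
3  L04  mediate  0.044137 -0.066219
recovered: 1.0
```

L01 warms in both seasons (warm type); L02 cools at ~−0.1 °C/day in both
(cold type); L03 and L04 flip trend direction between seasons, the
signature of the mediate type. All 12 planted labels are recovered despite
0.2 °C pixel noise and the +1.5 °C ambient offset between seasons, because
neighbor normalization removes everything the plots share.

The same run from the shell, end to end with a manifest:

```sh
thermotype run-all --seed 11 --out-dir run/
```

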