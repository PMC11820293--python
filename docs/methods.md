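# Methods

## The measurement model

A thermal camera images a replicated field trial as single-band rasters of
surface temperature (°C). Atmospheric/emissivity correction is treated as
already applied by the acquisition software: rasters enter the pipeline as
calibrated temperatures, and no radiometric model is implemented here.

Each plot is an axis-aligned rectangular ROI with 0-based, half-open pixel
bounds, which makes region disjointness checks unambiguous. The plot's
canopy temperature (CT) is the plain arithmetic mean of its finite,
unmasked pixels — no trimming, since explicit masking replaces the manual
exclusion of undesirable areas that an operator would do. Soil masking is
a fixed temperature ceiling: soil under radiation load reads warmer than
transpiring canopy, so pixels above `threshold` are excluded and counted.
The pipeline's default ceiling is the frame's ambient plus half the
generator's soil margin, which sits strictly between canopy maximum and
soil temperature for any positive margin.

## Neighbor normalization

Raw CT confounds genotype with ambient conditions. For plot p on one date,

    rel_ct(p) = ct(p) − mean{ ct(q) : q adjacent to p },

after which replicate plots of a line are averaged to one value per
(line, season, date). Subtracting a *local* mean makes the statistic
exactly invariant to any constant added to all plots on a date — the
mechanism by which a warmer second season (or a different camera
calibration) cancels. Replicates are normalized at plot level first
because adjacency is a spatial relation between plots; the reverse order
(`average_first`) is exposed for sensitivity analysis and coincides when
replicates agree exactly. The observed range of relative CT (about
−2…2 °C in this kind of trial) is a property of the data, not a clamp; no
clipping is applied. No row–column or spline field-trend surface is
fitted — the neighborhood mean *is* the local trend estimate.

Adjacency is data, not code: the layout file stores, per plot, an explicit
neighbor list. The generator builds it as an offset-row (hex-like) grid
neighborhood — two same-row flankers plus the two nearest plots in each
flanking row — which gives every interior plot exactly six neighbors, the
"six adjacent lines" convention of field thermography; edge and corner
plots keep the 2–5 neighbors that exist. Any other geometry can be
supplied by editing `layout.yaml`.

## Thermal-type classification

Per line and season, the trajectory of relative CT over measurement days
is summarized by its OLS slope (°C/day) and its mean (°C). The call is:

* **cold**: slope < −ε and mean < 0 in every season;
* **warm**: slope > +ε and mean > 0 in every season;
* **mediate**: anything else (including trend flips between seasons).

ε defaults to 0.01 °C/day so that numerically near-zero slopes never force
a cold/warm call; over a ~25-day season this corresponds to a total drift
of 0.25 °C, comfortably above fitting noise at the default conditions.
Requiring *both* the trend and the level in *every* season is the
conservative conjunction of "trends and averages"; a line must be
consistently cool and cooling to be called cold. "Decreasing trend" is
read as a negative OLS slope with tolerance, not strict monotonicity —
monotonicity at 5 noisy dates would be dominated by noise.

## Logistic grain filling

Thousand-grain dry weight over the middle/late filling period (t = 0 at
27 days after flowering) follows

    y(t) = k / (1 + a e^(−b t)),   k, a, b > 0,

fitted by bounded nonlinear least squares (`scipy.optimize.curve_fit`,
trust-region reflective). Initialization: k₀ = 1.05·max(y) (also 1.2 and
1.5 inflations), b₀ and a₀ from the log-linear regression of
ln(k₀/y − 1) on t, plus a coarse 2×3×3 multi-start grid as fallback; the
lowest-SSE converged solution wins. R² = 1 − SSE/SST; fits with R² ≤ 0.95
are flagged `adequate = False` rather than rejected, so non-sigmoid input
surfaces as a flag, never a silent acceptance.

Derived parameters (all closed-form in k, a, b):

* C₀ = k/(1+a) — initial weight y(0);
* Vmax = kb/4 — the rate at the inflection t* = ln(a)/b;
* Vmean = kb/6 — mean filling rate; Vmax/Vmean = 3/2 identically;
* D = 6/b — active filling period. No printed formula exists for D; 6/b
  is the unique choice making Vmean = k/D consistent with Vmean = kb/6,
  and is flagged here as an inference;
* T = −ln[(100/96 − 1)/a]/b — the time at which y reaches 96 % of k. The
  commonly printed bracketing of this expression is ambiguous; the form
  used here is the one that actually solves y(T) = 0.96k, verified in the
  tests against a root-bracketing oracle to 1e-8;
* V = V(T) and Y = y(T) (= 0.96k by construction). Whether "late grain
  accumulation" means the weight reached by T or the remainder k − y(T)
  is ambiguous; the literal reading y(T) is the default and both values
  are always emitted (`y_at_T`, `y_remaining`).

## Association reporting

Correlation panels use Pearson r with two-sided p from the exact
t-transform (n − 2 df) and stars at p < 0.05/0.01/0.001 — linear
correlation with parametric stars, no rank method. Missing values are
deleted pairwise because per-date panels have different coverage; a
zero-variance variable yields an undefined cell (NaN), never a fabricated
zero. No multiple-testing correction by default, matching per-cell star
reporting; Benjamini–Hochberg is available as a switch. Group contrasts
use Welch's t (two lines per type makes pooled variance indefensible) with
percent difference relative to the warm group and a compact-letter display
built from pairwise tests by insert-and-absorb; singleton groups get the
difference but no test.

## The synthetic generator, and what passing tests show

The generator emulates the *statistical* structure the analysis assumes,
not canopy physics:

* a grid trial, each line in 3 replicate plots placed by seeded random
  permutation; two seasons share the layout and differ by a +1.5 °C
  ambient offset;
* per-plot truth: ambient + line offset + line trend·day + a per-plot
  spatial effect (SD `replicate_sd`, default 0.1 °C — within-line
  plot-to-plot variation is not documented for such trials, so it is a
  parameter, not an assertion);
* pixels: truth + i.i.d. Gaussian sensor noise (default 0.2 °C, typical
  of uncooled microbolometers after correction); soil gaps at ambient
  +8 °C, a positive margin that makes threshold masking testable;
* planted types: cold lines at offset ≈ −0.8 °C and slope −0.1 °C/day in
  both seasons, warm mirrored, mediate near zero offset with alternating
  slope signs;
* filling series: logistic curves with k ∈ [35, 55] g, a ∈ [10, 30],
  b ∈ [0.15, 0.35]/day — the realistic envelope for wheat thousand-grain
  weight — sampled every 3 days over 0…24 and perturbed by 0.5 g additive
  noise;
* traits: a linear-Gaussian single-factor construction,
  trait = mean + sd·(r·z_CT + √(1−r²)·ε), giving any target Pearson
  correlation r with CT and an automatically positive-semidefinite joint
  structure.

Not emulated: radiative transfer, wind/cloud dynamics within a frame,
spatial noise correlation, irregular hand-drawn ROIs, registration error.
Passing tests therefore demonstrate that the *computations* are correct
and that the design recovers planted effects under clean Gaussian
assumptions — not that the thresholds would survive structured field
noise.

All randomness flows through `numpy.random.default_rng` seeded from the
spec seeds; fixed seeds give byte-identical rasters, CSVs and manifests.

## Problem sizes and numerics

Default analysis sizes were chosen so a full run is seconds: 12–20 lines
× 3 plots, 5 dates × 2 seasons, 10–16 px plot ROIs; 20-series adequacy
checks, 200-series parameter recovery, 1000-draw identity sweeps. Rasters
are float32 (matching camera output); all statistics are computed in
float64. Identity checks (Vmax vs numeric max, closed-form T vs Brent
root) hold to 1e-8 absolute; normalization shift-invariance to 1e-10.

## Known limitations

* Rectangular ROIs may bias CT relative to irregular hand ROIs; this
  cannot be quantified without real imagery.
* The cold/warm/mediate rule is a formalization of a qualitative
  selection; ε is a design default, not an estimated quantity.
* The power of the Welch contrast with 2 lines per type is minimal; the
  letter display degrades gracefully but says little at that size.
* Early filling (before 27 days after flowering) is outside the fitted
  window; alternative growth laws (Richards, Gompertz) are out of scope.
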