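"""Synthetic field-trial generator with known ground truth.

Everything the pipeline consumes can be generated here: thermal rasters of
a plot grid (canopy plus hotter soil gaps, Gaussian sensor noise),
thousand-grain-weight time series following the logistic grain-filling
model, per-line trait tables with a controllable Pearson correlation to
canopy temperature, and daily weather series.  Each generator returns its
ground truth alongside the data so recovery can be tested.

The emulated design is a randomized grid trial: each breeding line is
replicated over several plots, plots are separated by bare-soil gaps, and
two seasons share the layout but differ by a global ambient offset (season
two warmer).  Per-line canopy-temperature structure is a constant offset
from ambient plus a linear trend over the measurement days — the signal
the thermal-type classifier must recover.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .thermal import PlotLayout, PlotRegion, ThermalFrame

__all__ = [
    "FieldSpec",
    "FillingSpec",
    "TraitSpec",
    "plant_line_effects",
    "build_layout",
    "make_thermal_frames",
    "make_filling_series",
    "make_trait_table",
    "make_weather",
    "demo_weather",
    "logistic_weight",
]

DEFAULT_SEASONS = ("S1", "S2")
# Season-two ambient sits +1.5 degC above season one by default, mirroring a
# warmer second year that normalization must cancel.
DEFAULT_BASE_TEMP = {"S1": 25.0, "S2": 26.5}
# Thousand-grain-weight sampling days, t=0 at 27 days after flowering.
DEFAULT_SAMPLING_DAYS = tuple(range(0, 27, 3))


def _line_ids(n: int) -> list[str]:
    return [f"L{i + 1:02d}" for i in range(n)]


@dataclasses.dataclass
class FieldSpec:
    """Design of the synthetic field trial.

    Parameters
    ----------
    n_lines : int
        Number of breeding lines.
    plots_per_line : int
        Replicate plots per line (default 3, a three-replicate design).
    grid_shape : (rows, cols)
        Plot grid; ``rows*cols`` must hold all plots.
    plot_shape : (height, width)
        Plot ROI size in pixels.
    gap : int
        Bare-soil gap between plots, pixels.
    base_temp : mapping season -> degC
        Ambient canopy baseline per season.
    line_offset : mapping line -> degC, optional
        True per-line CT offset from ambient; drawn U(-1, 1) if omitted.
    trend_slope : mapping season -> (mapping line -> degC/day), optional
        True per-line linear CT trend within each season; zero if omitted.
    replicate_sd : float
        SD of a per-plot random effect (within-line spatial variation),
        degC; constant over dates for a given plot.
    noise_sd : float
        Pixel-level sensor noise SD, degC.
    soil_margin : float
        Soil pixels read this much hotter than the season ambient (degC).
    seed : int
        Seed controlling layout randomization, plot effects and noise;
        fixed seed gives bit-identical output.
    """

    n_lines: int
    plots_per_line: int = 3
    grid_shape: tuple[int, int] = (8, 8)
    plot_shape: tuple[int, int] = (12, 12)
    gap: int = 4
    base_temp: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_BASE_TEMP))
    line_offset: Mapping[str, float] | None = None
    trend_slope: Mapping[str, Mapping[str, float]] | None = None
    replicate_sd: float = 0.0
    noise_sd: float = 0.0
    soil_margin: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if self.n_lines * self.plots_per_line > rows * cols:
            raise ValueError(
                f"grid {rows}x{cols} too small for "
                f"{self.n_lines} lines x {self.plots_per_line} plots")
        if self.noise_sd < 0 or self.replicate_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if min(self.plot_shape) < 1 or self.gap < 0:
            raise ValueError("invalid plot geometry")
        self.lines = _line_ids(self.n_lines)
        if self.line_offset is None:
            rng = np.random.default_rng([self.seed, 0])
            self.line_offset = {l: float(v) for l, v in
                                zip(self.lines, rng.uniform(-1.0, 1.0, self.n_lines))}
        missing = set(self.lines) - set(self.line_offset)
        if missing:
            raise ValueError(f"line_offset missing lines: {sorted(missing)}")

    def slope(self, season: str, line: str) -> float:
        if self.trend_slope is None:
            return 0.0
        return float(self.trend_slope.get(season, {}).get(line, 0.0))

    @property
    def seasons(self) -> list[str]:
        return list(self.base_temp)


def plant_line_effects(n_cold: int, n_warm: int, n_mediate: int,
                       slope_mag: float = 0.1, offset_mag: float = 0.8,
                       seasons: Sequence[str] = DEFAULT_SEASONS,
                       seed: int = 0):
    """Plant cold/warm/mediate line effects with known labels.

    Cold lines get a negative CT offset and a decreasing trend in every
    season; warm lines the mirror image; mediate lines get near-zero
    offsets and trend signs that flip between seasons (the unstable
    behaviour that defines the mediate type).

    Returns ``(line_offset, trend_slope, true_type)`` dicts suitable for
    :class:`FieldSpec`.
    """
    rng = np.random.default_rng([seed, 1])
    lines = _line_ids(n_cold + n_warm + n_mediate)
    types = ["cold"] * n_cold + ["warm"] * n_warm + ["mediate"] * n_mediate
    rng.shuffle(types)
    offsets: dict[str, float] = {}
    slopes: dict[str, dict[str, float]] = {s: {} for s in seasons}
    for line, t in zip(lines, types):
        mag = float(rng.uniform(0.7, 1.3))
        if t == "cold":
            offsets[line] = -offset_mag * mag
            for s in seasons:
                slopes[s][line] = -slope_mag
        elif t == "warm":
            offsets[line] = offset_mag * mag
            for s in seasons:
                slopes[s][line] = slope_mag
        else:
            offsets[line] = float(rng.uniform(-0.1, 0.1))
            flip = rng.integers(0, 2)
            for i, s in enumerate(seasons):
                slopes[s][line] = slope_mag * (1 if (i + flip) % 2 else -1)
    return offsets, slopes, dict(zip(lines, types))


def build_layout(spec: FieldSpec) -> PlotLayout:
    """Randomized plot layout with a six-neighbor adjacency.

    Plots are laid on a regular grid with odd rows shifted half a plot
    sideways (offset rows, as planted field rows are), which gives every
    interior plot exactly six nearest neighbors: two same-row flankers and
    two plots in each flanking row.  Line-to-plot assignment is a seeded
    random permutation (a randomized complete design).  Edge plots keep the
    subset of those neighbors that exists.
    """
    rows, cols = spec.grid_shape
    ph, pw = spec.plot_shape
    g = spec.gap
    rng = np.random.default_rng([spec.seed, 2])
    cells = [(r, c) for r in range(rows) for c in range(cols)]
    order = rng.permutation(len(cells))
    assignments = [(line, rep) for line in spec.lines
                   for rep in range(1, spec.plots_per_line + 1)]

    half = (pw + g) // 2  # odd-row sideways shift
    regions = []
    cell_of: dict[tuple[int, int], str] = {}
    for (line, rep), idx in zip(assignments, order):
        r, c = cells[idx]
        row0 = g + r * (ph + g)
        col0 = g + c * (pw + g) + (half if r % 2 else 0)
        pid = f"P{r:02d}{c:02d}"
        regions.append(PlotRegion(pid, line, rep, row0, row0 + ph, col0, col0 + pw))
        cell_of[(r, c)] = pid

    # Offset-row hex neighborhood: same-row +-1; flanking rows at the two
    # nearest column positions given the half shift.
    def hex_neighbors(r: int, c: int):
        shift = 1 if r % 2 else -1
        cand = [(r, c - 1), (r, c + 1),
                (r - 1, c), (r - 1, c + shift),
                (r + 1, c), (r + 1, c + shift)]
        return [cell_of[rc] for rc in cand if rc in cell_of]

    adjacency = {cell_of[(r, c)]: hex_neighbors(r, c)
                 for (r, c) in cell_of}
    return PlotLayout(regions, adjacency)


def _frame_rng(spec: FieldSpec, season: str, date: int) -> np.random.Generator:
    si = spec.seasons.index(season)
    return np.random.default_rng([spec.seed, 3, si, int(date)])


def _plot_effects(spec: FieldSpec, layout: PlotLayout) -> dict[str, float]:
    rng = np.random.default_rng([spec.seed, 4])
    return {r.plot: float(rng.normal(0.0, spec.replicate_sd)) if spec.replicate_sd > 0 else 0.0
            for r in layout.regions}


def make_thermal_frames(spec: FieldSpec, dates: Sequence[int], season: str,
                        layout: PlotLayout | None = None):
    """Generate thermal frames for one season plus the ground-truth CT table.

    Each frame's soil background sits ``soil_margin`` above the season
    ambient; each plot region is filled with its true canopy temperature
    (ambient + line offset + trend*day + per-plot effect) plus pixel noise.

    Returns
    -------
    (frames, truth, layout)
        ``frames`` — list of :class:`ThermalFrame`, one per date;
        ``truth`` — DataFrame (plot, line, season, date, replicate,
        true_ct) of noiseless plot means; ``layout`` — the
        :class:`PlotLayout` used (built from the spec if not supplied).
    """
    if season not in spec.base_temp:
        raise ValueError(f"unknown season {season!r}")
    if layout is None:
        layout = build_layout(spec)
    ambient = float(spec.base_temp[season])
    plot_eff = _plot_effects(spec, layout)

    raster_shape = (
        spec.gap + spec.grid_shape[0] * (spec.plot_shape[0] + spec.gap),
        spec.gap + spec.grid_shape[1] * (spec.plot_shape[1] + spec.gap)
        + (spec.plot_shape[1] + spec.gap) // 2,
    )
    frames, truth_rows = [], []
    for date in dates:
        rng = _frame_rng(spec, season, date)
        pixels = np.full(raster_shape, ambient + spec.soil_margin, dtype=np.float64)
        for region in layout.regions:
            true_ct = (ambient + spec.line_offset[region.line]
                       + spec.slope(season, region.line) * date
                       + plot_eff[region.plot])
            pixels[region.slices()] = true_ct
            truth_rows.append({
                "plot": region.plot, "line": region.line, "season": season,
                "date": int(date), "replicate": region.replicate,
                "true_ct": true_ct,
            })
        if spec.noise_sd > 0:
            pixels += rng.normal(0.0, spec.noise_sd, raster_shape)
        frames.append(ThermalFrame(pixels.astype(np.float32), date=int(date),
                                   season=season,
                                   meta={"ambient_c": ambient, "rh_pct": 60.0}))
    truth = pd.DataFrame(truth_rows)
    return frames, truth, layout


# ---------------------------------------------------------------------------
# Grain filling


def logistic_weight(t, k: float, a: float, b: float):
    """Thousand-grain weight y(t) = k / (1 + a*exp(-b*t))."""
    t = np.asarray(t, dtype=float)
    return k / (1.0 + a * np.exp(-b * t))


@dataclasses.dataclass
class FillingSpec:
    """True logistic parameters per line plus the sampling design.

    ``params`` maps line -> (k, a, b): k the asymptotic thousand-grain
    weight (g), a the shape offset, b the rate (1/day).  ``days`` are
    sampling days with t=0 at 27 days after flowering.  Additive Gaussian
    noise of SD ``noise_sd`` grams emulates sampling/weighing error.
    """

    params: Mapping[str, tuple[float, float, float]]
    days: Sequence[float] = DEFAULT_SAMPLING_DAYS
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for line, (k, a, b) in self.params.items():
            if not (k > 0 and a > 0 and b > 0):
                raise ValueError(f"line {line!r}: k, a, b must all be positive")
        days = list(self.days)
        if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
            raise ValueError("sampling days must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    @staticmethod
    def random(n_lines: int, seed: int = 0, noise_sd: float = 0.5,
               days: Sequence[float] = DEFAULT_SAMPLING_DAYS,
               k_range=(35.0, 55.0), a_range=(10.0, 30.0),
               b_range=(0.15, 0.35)) -> "FillingSpec":
        """Draw per-line (k, a, b) uniformly from realistic wheat ranges."""
        rng = np.random.default_rng([seed, 5])
        params = {
            line: (float(rng.uniform(*k_range)), float(rng.uniform(*a_range)),
                   float(rng.uniform(*b_range)))
            for line in _line_ids(n_lines)
        }
        return FillingSpec(params=params, days=days, noise_sd=noise_sd, seed=seed)


def make_filling_series(spec: FillingSpec) -> pd.DataFrame:
    """Per-line thousand-grain-weight series from the logistic model.

    Returns a DataFrame ``(line, t_days, tgw_g)``; with ``noise_sd == 0``
    the series reproduces the logistic curve to machine precision.
    """
    rng = np.random.default_rng([spec.seed, 6])
    days = np.asarray(list(spec.days), dtype=float)
    parts = []
    for line, (k, a, b) in spec.params.items():
        y = logistic_weight(days, k, a, b)
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd, len(days))
        parts.append(pd.DataFrame({"line": line, "t_days": days, "tgw_g": y}))
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Traits


@dataclasses.dataclass
class TraitSpec:
    """Per-trait distributional targets and trait-CT correlation targets.

    ``traits`` maps trait name -> (mean, sd, target Pearson r with CT).
    Traits are built as ``mean + sd*(r*z + sqrt(1-r^2)*eps)`` with z the
    standardized CT and eps independent standard normal — the implied joint
    correlation matrix (single shared factor) is positive semidefinite for
    any |r| <= 1, which is validated at construction.
    """

    traits: Mapping[str, tuple[float, float, float]]
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (mean, sd, r) in self.traits.items():
            if sd < 0:
                raise ValueError(f"trait {name!r}: sd must be >= 0")
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"trait {name!r}: correlation target {r} outside [-1, 1]")


def make_trait_table(spec: TraitSpec, ct: pd.DataFrame,
                     ct_col: str = "rel_ct") -> pd.DataFrame:
    """Trait table with the requested Pearson correlation to CT.

    ``ct`` supplies one row per observational unit (typically line x date)
    with the CT covariate in ``ct_col``; the returned table carries the
    identifying columns, the CT column and one column per trait.  Sample
    correlations approach the targets as the number of rows grows.
    """
    if ct.empty:
        raise ValueError("CT table is empty")
    if ct_col not in ct.columns:
        raise ValueError(f"CT table lacks column {ct_col!r}")
    rng = np.random.default_rng([spec.seed, 7])
    z = ct[ct_col].to_numpy(dtype=float)
    sd_z = z.std(ddof=1) if len(z) > 1 else 0.0
    z = (z - z.mean()) / sd_z if sd_z > 0 else np.zeros_like(z)
    out = ct.copy()
    for name, (mean, sd, r) in spec.traits.items():
        eps = rng.standard_normal(len(z))
        out[name] = mean + sd * (r * z + math.sqrt(1.0 - r * r) * eps)
    return out


# ---------------------------------------------------------------------------
# Weather


def make_weather(rainfall_mm: Sequence[float],
                 temperature_c: Sequence[float]) -> pd.DataFrame:
    """Daily weather series as a DataFrame (day, rain_mm, temp_c).

    Round-trips losslessly through CSV.  Negative rainfall is rejected.
    """
    rain = np.asarray(list(rainfall_mm), dtype=float)
    temp = np.asarray(list(temperature_c), dtype=float)
    if len(rain) != len(temp):
        raise ValueError("rainfall and temperature series differ in length")
    if (rain < 0).any():
        raise ValueError("rainfall must be non-negative")
    return pd.DataFrame({"day": np.arange(1, len(rain) + 1),
                         "rain_mm": rain, "temp_c": temp})


def demo_weather() -> pd.DataFrame:
    """A wet-season fixture: a 13-day rain spell of 339.3 mm inside a
    60-day filling period totalling 539 mm.

    Emulates a season in which most of the period's rainfall falls in one
    prolonged late spell (26.1 mm/day for 13 days), with the remaining
    199.7 mm spread thinly over the rest of the period.
    """
    n = 60
    rain = np.zeros(n)
    rain[29:42] = 26.1            # 13-day spell, 13 * 26.1 = 339.3 mm
    light_days = [2, 6, 10, 14, 18, 22, 26, 45, 50, 55]
    rain[light_days] = 19.97      # 10 * 19.97 = 199.7 mm
    temp = 22.0 + 6.0 * np.sin(np.linspace(0, np.pi, n)) - 4.0 * (rain > 0)
    return make_weather(rain, temp)
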