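"""Thermal raster I/O, plot layouts and per-plot canopy-temperature extraction.

A field trial is imaged as single-band floating-point temperature rasters
(degrees Celsius, atmospheric correction assumed already applied by the
camera software).  Each plot occupies a rectangular region of interest (ROI)
in the raster; the plot's canopy temperature (CT) is the arithmetic mean of
its unmasked, finite pixels.  Soil pixels, which read hotter than canopy,
can be removed with a simple temperature threshold before averaging.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ThermalFrame",
    "PlotRegion",
    "PlotLayout",
    "read_frame",
    "write_frame",
    "apply_soil_mask",
    "extract_ct",
]

CT_COLUMNS = ["plot", "line", "season", "date", "replicate", "ct_mean", "n_pixels", "n_masked"]


@dataclasses.dataclass
class ThermalFrame:
    """One single-band temperature raster with acquisition metadata.

    Parameters
    ----------
    pixels : ndarray of float
        2-D array of surface temperatures in degrees Celsius.  NaN marks
        dropped (uncalibrated) pixels; infinities are rejected.
    date : int
        Day index within the season (day 0 = first measurement day).
    season : str
        Season label, e.g. ``"2022"``.
    meta : dict
        Free-form acquisition metadata (ambient temperature, relative
        humidity, ...).  Round-trips through the TIFF description tag.
    """

    pixels: np.ndarray
    date: int
    season: str
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if np.isinf(self.pixels).any():
            raise ValueError("pixels contain infinite temperatures")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclasses.dataclass(frozen=True)
class PlotRegion:
    """Axis-aligned plot ROI with 0-based, half-open pixel bounds."""

    plot: str
    line: str
    replicate: int
    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        if not (0 <= self.row0 < self.row1 and 0 <= self.col0 < self.col1):
            raise ValueError(f"plot {self.plot!r}: bounds must be non-empty half-open intervals")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)

    @property
    def n_pixels(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)


class PlotLayout:
    """Map from plot ids to raster regions plus a plot adjacency relation.

    Invariants enforced at construction: plot regions pairwise disjoint,
    adjacency symmetric, no plot adjacent to itself, all adjacency entries
    name known plots.
    """

    def __init__(self, regions: Sequence[PlotRegion], adjacency: Mapping[str, Sequence[str]]):
        self.regions: list[PlotRegion] = list(regions)
        self.adjacency: dict[str, list[str]] = {p: sorted(ns) for p, ns in adjacency.items()}
        self._by_id = {r.plot: r for r in self.regions}
        if len(self._by_id) != len(self.regions):
            raise ValueError("duplicate plot ids in layout")
        self._validate()

    def _validate(self) -> None:
        # Disjointness: intervals on both axes must not overlap simultaneously
        regs = self.regions
        for i, a in enumerate(regs):
            for b in regs[i + 1 :]:
                if a.row0 < b.row1 and b.row0 < a.row1 and a.col0 < b.col1 and b.col0 < a.col1:
                    raise ValueError(f"plot regions {a.plot!r} and {b.plot!r} overlap")
        for p, neighbors in self.adjacency.items():
            if p not in self._by_id:
                raise ValueError(f"adjacency lists unknown plot {p!r}")
            for q in neighbors:
                if q not in self._by_id:
                    raise ValueError(f"plot {p!r} adjacent to unknown plot {q!r}")
                if q == p:
                    raise ValueError(f"plot {p!r} is adjacent to itself")
                if p not in self.adjacency.get(q, ()):
                    raise ValueError(f"adjacency not symmetric: {p!r}->{q!r}")

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, plot: str) -> PlotRegion:
        return self._by_id[plot]

    def neighbors(self, plot: str) -> list[str]:
        return self.adjacency.get(plot, [])

    def check_frame(self, frame: ThermalFrame) -> None:
        """Raise if any region falls outside the frame."""
        nr, nc = frame.shape
        for r in self.regions:
            if r.row1 > nr or r.col1 > nc:
                raise ValueError(f"plot {r.plot!r} bounds exceed raster shape {frame.shape}")

    # --- YAML round-trip -------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "plots": [dataclasses.asdict(r) for r in self.regions],
            "adjacency": self.adjacency,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlotLayout":
        doc = yaml.safe_load(Path(path).read_text())
        regions = [PlotRegion(**entry) for entry in doc["plots"]]
        return cls(regions, doc.get("adjacency", {}))


def write_frame(frame: ThermalFrame, path: str | Path) -> None:
    """Write a frame as a single-band float32 TIFF.

    Metadata (date, season, meta dict) is stored as JSON in the TIFF
    description tag so that ``read_frame(write_frame(x)) == x``.
    """
    desc = json.dumps({"date": frame.date, "season": frame.season, "meta": frame.meta})
    tifffile.imwrite(Path(path), frame.pixels.astype(np.float32), description=desc)


def read_frame(path: str | Path, date: int | None = None, season: str | None = None,
               meta: dict | None = None) -> ThermalFrame:
    """Read a single-band float TIFF as a :class:`ThermalFrame`.

    Explicit ``date``/``season``/``meta`` arguments override anything found
    in the file's description tag.  Multi-band or integer rasters are
    rejected: the pipeline only deals in calibrated floating-point
    temperatures.
    """
    with tifffile.TiffFile(Path(path)) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        desc = page.description
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.floating):
        raise ValueError(f"{path}: expected floating-point temperatures, got dtype {arr.dtype}")
    header: dict = {}
    if desc:
        try:
            header = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            header = {}
    return ThermalFrame(
        pixels=arr,
        date=date if date is not None else int(header.get("date", 0)),
        season=season if season is not None else str(header.get("season", "")),
        meta=meta if meta is not None else dict(header.get("meta", {})),
    )


def apply_soil_mask(frame: ThermalFrame, threshold: float) -> np.ndarray:
    """Boolean mask of pixels to exclude: True where temperature > threshold.

    Soil reads hotter than canopy under radiation load, so a fixed ceiling
    removes bare-ground pixels from ROI means.  NaN pixels are never part of
    the mask (they are excluded from means regardless).
    """
    if not np.isfinite(threshold):
        if threshold == np.inf:
            return np.zeros(frame.shape, dtype=bool)
        raise ValueError("threshold must be finite or +inf")
    with np.errstate(invalid="ignore"):
        return frame.pixels > threshold


def extract_ct(frame: ThermalFrame, layout: PlotLayout,
               mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-plot mean canopy temperature for one frame.

    Parameters
    ----------
    frame : ThermalFrame
    layout : PlotLayout
        Must fit inside the frame.
    mask : bool ndarray, optional
        Pixels to exclude (e.g. from :func:`apply_soil_mask`); same shape as
        the frame.

    Returns
    -------
    DataFrame with columns ``plot, line, season, date, replicate, ct_mean,
    n_pixels, n_masked`` — one row per plot.  ``ct_mean`` is the arithmetic
    mean of unmasked, finite pixels; ``n_masked`` counts pixels removed by
    the mask or by being NaN.

    Raises
    ------
    ValueError
        If the layout exceeds the frame, the mask shape mismatches, or a
        plot has no usable pixels left (fully masked).
    """
    layout.check_frame(frame)
    if mask is not None and mask.shape != frame.shape:
        raise ValueError(f"mask shape {mask.shape} != frame shape {frame.shape}")
    rows = []
    for region in layout.regions:
        sl = region.slices()
        block = frame.pixels[sl].astype(np.float64)
        good = np.isfinite(block)
        if mask is not None:
            good &= ~mask[sl]
        n_good = int(good.sum())
        if n_good == 0:
            raise ValueError(f"plot {region.plot!r} has no usable pixels (fully masked)")
        rows.append({
            "plot": region.plot,
            "line": region.line,
            "season": frame.season,
            "date": frame.date,
            "replicate": region.replicate,
            "ct_mean": float(block[good].mean()),
            "n_pixels": n_good,
            "n_masked": int(region.n_pixels - n_good),
        })
    return pd.DataFrame(rows, columns=CT_COLUMNS)


def extract_ct_frames(frames: Sequence[ThermalFrame], layout: PlotLayout,
                      soil_threshold: float | None = None) -> pd.DataFrame:
    """Extract CT for a sequence of frames, optionally soil-masking each."""
    parts = []
    for frame in frames:
        m = apply_soil_mask(frame, soil_threshold) if soil_threshold is not None else None
        parts.append(extract_ct(frame, layout, mask=m))
    return pd.concat(parts, ignore_index=True)
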