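"""Neighbor-based canopy-temperature normalization.

Raw plot CT confounds genotype with ambient conditions (weather, time of
day, camera drift), which differ between measurement days and between
seasons.  Subtracting the mean CT of each plot's adjacent plots removes
any effect shared by a neighborhood — in particular a global per-date or
per-season offset — leaving a relative CT on which lines can be compared
across dates and years.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["normalize", "season_offset_check"]


def _rel_one_date(sub: pd.DataFrame, adjacency: Mapping[str, Sequence[str]]) -> pd.Series:
    ct = sub.set_index("plot")["ct_mean"]
    rel = {}
    for plot, value in ct.items():
        neighbors = adjacency.get(plot, [])
        if not neighbors:
            raise ValueError(f"plot {plot!r} has no neighbors; cannot normalize")
        present = [q for q in neighbors if q in ct.index]
        if len(present) < len(neighbors):
            missing = sorted(set(neighbors) - set(present))
            warnings.warn(
                f"plot {plot!r}: neighbors {missing} missing on "
                f"season {sub['season'].iat[0]!r} date {sub['date'].iat[0]}; "
                "dropped from the neighbor mean", stacklevel=3)
        if not present:
            raise ValueError(f"plot {plot!r} has no neighbor with a CT value on this date")
        rel[plot] = value - ct.loc[present].mean()
    return pd.Series(rel, name="rel_ct")


def normalize(ct: pd.DataFrame, adjacency: Mapping[str, Sequence[str]],
              order: str = "normalize_first") -> pd.DataFrame:
    """Relative CT per (line, season, date).

    For every plot p on a given date, ``rel_ct(p) = ct(p) - mean{ct(q): q
    adjacent to p}``.  Replicate plots of the same line are then averaged
    to a single per-line value.

    Parameters
    ----------
    ct : DataFrame
        Raw CT rows with columns ``plot, line, season, date, ct_mean``
        (one row per plot per date), e.g. from
        :func:`thermotype.thermal.extract_ct`.
    adjacency : mapping plot -> neighbor plots
        Spatial neighborhood, e.g. ``PlotLayout.adjacency``.
    order : {"normalize_first", "average_first"}
        ``normalize_first`` (default) subtracts neighbor means from raw
        plot values and then averages replicates; ``average_first``
        replaces each plot's CT by its line's mean CT on that date before
        subtraction.  The two orders coincide when replicates of a line
        agree exactly.

    Returns
    -------
    DataFrame ``(line, season, date, rel_ct)``, one row per combination.

    Raises
    ------
    ValueError
        If a plot has no neighbors at all (isolated plot), or none of its
        neighbors carries a CT value on some date.  A neighbor missing on
        a single date is merely dropped from the mean, with a warning.
    """
    if order not in ("normalize_first", "average_first"):
        raise ValueError(f"unknown order {order!r}")
    ct = ct.copy()
    if order == "average_first":
        ct["ct_mean"] = ct.groupby(["line", "season", "date"])["ct_mean"].transform("mean")
    parts = []
    for (season, date), sub in ct.groupby(["season", "date"], sort=True):
        rel = _rel_one_date(sub, adjacency)
        merged = sub.merge(rel.rename("rel_ct"), left_on="plot", right_index=True)
        parts.append(merged[["line", "season", "date", "rel_ct"]])
    out = (pd.concat(parts, ignore_index=True)
           .groupby(["line", "season", "date"], as_index=False)["rel_ct"].mean())
    return out


def season_offset_check(ct: pd.DataFrame) -> pd.DataFrame:
    """Mean raw-CT difference between two seasons at paired dates.

    The two seasons' measurement days are paired by their shared date
    label; for each paired date the mean CT over all plots is differenced
    (second season minus first, in season sort order).  Dates present in
    only one season are excluded with a warning.

    Returns a DataFrame ``(date, mean_s1, mean_s2, diff)``.
    """
    seasons = sorted(ct["season"].unique())
    if len(seasons) != 2:
        raise ValueError(f"expected exactly 2 seasons, found {seasons}")
    s1, s2 = seasons
    m = (ct.groupby(["season", "date"])["ct_mean"].mean()
         .unstack("season"))
    unpaired = m.index[m[[s1, s2]].isna().any(axis=1)]
    if len(unpaired):
        warnings.warn(f"dates {list(unpaired)} present in only one season; excluded",
                      stacklevel=2)
        m = m.drop(index=unpaired)
    out = pd.DataFrame({
        "date": m.index,
        "mean_s1": m[s1].to_numpy(),
        "mean_s2": m[s2].to_numpy(),
    })
    out["diff"] = out["mean_s2"] - out["mean_s1"]
    return out.reset_index(drop=True)
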