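"""Thermal-type classification of lines from multi-season relative CT.

A line whose canopy runs consistently cooler than its neighbors and keeps
cooling through grain filling in every season is a cold-type line; the
mirror image is warm-type; everything inconsistent between seasons is
mediate-type.  The call is made from two per-season summaries of the
relative-CT trajectory: the ordinary-least-squares trend slope and the
mean level.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TypeCall", "trend_slope", "classify", "classify_table"]

#: Default slope tolerance (degC/day): slopes within +-epsilon of zero are
#: treated as flat, so near-zero trends never force a cold/warm call.
DEFAULT_EPSILON = 0.01


@dataclasses.dataclass(frozen=True)
class TypeCall:
    """Classification of one line with its per-season evidence."""

    line: str
    call: str  # "cold" | "warm" | "mediate"
    slopes: dict  # season -> degC/day
    means: dict  # season -> mean relative CT, degC


def trend_slope(days, rel_ct) -> float:
    """OLS slope of relative CT on day index within one season (degC/day)."""
    days = np.asarray(days, dtype=float)
    rel_ct = np.asarray(rel_ct, dtype=float)
    if len(days) < 3:
        raise ValueError(f"need >=3 dates for a trend, got {len(days)}")
    if np.ptp(days) == 0:
        raise ValueError("all dates identical; slope undefined")
    return float(stats.linregress(days, rel_ct).slope)


def classify(slopes: dict, means: dict, epsilon: float = DEFAULT_EPSILON) -> str:
    """Apply the cold/warm/mediate rule to per-season slopes and means.

    cold    iff slope < -epsilon AND mean < 0 in *every* season;
    warm    iff slope > +epsilon AND mean > 0 in *every* season;
    mediate otherwise.

    Requiring both the trend and the level is the conservative reading of a
    selection made "on trends and averages": a line must be consistently
    cool *and* cooling (resp. warm and warming) across all seasons.
    """
    if set(slopes) != set(means) or not slopes:
        raise ValueError("slopes and means must cover the same non-empty season set")
    if all(s < -epsilon for s in slopes.values()) and all(m < 0 for m in means.values()):
        return "cold"
    if all(s > epsilon for s in slopes.values()) and all(m > 0 for m in means.values()):
        return "warm"
    return "mediate"


def classify_table(rel: pd.DataFrame, epsilon: float = DEFAULT_EPSILON,
                   min_seasons: int = 2) -> pd.DataFrame:
    """Classify every line in a relative-CT table.

    Parameters
    ----------
    rel : DataFrame
        ``(line, season, date, rel_ct)`` as produced by
        :func:`thermotype.normct.normalize`; every line must appear in at
        least ``min_seasons`` seasons with >=3 dates each.
    epsilon : float
        Slope tolerance in degC/day (see :func:`classify`).

    Returns
    -------
    DataFrame with one row per line: ``line, call`` plus ``slope_<season>``
    and ``mean_<season>`` evidence columns.  Calls partition the line set.
    """
    seasons = sorted(rel["season"].unique())
    rows = []
    for line, sub in rel.groupby("line", sort=True):
        line_seasons = sorted(sub["season"].unique())
        if len(line_seasons) < min_seasons:
            raise ValueError(
                f"line {line!r} observed in {len(line_seasons)} season(s); "
                f"need >={min_seasons}")
        slopes, means = {}, {}
        for season in line_seasons:
            ss = sub[sub["season"] == season].sort_values("date")
            slopes[season] = trend_slope(ss["date"], ss["rel_ct"])
            means[season] = float(ss["rel_ct"].mean())
        row = {"line": line, "call": classify(slopes, means, epsilon)}
        for season in seasons:
            row[f"slope_{season}"] = slopes.get(season, np.nan)
            row[f"mean_{season}"] = means.get(season, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
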