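"""Association reporting: correlation panels, group contrasts, weather sums.

Mirrors the reporting conventions of field-phenotyping studies: Pearson
correlation matrices with significance stars, cold-vs-warm group contrasts
with percent differences and compact-letter displays, dry-matter deltas
between sampling dates, and rainfall window summaries.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "star",
    "correlation_panel",
    "group_contrast",
    "dry_matter_delta",
    "weather_summary",
    "plot_corr_heatmap",
]

_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def star(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else empty."""
    if not np.isfinite(p):
        return ""
    for level, s in _STAR_LEVELS:
        if p < level:
            return s
    return ""


def correlation_panel(table: pd.DataFrame, variables: Sequence[str],
                      by: str | None = None,
                      bh_correct: bool = False) -> pd.DataFrame:
    """Pairwise Pearson correlations with two-sided p-values and stars.

    Missing values are excluded pairwise; each cell needs >=3 complete
    pairs.  A variable with zero variance in a cell yields an undefined
    (NaN) correlation, never a fabricated 0.  p-values come from the exact
    t-transform with n-2 degrees of freedom.

    Parameters
    ----------
    table : DataFrame with one column per variable.
    variables : which columns to correlate.
    by : optional column to split the panel on (e.g. measurement date).
    bh_correct : apply Benjamini-Hochberg correction across each panel's
        off-diagonal cells before assigning stars (off by default, matching
        per-cell reporting).

    Returns
    -------
    Long DataFrame ``(group?, var1, var2, r, p, star, n)`` covering every
    unordered pair including the unit diagonal.
    """
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"variables not in table: {missing}")
    groups = [(None, table)] if by is None else list(table.groupby(by, sort=True))
    parts = []
    for gname, sub in groups:
        rows = []
        for v1, v2 in itertools.combinations_with_replacement(variables, 2):
            x = sub[v1].to_numpy(dtype=float)
            y = sub[v2].to_numpy(dtype=float)
            good = np.isfinite(x) & np.isfinite(y)
            n = int(good.sum())
            if v1 == v2:
                r, p = 1.0, 0.0
            elif n < 3:
                raise ValueError(f"pair ({v1}, {v2}): only {n} complete pairs, need >=3")
            elif np.ptp(x[good]) == 0 or np.ptp(y[good]) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x[good], y[good])
            rows.append({"var1": v1, "var2": v2, "r": float(r), "p": float(p), "n": n})
        panel = pd.DataFrame(rows)
        off = (panel["var1"] != panel["var2"]) & panel["p"].notna()
        p_for_stars = panel["p"].copy()
        if bh_correct and off.any():
            from statsmodels.stats.multitest import multipletests
            p_for_stars.loc[off] = multipletests(panel.loc[off, "p"], method="fdr_bh")[1]
        panel["star"] = [star(p) for p in p_for_stars]
        if by is not None:
            panel.insert(0, by, gname)
        parts.append(panel)
    return pd.concat(parts, ignore_index=True)


def plot_corr_heatmap(panel: pd.DataFrame, path=None):
    """Render a correlation panel as an annotated heatmap (r value + stars).

    Requires matplotlib (the ``plot`` extra).  Returns the Axes; saves a
    PNG when ``path`` is given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    variables = list(dict.fromkeys(panel["var1"]))
    mat = panel.pivot_table(index="var1", columns="var2", values="r")
    mat = mat.combine_first(mat.T).reindex(index=variables, columns=variables)
    stars = {(r["var1"], r["var2"]): r["star"] for _, r in panel.iterrows()}
    fig, ax = plt.subplots(figsize=(1 + 0.7 * len(variables),) * 2)
    im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(variables)), variables, rotation=45, ha="right")
    ax.set_yticks(range(len(variables)), variables)
    for i, v1 in enumerate(variables):
        for j, v2 in enumerate(variables):
            r = mat.iloc[i, j]
            if np.isfinite(r):
                s = stars.get((v1, v2)) or stars.get((v2, v1)) or ""
                ax.text(j, i, f"{r:.2f}{s}", ha="center", va="center",
                        fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8, label="Pearson r")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax


def _letters_from_pairs(groups: Sequence[str], sig: Mapping[frozenset, bool]) -> dict:
    """Compact-letter display by the insert-and-absorb algorithm.

    Groups sharing a letter are not significantly different; significantly
    different groups never share one.
    """
    letter_sets: list[set[str]] = [set(groups)]
    for (pair, is_sig) in sig.items():
        if not is_sig:
            continue
        g1, g2 = sorted(pair)
        for s in list(letter_sets):
            if g1 in s and g2 in s:
                letter_sets.remove(s)
                a, b = s - {g2}, s - {g1}
                for new in (a, b):
                    if not any(new <= other for other in letter_sets):
                        letter_sets.append(new)
    letter_sets.sort(key=lambda s: sorted(s))
    out: dict[str, str] = {g: "" for g in groups}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", letter_sets):
        for g in s:
            out[g] += letter
    return out


def group_contrast(values: pd.DataFrame, trait: str, group_col: str = "call",
                   reference: str | None = None, alpha: float = 0.05) -> dict:
    """Group means, percent difference and Welch test for one trait.

    Parameters
    ----------
    values : DataFrame with a group label column and the trait column.
    trait : trait column name.
    group_col : group label column (default the type-call column).
    reference : the group to express the percent difference against
        (denominator); defaults to the second group in sorted order, so a
        cold-vs-warm contrast reports how much higher cold is than warm.
    alpha : significance level for the compact-letter display.

    Returns
    -------
    dict with ``means`` (group -> mean), ``n`` (group -> size),
    ``abs_diff``, ``pct_diff`` (first non-reference group vs reference,
    in percent), ``welch_p`` and ``letters``.  With a singleton group the
    difference is still reported but the test is skipped with a warning
    (p = NaN, all groups share a letter).
    """
    sub = values[[group_col, trait]].dropna()
    groups = sorted(sub[group_col].unique())
    if len(groups) < 2:
        raise ValueError(f"need >=2 non-empty groups, found {groups}")
    by_group = {g: sub.loc[sub[group_col] == g, trait].to_numpy(dtype=float)
                for g in groups}
    means = {g: float(v.mean()) for g, v in by_group.items()}
    sizes = {g: int(len(v)) for g, v in by_group.items()}

    if reference is None:
        reference = groups[1] if len(groups) == 2 else groups[-1]
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")
    other = next(g for g in groups if g != reference)
    abs_diff = means[other] - means[reference]
    pct_diff = (100.0 * abs_diff / means[reference]
                if means[reference] != 0 else np.nan)

    skip_test = any(n < 2 for n in sizes.values())
    if skip_test:
        warnings.warn("a group has fewer than 2 observations; Welch test skipped",
                      stacklevel=2)
    sig: dict[frozenset, bool] = {}
    pairwise_p: dict[tuple, float] = {}
    for g1, g2 in itertools.combinations(groups, 2):
        if skip_test and (sizes[g1] < 2 or sizes[g2] < 2):
            p = np.nan
        else:
            p = float(stats.ttest_ind(by_group[g1], by_group[g2], equal_var=False).pvalue)
        pairwise_p[(g1, g2)] = p
        sig[frozenset((g1, g2))] = bool(np.isfinite(p) and p < alpha)
    welch_p = pairwise_p[tuple(sorted((other, reference)))]
    return {
        "means": means, "n": sizes,
        "comparison": (other, reference),
        "abs_diff": float(abs_diff), "pct_diff": float(pct_diff),
        "welch_p": welch_p, "pairwise_p": pairwise_p,
        "letters": _letters_from_pairs(groups, sig),
    }


def dry_matter_delta(weights: pd.DataFrame, dap_from: int = 27,
                     dap_to: int = 33) -> pd.DataFrame:
    """Per-line dry-matter change between two sampling dates.

    ``weights`` is long-form ``(line, organ, dap, weight_g)``; the delta is
    ``weight(dap_to) - weight(dap_from)`` per (line, organ).  Lines missing
    either date are skipped with a warning.
    """
    need = {"line", "organ", "dap", "weight_g"}
    if not need <= set(weights.columns):
        raise ValueError(f"weights table needs columns {sorted(need)}")
    rows, skipped = [], []
    for (line, organ), sub in weights.groupby(["line", "organ"], sort=True):
        w = sub.set_index("dap")["weight_g"]
        if dap_from not in w.index or dap_to not in w.index:
            skipped.append((line, organ))
            continue
        rows.append({"line": line, "organ": organ,
                     "delta_g": float(w.loc[dap_to] - w.loc[dap_from])})
    if skipped:
        warnings.warn(f"missing {dap_from} or {dap_to} DAP weight for {skipped}; skipped",
                      stacklevel=2)
    return pd.DataFrame(rows, columns=["line", "organ", "delta_g"])


def weather_summary(weather: pd.DataFrame, window: tuple[int, int],
                    period: tuple[int, int] | None = None) -> dict:
    """Rainfall totals for a window inside a period, with the window's share.

    Parameters
    ----------
    weather : DataFrame ``(day, rain_mm, ...)``.
    window : (first_day, last_day), inclusive on both ends.
    period : (first_day, last_day); defaults to the full series.

    Returns
    -------
    dict: ``window_total_mm``, ``period_total_mm``, ``fraction_pct`` (full
    precision) and ``fraction_pct_rounded`` (integer percent, the form
    such studies print).  With a zero period total the fraction is NaN.
    """
    if period is None:
        period = (int(weather["day"].min()), int(weather["day"].max()))
    w0, w1 = window
    p0, p1 = period
    if not (p0 <= w0 <= w1 <= p1):
        raise ValueError(f"window {window} not inside period {period}")
    day = weather["day"]
    period_total = float(weather.loc[day.between(p0, p1), "rain_mm"].sum())
    window_total = float(weather.loc[day.between(w0, w1), "rain_mm"].sum())
    if period_total > 0:
        frac = 100.0 * window_total / period_total
        frac_round: float | int = int(round(frac))
    else:
        frac, frac_round = float("nan"), float("nan")
    return {
        "window_total_mm": window_total,
        "period_total_mm": period_total,
        "fraction_pct": frac,
        "fraction_pct_rounded": frac_round,
    }
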