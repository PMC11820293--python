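"""Correlation panels, group contrasts, dry-matter deltas, weather sums."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thermotype import synthgen
from thermotype.assoc import (correlation_panel, dry_matter_delta,
                              group_contrast, star, weather_summary)


def pearson_oracle(x, y):
    """Covariance-formula r and t-transform p, independent of scipy."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    r = (xc * yc).sum() / math.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p


class TestStars:
    @pytest.mark.parametrize("p,expected", [
        (0.0005, "***"), (0.001, "**"), (0.005, "**"), (0.01, "*"),
        (0.04, "*"), (0.05, ""), (0.5, ""), (float("nan"), ""),
    ])
    def test_thresholds(self, p, expected):
        assert star(p) == expected


class TestCorrelationPanel:
    def test_exact_linear_dependence(self):
        df = pd.DataFrame({"x": np.arange(8.0)})
        df["y"] = 2 * df["x"] + 3
        panel = correlation_panel(df, ["x", "y"]).set_index(["var1", "var2"])
        cell = panel.loc[("x", "y")]
        assert cell["r"] == pytest.approx(1.0)
        assert cell["star"] == "***"

    def test_exact_negative(self):
        df = pd.DataFrame({"x": np.arange(6.0)})
        df["y"] = -df["x"]
        panel = correlation_panel(df, ["x", "y"]).set_index(["var1", "var2"])
        assert panel.loc[("x", "y"), "r"] == pytest.approx(-1.0)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.normal(size=20), "y": rng.normal(size=20)})
        panel = correlation_panel(df, ["x", "y"]).set_index(["var1", "var2"])
        r_o, p_o = pearson_oracle(df["x"], df["y"])
        assert panel.loc[("x", "y"), "r"] == pytest.approx(r_o, abs=1e-12)
        assert panel.loc[("x", "y"), "p"] == pytest.approx(p_o, rel=1e-9)

    def test_zero_variance_cell_undefined(self):
        df = pd.DataFrame({"x": np.arange(6.0), "y": np.full(6, 3.0)})
        panel = correlation_panel(df, ["x", "y"]).set_index(["var1", "var2"])
        assert math.isnan(panel.loc[("x", "y"), "r"])
        assert panel.loc[("x", "y"), "star"] == ""

    def test_unit_diagonal_and_pairwise_deletion(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("abc"))
        df.loc[3:6, "b"] = np.nan
        panel = correlation_panel(df, list("abc")).set_index(["var1", "var2"])
        for v in "abc":
            assert panel.loc[(v, v), "r"] == 1.0
        assert panel.loc[("a", "b"), "n"] == 11
        assert panel.loc[("a", "c"), "n"] == 15

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"x": rng.normal(size=30), "y": rng.normal(size=30)})
        df2 = pd.DataFrame({"x": 5 * df["x"] - 2, "y": 0.1 * df["y"] + 7})
        r1 = correlation_panel(df, ["x", "y"]).set_index(["var1", "var2"]).loc[("x", "y"), "r"]
        r2 = correlation_panel(df2, ["x", "y"]).set_index(["var1", "var2"]).loc[("x", "y"), "r"]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_no_star_above_threshold(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        panel = correlation_panel(df, list("abcd"))
        for _, row in panel.iterrows():
            if row["star"] == "":
                assert not (row["p"] < 0.05)
            else:
                assert row["p"] < {"*": 0.05, "**": 0.01, "***": 0.001}[row["star"]]

    def test_too_few_pairs_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 1.0]})
        with pytest.raises(ValueError, match=">=3"):
            correlation_panel(df, ["x", "y"])

    def test_negative_ct_pn_cell_recovered(self):
        """Planted strong negative CT-Pn correlation shows as a *** cell."""
        rng = np.random.default_rng(8)
        ct = pd.DataFrame({"line": [f"L{i}" for i in range(60)],
                           "rel_ct": rng.normal(0, 0.8, 60)})
        spec = synthgen.TraitSpec(traits={"Pn": (20.0, 3.0, -0.9)}, seed=8)
        table = synthgen.make_trait_table(spec, ct)
        panel = correlation_panel(table, ["rel_ct", "Pn"]).set_index(["var1", "var2"])
        cell = panel.loc[("rel_ct", "Pn")]
        assert cell["r"] < -0.7
        assert cell["star"] == "***"


class TestGroupContrast:
    @staticmethod
    def _table(cold, warm):
        return pd.DataFrame({
            "call": ["cold"] * len(cold) + ["warm"] * len(warm),
            "Pn": list(cold) + list(warm)})

    def test_twenty_percent_higher(self):
        out = group_contrast(self._table([11.0, 12.0, 13.0], [9.0, 10.0, 11.0]),
                             "Pn")
        assert out["means"] == {"cold": 12.0, "warm": 10.0}
        assert out["pct_diff"] == pytest.approx(20.0)
        assert out["comparison"] == ("cold", "warm")

    def test_identical_groups_share_letter(self):
        out = group_contrast(self._table([10.0, 11.0, 12.0], [10.0, 11.0, 12.0]),
                             "Pn")
        assert out["pct_diff"] == pytest.approx(0.0)
        assert out["welch_p"] > 0.9
        assert out["letters"]["cold"] == out["letters"]["warm"]

    def test_separated_groups_differ_in_letters(self):
        out = group_contrast(self._table([20.0, 20.1, 19.9, 20.2],
                                         [10.0, 10.1, 9.9, 10.2]), "Pn")
        assert out["welch_p"] < 0.001
        assert set(out["letters"]["cold"]).isdisjoint(out["letters"]["warm"])

    def test_singleton_group_skips_test(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = group_contrast(self._table([12.0], [9.0, 10.0, 11.0]), "Pn")
        assert out["pct_diff"] == pytest.approx(20.0)
        assert math.isnan(out["welch_p"])
        assert out["letters"]["cold"] == out["letters"]["warm"]

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match=">=2"):
            group_contrast(pd.DataFrame({"call": ["cold"] * 3,
                                         "Pn": [1.0, 2.0, 3.0]}), "Pn")

    def test_rejection_rate_matches_power_oracle(self):
        """Welch rejection rate at d=1, n=30/30 matches analytic power."""
        from statsmodels.stats.power import TTestIndPower
        power = TTestIndPower().power(effect_size=1.0, nobs1=30, ratio=1.0,
                                      alpha=0.05)
        rng = np.random.default_rng(9)
        n_sim, hits = 300, 0
        for _ in range(n_sim):
            df = self._table(rng.normal(1.0, 1.0, 30), rng.normal(0.0, 1.0, 30))
            if group_contrast(df, "Pn")["welch_p"] < 0.05:
                hits += 1
        rate = hits / n_sim
        mc_err = 3 * math.sqrt(power * (1 - power) / n_sim)
        assert rate == pytest.approx(power, abs=max(mc_err, 0.04))


class TestDryMatterDelta:
    def test_simple_delta(self):
        w = pd.DataFrame({"line": ["L1"] * 2, "organ": ["spike"] * 2,
                          "dap": [27, 33], "weight_g": [30.0, 41.5]})
        out = dry_matter_delta(w)
        assert out["delta_g"].iloc[0] == pytest.approx(11.5)

    def test_equal_weights_zero(self):
        w = pd.DataFrame({"line": ["L1"] * 2, "organ": ["stem"] * 2,
                          "dap": [27, 33], "weight_g": [12.0, 12.0]})
        assert dry_matter_delta(w)["delta_g"].iloc[0] == 0.0

    def test_matches_rowwise_oracle(self):
        rng = np.random.default_rng(10)
        rows = []
        for line in [f"L{i}" for i in range(6)]:
            for organ in ("spike", "stem", "whole"):
                for dap in (27, 33):
                    rows.append({"line": line, "organ": organ, "dap": dap,
                                 "weight_g": float(rng.uniform(5, 50))})
        w = pd.DataFrame(rows)
        out = dry_matter_delta(w).set_index(["line", "organ"])["delta_g"]
        for (line, organ), sub in w.groupby(["line", "organ"]):
            d = dict(zip(sub["dap"], sub["weight_g"]))
            assert out.loc[(line, organ)] == pytest.approx(d[33] - d[27])

    def test_missing_date_skipped_with_warning(self):
        w = pd.DataFrame({"line": ["L1", "L2", "L2"],
                          "organ": ["spike"] * 3,
                          "dap": [27, 27, 33],
                          "weight_g": [30.0, 28.0, 39.0]})
        with pytest.warns(UserWarning, match="L1"):
            out = dry_matter_delta(w)
        assert out["line"].tolist() == ["L2"]


class TestWeatherSummary:
    def test_window_equals_period(self):
        w = synthgen.make_weather([1.0] * 10, [20.0] * 10)
        out = weather_summary(w, window=(1, 10))
        assert out["fraction_pct"] == pytest.approx(100.0)

    def test_wet_spell_fraction(self):
        """A 339.3 mm spell in a 539 mm season is 63% after rounding."""
        out = weather_summary(synthgen.demo_weather(), window=(30, 42))
        assert out["window_total_mm"] == pytest.approx(339.3, abs=1e-9)
        assert out["period_total_mm"] == pytest.approx(539.0, abs=1e-9)
        assert out["fraction_pct"] == pytest.approx(62.95, abs=0.01)
        assert out["fraction_pct_rounded"] == 63

    def test_disjoint_windows_partition_total(self):
        rng = np.random.default_rng(11)
        w = synthgen.make_weather(rng.uniform(0, 10, 30), np.full(30, 20.0))
        parts = [weather_summary(w, window=(a, b))["window_total_mm"]
                 for a, b in ((1, 10), (11, 20), (21, 30))]
        assert sum(parts) == pytest.approx(float(w["rain_mm"].sum()), abs=1e-9)

    def test_zero_period_fraction_undefined(self):
        w = synthgen.make_weather([0.0] * 5, [20.0] * 5)
        out = weather_summary(w, window=(2, 3))
        assert math.isnan(out["fraction_pct"])

    def test_window_outside_period_rejected(self):
        w = synthgen.make_weather([1.0] * 5, [20.0] * 5)
        with pytest.raises(ValueError, match="inside"):
            weather_summary(w, window=(3, 9))
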