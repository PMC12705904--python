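"""Indentation-depth binning, ANOVA with Bonferroni, group comparison and
the logarithmic trend fit."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ramident.indentation import (
    NO_DATA,
    anova_bins,
    bin_depths,
    compare_near_lumen,
    fit_log_trend,
)
from ramident.synthetic import generate_indentation


def records(distances, depths, group="test"):
    return pd.DataFrame(
        {
            "tooth_id": "T05",
            "quadrant": "A",
            "distance_um": np.asarray(distances, float),
            "depth_um": np.asarray(depths, float),
            "group": group,
        }
    )


def brute_force_f(groups):
    """One-way ANOVA F from explicit sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestBinDepths:
    def test_single_record_per_bin(self):
        out = bin_depths(records([50.0, 150.0], [70.0, 60.0]))
        assert out.loc[out["bin"] == "Up to 100 um", "mean"].iloc[0] == 70.0
        assert out.loc[out["bin"] == "> 100-200 um", "mean"].iloc[0] == 60.0

    def test_empty_bin_reports_no_data(self):
        out = bin_depths(records([50.0], [70.0]))
        row = out[out["bin"] == "> 300-400 um"].iloc[0]
        assert row["n"] == 0
        assert row["note"] == NO_DATA

    def test_mean_and_sample_sd(self):
        out = bin_depths(records([50.0, 60.0], [60.0, 70.0]))
        row = out[out["bin"] == "Up to 100 um"].iloc[0]
        assert row["mean"] == pytest.approx(65.0)
        assert row["sd"] == pytest.approx(7.0710678, abs=1e-4)


class TestAnovaBins:
    def test_f_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0, 900, 80)
        y = 60 + 5 * rng.standard_normal(80)
        res = anova_bins(records(d, y))
        df = records(d, y)
        df["_bin"] = pd.cut(df["distance_um"], bins=range(0, 1000, 100))
        groups = [g["depth_um"].to_numpy() for _, g in df.groupby("_bin", observed=True)]
        assert res.f == pytest.approx(brute_force_f(groups), abs=1e-8)

    def test_bonferroni_is_m_times_raw_capped(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(0, 900, 80)
        y = 60 + 5 * rng.standard_normal(80)
        res = anova_bins(records(d, y))
        m = len(res.pairwise)
        for _, row in res.pairwise.iterrows():
            if np.isfinite(row["p_raw"]):
                assert row["p_bonferroni"] == pytest.approx(
                    min(1.0, m * row["p_raw"]), abs=1e-12
                )

    def test_identical_bins_give_f_zero(self):
        d = [50.0, 60.0, 150.0, 160.0]
        y = [60.0, 60.0, 60.0, 60.0]
        res = anova_bins(records(d, y))
        assert res.degenerate
        assert res.f == 0.0

    def test_filtered_frame_with_noncontiguous_index(self):
        # bin assignment must align on the original index, not positions
        rng = np.random.default_rng(23)
        df = records(rng.uniform(0, 900, 60), 60 + 3 * rng.standard_normal(60))
        df["group"] = ["test", "control"] * 30
        sub = df[df["group"] == "control"]  # non-contiguous index
        res = anova_bins(sub)
        assert np.isfinite(res.f)

    def test_requires_two_populated_bins(self):
        with pytest.raises(ValueError):
            anova_bins(records([50.0, 60.0], [60.0, 61.0]))

    def test_detects_near_lumen_shift(self):
        # near-lumen bins shifted +10 um at sd 5: p < 0.05 in >= 95% of reps
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            d = rng.uniform(0, 900, 90)
            y = 60 + 5 * rng.standard_normal(90)
            y[d <= 200] += 10.0
            res = anova_bins(records(d, y))
            hits += res.p < 0.05
        assert hits / n_rep >= 0.95


class TestCompareNearLumen:
    def test_identical_samples_zero_difference(self):
        a = records([50, 100, 150, 180], [60, 62, 61, 63])
        res = compare_near_lumen(a, a)
        assert res.mean_difference == 0.0
        assert res.ci_lo <= 0.0 <= res.ci_hi

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(9)
        a = records(rng.uniform(0, 200, 20), 70 + 5 * rng.standard_normal(20))
        b = records(rng.uniform(0, 200, 10), 64 + 2 * rng.standard_normal(10), "control")
        res = compare_near_lumen(a, b)
        t, p = stats.ttest_ind(a["depth_um"], b["depth_um"], equal_var=False)
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_empty_control_rejected(self):
        a = records([50, 100], [60, 62])
        b = records([500.0, 600.0], [60.0, 61.0], "control")  # nothing <= 200
        with pytest.raises(ValueError):
            compare_near_lumen(a, b)


class TestFitLogTrend:
    def test_noiseless_exact_recovery_fixed_c(self):
        d = np.array([10.0, 50.0, 100.0, 300.0, 700.0])
        y = 90.0 - 4.5 * np.log(d + 1.0)
        fit = fit_log_trend(records(d, y))
        assert fit.a == pytest.approx(90.0, rel=1e-9)
        assert fit.b == pytest.approx(4.5, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_free_offset_recovery(self):
        d = np.array([10.0, 50.0, 100.0, 200.0, 300.0, 500.0, 700.0, 900.0])
        y = 100.0 - 6.0 * np.log(d + 40.0)
        fit = fit_log_trend(records(d, y), fit_c=True)
        assert fit.a == pytest.approx(100.0, rel=1e-3)
        assert fit.b == pytest.approx(6.0, rel=1e-3)
        assert fit.c == pytest.approx(40.0, rel=1e-2)

    def test_flat_data_gives_near_zero_slope(self):
        d = np.array([10.0, 100.0, 400.0, 900.0])
        fit = fit_log_trend(records(d, np.full(4, 60.0)))
        assert fit.b == pytest.approx(0.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_log_trend(records([10.0, 20.0], [60.0, 61.0]))

    def test_nonpositive_offset_rejected(self):
        with pytest.raises(ValueError):
            fit_log_trend(records([10.0, 20.0, 30.0], [60.0, 61.0, 62.0]), c=0.0)


class TestGeneratorTrends:
    def test_test_trend_above_control_within_900um(self):
        d = np.arange(10.0, 901.0, 10.0)
        test = generate_indentation("T05", "test", d)
        ctrl = generate_indentation("C12", "control", d)
        ft = fit_log_trend(test.assign(depth_um=test["depth_um"]))
        fc = fit_log_trend(ctrl.assign(depth_um=ctrl["depth_um"]))
        pred_t = ft.a - ft.b * np.log(d + ft.c)
        pred_c = fc.a - fc.b * np.log(d + fc.c)
        assert np.all(pred_t > pred_c)

    def test_binned_test_means_decrease_outward_in_expectation(self):
        rng = np.random.default_rng(6)
        frames = [
            generate_indentation("T05", "test", rng.uniform(0, 900, 200), seed=s)
            for s in range(10)
        ]
        out = bin_depths(pd.concat(frames, ignore_index=True))
        means = out["mean"].to_numpy()
        assert means[0] > means[-1]
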