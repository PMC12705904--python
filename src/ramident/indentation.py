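"""Reference-point indentation depth versus distance from the canal lumen.

Total indentation distance (the probe depth at the end of the cyclic
test, a microhardness surrogate) is summarized in 100-um distance bins,
compared across bins by one-way ANOVA with Bonferroni-adjusted pairwise
tests, compared between treated and control roots near the lumen with a
Welch two-sample test, and fitted with the logarithmic trend
``depth = a - b * ln(distance + c)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .gradient import DEFAULT_BIN_EDGES, assign_bins

NO_DATA = "No data"


def bin_depths(
    records: pd.DataFrame, edges=DEFAULT_BIN_EDGES
) -> pd.DataFrame:
    """Per-bin mean, sample SD and count of indentation depth.

    Bins are half-open (lo, hi] and labeled "Up to 100 um",
    "> 100-200 um", ...; empty bins are reported with the "No data"
    marker and NaN statistics.
    """
    df = records.copy()
    df["_bin"] = assign_bins(df["distance_um"], edges)
    rows = []
    for label, sub in df.groupby("_bin", observed=False):
        depths = sub["depth_um"].to_numpy(float)
        n = depths.size
        rows.append(
            {
                "bin": str(label),
                "mean": depths.mean() if n else np.nan,
                "sd": depths.std(ddof=1) if n > 1 else (0.0 if n == 1 else np.nan),
                "n": n,
                "note": "" if n else NO_DATA,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    pairwise: pd.DataFrame
    degenerate: bool = False


def anova_bins(records: pd.DataFrame, edges=DEFAULT_BIN_EDGES) -> AnovaResult:
    """One-way ANOVA of depth across distance bins.

    All pairwise bin comparisons (two-sample t) are Bonferroni-adjusted
    with the family equal to every pair of non-empty bins:
    p_adj = min(1, m * p_raw). Requires at least two bins with two or
    more records; zero within-bin variance everywhere is flagged as
    degenerate (F reported as 0).
    """
    df = records.copy()
    df["_bin"] = assign_bins(df["distance_um"], edges)
    groups = {
        str(label): sub["depth_um"].to_numpy(float)
        for label, sub in df.groupby("_bin", observed=True)
        if len(sub)
    }
    sizable = [g for g in groups.values() if g.size >= 2]
    if len(groups) < 2 or len(sizable) < 2:
        raise ValueError("need >= 2 non-empty bins with >= 2 records each")

    pooled_within = np.concatenate([g - g.mean() for g in groups.values()])
    degenerate = bool(np.allclose(pooled_within, 0.0))
    if degenerate:
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*groups.values())

    pairs = list(combinations(sorted(groups), 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        ga, gb = groups[a], groups[b]
        if ga.size < 2 and gb.size < 2:
            t_val, p_raw = np.nan, np.nan
        else:
            t_val, p_raw = stats.ttest_ind(ga, gb, equal_var=True)
        rows.append(
            {
                "bin_a": a,
                "bin_b": b,
                "mean_diff": ga.mean() - gb.mean(),
                "t": t_val,
                "p_raw": p_raw,
                "p_bonferroni": min(1.0, m * p_raw) if np.isfinite(p_raw) else np.nan,
            }
        )
    return AnovaResult(float(f_stat), float(p_val), pd.DataFrame(rows), degenerate)


@dataclass(frozen=True)
class NearLumenComparison:
    mean_difference: float  # test minus control, um
    ci_lo: float
    ci_hi: float
    t: float
    p: float
    n_test: int
    n_control: int


def compare_near_lumen(
    test_records: pd.DataFrame,
    control_records: pd.DataFrame,
    cutoff_um: float = 200.0,
) -> NearLumenComparison:
    """Welch two-sample comparison of depths within ``cutoff_um`` of the
    lumen between the treated and control groups."""
    a = test_records.loc[
        test_records["distance_um"] <= cutoff_um, "depth_um"
    ].to_numpy(float)
    b = control_records.loc[
        control_records["distance_um"] <= cutoff_um, "depth_um"
    ].to_numpy(float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 depths per group within the cutoff")
    t_val, p_val = stats.ttest_ind(a, b, equal_var=False)
    diff = a.mean() - b.mean()
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    se = np.sqrt(va + vb)
    if se > 0:
        df_w = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        half = stats.t.ppf(0.975, df_w) * se
    else:
        half = 0.0
    return NearLumenComparison(
        float(diff), float(diff - half), float(diff + half),
        float(t_val), float(p_val), a.size, b.size,
    )


@dataclass(frozen=True)
class LogTrendFit:
    a: float
    b: float
    c: float
    r2: float


def fit_log_trend(
    records: pd.DataFrame, c: float = 1.0, fit_c: bool = False
) -> LogTrendFit:
    """Least-squares fit of depth = a - b*ln(distance + c).

    With ``c`` fixed (default 1 um, so distance 0 is admissible) the
    model is linear in ln(distance + c) and solved in closed form;
    ``fit_c=True`` frees the offset via nonlinear least squares.
    """
    d = records["distance_um"].to_numpy(float)
    y = records["depth_um"].to_numpy(float)
    if d.size < 3:
        raise ValueError("need at least 3 records for the logarithmic fit")
    if fit_c:
        from scipy.optimize import curve_fit

        def model(x, a, b, cc):
            return a - b * np.log(x + cc)

        (a, b, c), _ = curve_fit(
            model, d, y, p0=(y.max(), 1.0, max(c, 1e-3)),
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        pred = model(d, a, b, c)
    else:
        if c <= 0:
            raise ValueError("offset c must be > 0")
        X = np.column_stack([np.ones_like(d), -np.log(d + c)])
        (a, b), *_ = np.linalg.lstsq(X, y, rcond=None)
        pred = X @ np.array([a, b])
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float(((y - pred) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return LogTrendFit(float(a), float(b), float(c), r2)
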