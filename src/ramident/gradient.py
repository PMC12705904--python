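"""Spatial gradient of collagen band features along root transects.

Three complementary views of the degradation gradient:

* distance-binned ordinary least squares of band area on distance (per
  100 um), stratified by root maturity, with the extent of canal
  instrumentation as a covariate;
* a saturating-exponential fit of Amide I peak height versus distance,
  y(d) = y_inf - (y_inf - y0) * exp(-d / lambda), whose 95%-recovery
  point d = lambda * ln(20) estimates the boundary of the NaOCl effect;
* a decay-form trend of the spectral quality index versus distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import least_squares

#: Default 100-um distance bin edges out to 900 um from the canal lumen.
DEFAULT_BIN_EDGES = tuple(float(x) for x in range(0, 1000, 100))

ENTIRE_LABEL = "Entire thickness"


def bin_label(lo: float, hi: float) -> str:
    if lo == 0:
        return f"Up to {hi:.0f} um"
    return f"> {lo:.0f}-{hi:.0f} um"


def assign_bins(distance_um, edges=DEFAULT_BIN_EDGES) -> pd.Series:
    """Assign distances to half-open bins (lo, hi]; NaN outside range.

    The result is aligned to the input's index when a Series is given.
    """
    labels = [bin_label(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]
    cats = pd.cut(np.asarray(distance_um, float), bins=list(edges),
                  labels=labels, right=True)
    index = distance_um.index if isinstance(distance_um, pd.Series) else None
    return pd.Series(cats, index=index)


@dataclass(frozen=True)
class GradientFit:
    """One per-(stratum, bin, band) linear-model result.

    ``coefficient`` is the change in band area per 100 um of distance
    from the canal lumen; bins with fewer than 3 accepted sites carry
    ``insufficient_data=True`` and NaN estimates.
    """

    stratum: str
    bin: str
    band: str
    coefficient: float
    ci_lo: float
    ci_hi: float
    p_value: float
    n_sites: int
    insufficient_data: bool = False


def _fit_ols(sub: pd.DataFrame, band: str, covariate: str | None) -> tuple:
    y = sub[band].to_numpy(float)
    x = sub["distance_um"].to_numpy(float) / 100.0
    cols = {"dist100": x}
    if covariate and covariate in sub.columns:
        c = sub[covariate].to_numpy(float)
        if np.ptp(c) > 0:  # per-tooth constants are collinear with the intercept
            cols[covariate] = c
    X = sm.add_constant(pd.DataFrame(cols), has_constant="add")
    model = sm.OLS(y, X).fit()
    ci = model.conf_int(alpha=0.05)
    return (
        float(model.params["dist100"]),
        float(ci.loc["dist100", 0]),
        float(ci.loc["dist100", 1]),
        float(model.pvalues["dist100"]),
    )


def binned_linear_models(
    features: pd.DataFrame,
    bands: tuple[str, ...] = ("area_amide1", "area_amide3"),
    strata: str | None = "maturity_group",
    covariate: str | None = "ei_mean_mm",
    edges=DEFAULT_BIN_EDGES,
    require_accepted: bool = True,
) -> list[GradientFit]:
    """Per-(stratum, distance-bin, band) OLS of band area on distance.

    Only quality-accepted spectra (QI <= 6) enter when an ``accepted``
    column is present. Each stratum additionally receives an
    "Entire thickness" pseudo-bin over all distances. Bins with fewer
    than 3 sites, or without distance variation, are flagged as having
    insufficient data.
    """
    if features.empty:
        raise ValueError("empty feature table")
    df = features
    if require_accepted and "accepted" in df.columns:
        df = df[df["accepted"].astype(bool)]
    if df.empty:
        raise ValueError("no accepted spectra in the feature table")
    df = df.copy()
    df["_bin"] = assign_bins(df["distance_um"], edges)

    if strata and strata in df.columns:
        groups = [(str(v), sub) for v, sub in df.groupby(strata, observed=True)]
    else:
        groups = [("all", df)]

    fits: list[GradientFit] = []
    for stratum, sub in groups:
        bin_iter = [(ENTIRE_LABEL, sub)] + [
            (str(lbl), b) for lbl, b in sub.groupby("_bin", observed=False)
        ]
        for label, binned in bin_iter:
            for band in bands:
                n = len(binned)
                degenerate = n >= 1 and np.ptp(binned["distance_um"].to_numpy(float)) == 0
                if n < 3 or degenerate:
                    fits.append(
                        GradientFit(stratum, label, band, np.nan, np.nan, np.nan,
                                    np.nan, n, insufficient_data=True)
                    )
                    continue
                coef, lo, hi, p = _fit_ols(binned, band, covariate)
                fits.append(GradientFit(stratum, label, band, coef, lo, hi, p, n))
    return fits


def gradient_table(fits: list[GradientFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stratum": f.stratum,
                "bin": f.bin,
                "band": f.band,
                "coefficient": f.coefficient,
                "ci_lo": f.ci_lo,
                "ci_hi": f.ci_hi,
                "p_value": f.p_value,
                "n_sites": f.n_sites,
                "insufficient_data": f.insufficient_data,
            }
            for f in fits
        ]
    )


# ---------------------------------------------------------------------------
# Saturating-exponential decay fit and boundary estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecayFit:
    """Parameters of y(d) = y_inf - (y_inf - y0) * exp(-d / lambda).

    ``boundary_um = lambda * ln(20)`` is the distance at which the fitted
    amplitude recovers 95% of the lumen-to-asymptote deficit. For flat
    data the decay length is unidentifiable and reported as NaN with the
    ``unidentifiable`` flag set.
    """

    y0: float
    y_inf: float
    lam: float
    boundary_um: float
    rss: float
    r2: float
    unidentifiable: bool = False


def _decay(params, d):
    y0, y_inf, lam = params
    return y_inf - (y_inf - y0) * np.exp(-d / lam)


def fit_decay(
    distance_um,
    y,
    lambda_starts: tuple[float, ...] = (50.0, 100.0, 250.0, 500.0, 1000.0),
    flat_alpha: float = 0.05,
) -> DecayFit:
    """Fit the saturating-exponential amplitude-versus-distance model.

    Multi-start nonlinear least squares over a grid of initial decay
    lengths; the best (lowest-RSS) solution is kept. The decay length is
    reported as unidentifiable (NaN, flag set) when an F-test cannot
    reject the constant-mean model at level ``flat_alpha`` -- the flat
    (control) regime, where lambda carries no information.
    """
    d = np.asarray(distance_um, float)
    yv = np.asarray(y, float)
    if d.size < 5:
        raise ValueError("need at least 5 points for the decay fit")
    if np.unique(d).size < 2:
        raise ValueError("need at least 2 distinct distances")

    y_inf0 = float(yv[np.argsort(d)[-max(3, d.size // 4):]].mean())
    y00 = float(yv[np.argsort(d)[: max(2, d.size // 6)]].mean())
    best = None
    for lam0 in lambda_starts:
        try:
            res = least_squares(
                lambda p: _decay(p, d) - yv,
                x0=[y00, y_inf0, lam0],
                bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, 1e7]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("decay fit failed to converge from all starts")

    y0, y_inf, lam = (float(v) for v in best.x)
    resid = _decay(best.x, d) - yv
    rss = float(resid @ resid)
    tss = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0

    # F-test of the 3-parameter decay against the 1-parameter constant
    scale = max(1.0, abs(float(yv.mean())))
    flat = tss <= d.size * (1e-12 * scale) ** 2 or abs(y_inf - y0) <= 1e-9 * scale
    dof = d.size - 3
    if not flat and dof >= 1 and rss > 0:
        f_stat = ((tss - rss) / 2.0) / (rss / dof)
        flat = bool(stats.f.sf(f_stat, 2, dof) > flat_alpha)
    if flat:
        return DecayFit(y0, y_inf, np.nan, np.nan, rss, r2, unidentifiable=True)
    boundary = lam * np.log(20.0) if y0 < y_inf else np.nan
    return DecayFit(y0, y_inf, lam, boundary, rss, r2)


def quality_trend(
    quality: pd.DataFrame, r2_caution: float = 0.2
) -> dict:
    """Decay-form trend of the quality index versus distance.

    Returns the fitted :class:`DecayFit` together with a caution flag set
    when r^2 falls below ``r2_caution`` (a weak, unreliable trend).
    """
    if quality.empty:
        raise ValueError("empty quality table")
    fit = fit_decay(quality["distance_um"], quality["qi"])
    return {"fit": fit, "r2": fit.r2, "caution": bool(fit.r2 < r2_caution)}
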