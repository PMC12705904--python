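"""Spectral preprocessing: baseline correction, smoothing, normalization.

The fixed pipeline order applied before any spectral comparison is
baseline -> smooth -> carbonate normalization -> zero offset. Stages mark
their output via ``meta`` flags; re-running the pipeline on already
processed data is a no-op for the irreversible stages (baseline, smooth),
which makes the full pipeline idempotent.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .io import Spectrum

logger = logging.getLogger(__name__)

#: Band-free region used to estimate the noise level of a spectrum.
QUIET_WINDOW = (1500.0, 1580.0)

CARBONATE_CENTER = 1072.0
CARBONATE_HALFWIDTH = 15.0


class NormalizationError(ValueError):
    """Carbonate reference peak not distinguishable from the noise floor.

    Signals a fluorescence-masked spectrum; callers should route such
    spectra to quality scoring as unacceptable rather than normalize them.
    """


# ---------------------------------------------------------------------------
# Baseline correction
# ---------------------------------------------------------------------------

def _als_baseline(
    y: np.ndarray, lam: float = 1e7, p: float = 0.01, niter: int = 20
) -> np.ndarray:
    """Asymmetric least squares (Whittaker) baseline.

    Minimizes sum(w_i (y_i - z_i)^2) + lam * sum((Delta^2 z)^2) with
    asymmetric weights w_i = p above the baseline and 1 - p below it.
    Solved with a banded Cholesky factorization (pentadiagonal system).
    """
    n = y.size
    # Diagonals of D2.T @ D2 (interior stencil [1 -4 6 -4 1])
    main = np.full(n, 6.0)
    main[[0, -1]] = 1.0
    main[[1, -2]] = 5.0
    off1 = np.full(n - 1, -4.0)
    off1[[0, -1]] = -2.0
    off2 = np.full(n - 2, 1.0)
    w = np.ones(n)
    z = y.copy()
    for _ in range(niter):
        ab = np.zeros((3, n))
        ab[0, 2:] = lam * off2
        ab[1, 1:] = lam * off1
        ab[2, :] = lam * main + w
        z_new = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z_new, p, 1.0 - p)
        converged = np.array_equal(w_new, w)
        z = z_new
        w = w_new
        if converged:
            break
    return z


def _poly_baseline(
    y: np.ndarray, x: np.ndarray, degree: int = 5, tol: float = 1e-8, max_iter: int = 100
) -> np.ndarray:
    """Iterative polynomial (ModPoly-style) baseline.

    Repeatedly fits a polynomial and clips the working curve to the fit,
    so peaks are progressively excluded. On a pure polynomial input of
    degree <= ``degree`` the first fit is exact.
    """
    xs = (x - x.mean()) / (x.max() - x.min())
    work = y.copy()
    prev = None
    for _ in range(max_iter):
        coef = np.polynomial.polynomial.polyfit(xs, work, degree)
        fit = np.polynomial.polynomial.polyval(xs, coef)
        work = np.minimum(work, fit)
        if prev is not None:
            scale = max(np.abs(fit).max(), 1.0)
            if np.abs(fit - prev).max() <= tol * scale:
                break
        prev = fit
    return fit


def baseline_correct(
    spectrum: Spectrum, method: str = "als", **params
) -> Spectrum:
    """Remove the slowly varying fluorescence background.

    ``method`` is ``'als'`` (asymmetric least squares, the default for
    Raman fluorescence backgrounds) or ``'poly'`` (iterative polynomial,
    a simple reproducibility fallback). The input spectrum is not
    modified.
    """
    y = spectrum.intensity
    if np.ptp(y) == 0:
        warnings.warn("degenerate constant spectrum; baseline set to the constant")
        return spectrum.replace(np.zeros_like(y), baseline_corrected=True)
    if spectrum.meta.get("baseline_corrected"):
        return spectrum.replace(y.copy())
    if method == "als":
        z = _als_baseline(y, **params)
    elif method == "poly":
        z = _poly_baseline(y, spectrum.wavenumber, **params)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return spectrum.replace(y - z, baseline_corrected=True)


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def smooth(spectrum: Spectrum, window: int = 8, method: str = "moving_average") -> Spectrum:
    """Smooth a spectrum.

    The default is an 8-point moving average; for the even window the
    average runs over samples k-4 ... k+3, and edge samples use the
    shrunken window that fits inside the grid. ``method='savgol'`` applies
    a Savitzky-Golay filter (odd window, polynomial order 2) instead.
    """
    y = spectrum.intensity
    n = y.size
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds spectrum length {n}")
    if spectrum.meta.get("smoothed"):
        return spectrum.replace(y.copy())
    if window == 1:
        return spectrum.replace(y.copy(), smoothed=True)
    if method == "savgol":
        wl = window if window % 2 == 1 else window + 1
        return spectrum.replace(savgol_filter(y, wl, 2), smoothed=True)
    if method != "moving_average":
        raise ValueError(f"unknown smoothing method {method!r}")
    half_lo = window // 2
    half_hi = window - half_lo - 1  # k-4 ... k+3 for window 8
    cs = np.concatenate([[0.0], np.cumsum(y)])
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    out = (cs[hi] - cs[lo]) / (hi - lo)
    return spectrum.replace(out, smoothed=True)


# ---------------------------------------------------------------------------
# Normalization and offset
# ---------------------------------------------------------------------------

def estimate_noise_sd(spectrum: Spectrum, quiet_window=QUIET_WINDOW) -> float:
    """Standard deviation of the linearly detrended quiet-window residual."""
    wn, y = spectrum.window(*quiet_window)
    coef = np.polyfit(wn, y, 1)
    resid = y - np.polyval(coef, wn)
    return float(resid.std(ddof=1))


def carbonate_peak_height(
    spectrum: Spectrum,
    ref_center: float = CARBONATE_CENTER,
    ref_halfwidth: float = CARBONATE_HALFWIDTH,
) -> float:
    """Maximum intensity within ref_center +/- ref_halfwidth."""
    _, y = spectrum.window(ref_center - ref_halfwidth, ref_center + ref_halfwidth)
    return float(y.max())


def normalize_carbonate(
    spectrum: Spectrum,
    ref_center: float = CARBONATE_CENTER,
    ref_halfwidth: float = CARBONATE_HALFWIDTH,
    noise_k: float = 3.0,
    mode: str = "height",
) -> Spectrum:
    """Normalize to the carbonate (CO3^2-) reference band at 1072 cm^-1.

    Intensities are divided by the carbonate peak height so the peak
    equals exactly 1 (``mode='area'`` divides by the band area instead).
    Raises :class:`NormalizationError` when the peak does not rise at
    least ``noise_k`` noise standard deviations above the local window
    median -- the signature of a fluorescence-masked spectrum.
    """
    wn, y = spectrum.window(ref_center - ref_halfwidth, ref_center + ref_halfwidth)
    height = float(y.max())
    prominence = height - float(np.median(y))
    noise = estimate_noise_sd(spectrum)
    if height <= 0 or prominence <= noise_k * noise:
        raise NormalizationError(
            f"carbonate peak (prominence {prominence:.3g}) not above the noise "
            f"floor ({noise_k:.3g} x {noise:.3g}); spectrum is fluorescence-masked"
        )
    if mode == "height":
        divisor = height
    elif mode == "area":
        divisor = float(np.trapezoid(y, wn))
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return spectrum.replace(spectrum.intensity / divisor, normalized=True)


def offset_zero(spectrum: Spectrum) -> Spectrum:
    """Shift intensities so the minimum over the analysis range is 0."""
    return spectrum.replace(spectrum.intensity - spectrum.intensity.min())


def preprocess(
    spectrum: Spectrum,
    baseline_method: str = "als",
    baseline_params: dict | None = None,
    window: int = 8,
    smooth_method: str = "moving_average",
    normalize_mode: str = "height",
    noise_k: float = 3.0,
) -> Spectrum:
    """Full pipeline: baseline -> smooth -> normalize -> offset.

    Idempotent: pipeline output carries a ``preprocessed`` meta flag and
    is returned unchanged (as a copy) if run through the pipeline again;
    the individual baseline and smoothing stages are likewise skipped on
    spectra already carrying their stage flags.

    Raises :class:`NormalizationError` for fluorescence-masked spectra.
    """
    if spectrum.meta.get("preprocessed"):
        return spectrum.replace(spectrum.intensity.copy())
    s = baseline_correct(spectrum, method=baseline_method, **(baseline_params or {}))
    s = smooth(s, window=window, method=smooth_method)
    s = normalize_carbonate(s, noise_k=noise_k, mode=normalize_mode)
    out = offset_zero(s)
    out.meta["preprocessed"] = True
    return out
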