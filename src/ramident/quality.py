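"""Spectral quality rating and the QI <= 6 inclusion filter.

Each normalized spectrum is divided into three regions (Amide III, Amide
I, and the 1450 cm^-1 band), each rated 1 (optimal) to 3 (unacceptable)
against the carbonate reference height, then an overall general quality
score is assigned and the quality index computed as

    QI = (r_amide3 + r_amide1 + r_1450) * general

Only spectra with QI <= 6 enter the integrated band-area analysis. The
worked examples fixing the operator precedence are ([3+1+1] x 2 = 10,
rejected) and ([2+2+2] x 1 = 6, accepted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .features import DEFAULT_WINDOWS, BandWindow
from .io import Spectrum
from .preprocess import NormalizationError, preprocess

QI_THRESHOLD = 6

#: Amide band heights must fall between 25% and 75% of the carbonate
#: reference height; both bounds are closed (0.25 and 0.75 acceptable).
RATING_LO = 0.25
RATING_HI = 0.75

#: Minimum prominence (in carbonate-normalized units) for a local maximum
#: to count as a peak when rating a region; suppresses noise ripples.
PEAK_PROMINENCE = 0.02


@dataclass(frozen=True)
class QualityScore:
    """Region ratings, general quality, QI and the acceptance flag."""

    r_amide3: int
    r_amide1: int
    r_1450: int
    general: int
    qi: int
    accepted: bool


def rate_region(
    spectrum: Spectrum, window: BandWindow, carbonate_height: float = 1.0
) -> int:
    """Rate one spectral region 1-3 against the carbonate reference.

    H is the main peak height (local maximum nearest the nominal center)
    and A the tallest accessory peak (any other local maximum in the
    window; 0 if none), both relative to the carbonate height. Rating 3
    applies when A > H or H is outside [0.25, 0.75]; rating 2 when the
    accessory peak itself lies in [0.25, 0.75]; rating 1 otherwise.
    A flat window (no local maximum) rates 3 because H < 0.25.
    """
    wn, y = spectrum.window(window.lo, window.hi)
    rel = y / carbonate_height
    peaks, _ = find_peaks(rel, prominence=PEAK_PROMINENCE)
    if peaks.size == 0:
        main_h, acc_h = 0.0, 0.0
    else:
        main_idx = peaks[np.argmin(np.abs(wn[peaks] - window.center))]
        main_h = float(rel[main_idx])
        others = peaks[peaks != main_idx]
        acc_h = float(rel[others].max()) if others.size else 0.0
    if acc_h > main_h or main_h < RATING_LO or main_h > RATING_HI:
        return 3
    if RATING_LO <= acc_h <= RATING_HI:
        return 2
    return 1


def general_quality(ratings) -> int:
    """Overall general quality from the three region ratings.

    1 when no region is unacceptable, 3 when all three are (a spectrum
    not resembling collagen in any part), 2 otherwise.
    """
    ratings = list(ratings)
    if len(ratings) != 3 or any(r not in (1, 2, 3) for r in ratings):
        raise ValueError("expected three ratings in {1, 2, 3}")
    n_bad = sum(r == 3 for r in ratings)
    if n_bad == 0:
        return 1
    if n_bad == 3:
        return 3
    return 2


def compute_qi(
    r_amide3: int, r_amide1: int, r_1450: int, general: int
) -> tuple[int, bool]:
    """QI = (sum of region ratings) x general; accepted iff QI <= 6."""
    for r in (r_amide3, r_amide1, r_1450, general):
        if r not in (1, 2, 3):
            raise ValueError("ratings and general quality must be in {1, 2, 3}")
    qi = (r_amide3 + r_amide1 + r_1450) * general
    return qi, qi <= QI_THRESHOLD


def score_spectrum(
    spectrum: Spectrum,
    windows: dict[str, BandWindow] | None = None,
    preprocessed: bool = False,
    **preprocess_kwargs,
) -> QualityScore:
    """Score a spectrum end to end.

    Raw spectra are run through the preprocessing pipeline first; spectra
    whose carbonate normalization fails (fluorescence-masked) receive the
    worst possible score (ratings 3,3,3; general 3; QI 27).
    """
    windows = windows or DEFAULT_WINDOWS
    if not preprocessed:
        try:
            spectrum = preprocess(spectrum, **preprocess_kwargs)
        except NormalizationError:
            return QualityScore(3, 3, 3, 3, 27, False)
    r3 = rate_region(spectrum, windows["amide3"])
    r1 = rate_region(spectrum, windows["amide1"])
    r1450 = rate_region(spectrum, windows["ch_1450"])
    general = general_quality((r3, r1, r1450))
    qi, accepted = compute_qi(r3, r1, r1450, general)
    return QualityScore(r3, r1, r1450, general, qi, accepted)


def quality_table(scores: list[QualityScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "r_amide3": [s.r_amide3 for s in scores],
            "r_amide1": [s.r_amide1 for s in scores],
            "r_1450": [s.r_1450 for s in scores],
            "general": [s.general for s in scores],
            "qi": [s.qi for s in scores],
            "accepted": [s.accepted for s in scores],
        }
    )
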