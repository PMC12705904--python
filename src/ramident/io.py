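"""Reading and writing of point Raman spectra, manifests, and tabular outputs.

Spectra are stored one per file as two-column delimited text
(``wavenumber_cm1,intensity``); a manifest CSV carries the per-spectrum
acquisition metadata (tooth, quadrant, distance from the canal lumen,
acquisition time, tubule locus, treatment group).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Every analysis window (carbonate 1072, Amide III 1215-1302, CH 1450,
#: Amide I 1615-1719 cm-1) must lie inside the wavenumber grid.
REQUIRED_RANGE = (1072.0 - 20.0, 1719.0 + 10.0)

VALID_QUADRANTS = ("A", "B", "C", "D")  # buccal, mesial, lingual/palatal, distal
VALID_LOCI = ("intra_tubular", "inter_tubular")
VALID_TREATMENTS = ("naocl", "control")

MANIFEST_COLUMNS = [
    "file",
    "tooth_id",
    "quadrant",
    "distance_um",
    "acq_min",
    "locus",
    "treatment",
]


class SpectrumValidationError(ValueError):
    """Raised when a spectrum fails structural validation."""


@dataclass
class Spectrum:
    """A single point Raman spectrum.

    Parameters
    ----------
    wavenumber : ndarray
        Strictly ascending Raman shifts in cm^-1. Must cover at least
        [1052, 1729] cm^-1 so that all band windows fit inside the grid.
    intensity : ndarray
        Detector counts (arbitrary units), same length as ``wavenumber``.
    meta : dict
        Acquisition metadata (tooth_id, quadrant, distance_um, acq_min,
        locus, treatment, ...), plus processing flags added downstream.
    """

    wavenumber: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.wavenumber.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumValidationError("wavenumber and intensity must be 1-D")
        if self.wavenumber.size != self.intensity.size:
            raise SpectrumValidationError(
                f"length mismatch: {self.wavenumber.size} wavenumbers vs "
                f"{self.intensity.size} intensities"
            )
        if self.wavenumber.size < 2:
            raise SpectrumValidationError("spectrum needs at least 2 samples")
        dw = np.diff(self.wavenumber)
        if np.any(dw == 0):
            raise SpectrumValidationError("duplicate wavenumbers")
        if np.any(dw < 0):
            raise SpectrumValidationError("wavenumbers must be strictly ascending")
        lo, hi = REQUIRED_RANGE
        if self.wavenumber[0] > lo or self.wavenumber[-1] < hi:
            raise SpectrumValidationError(
                f"grid [{self.wavenumber[0]:g}, {self.wavenumber[-1]:g}] cm^-1 "
                f"does not cover the required range [{lo:g}, {hi:g}] cm^-1"
            )

    def replace(self, intensity: np.ndarray, **meta_updates) -> "Spectrum":
        """Return a copy with new intensities (the grid is shared)."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(self.wavenumber.copy(), np.asarray(intensity, float), meta)

    def window(self, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
        """Return (wavenumber, intensity) restricted to the closed [lo, hi]."""
        m = (self.wavenumber >= lo) & (self.wavenumber <= hi)
        if not m.any():
            raise SpectrumValidationError(f"window [{lo}, {hi}] outside grid")
        return self.wavenumber[m], self.intensity[m]

    def __len__(self) -> int:
        return int(self.wavenumber.size)


def _sniff_delimiter(line: str) -> str:
    # instrument exports use comma or tab; fall back to whitespace
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return " "


def read_spectrum(path: str | Path, meta: dict | None = None) -> Spectrum:
    """Read a two-column delimited text spectrum.

    Descending wavenumber order is reversed with a logged notice.
    Non-numeric rows raise a parse error naming the offending line.
    """
    path = Path(path)
    wn: list[float] = []
    inten: list[float] = []
    with open(path) as fh:
        first = fh.readline()
        delim = _sniff_delimiter(first)
        lines = [first] + fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in line.replace(delim, " ").split() if p]
        if len(parts) < 2:
            raise SpectrumValidationError(f"{path}:{lineno}: fewer than 2 columns")
        try:
            w, y = float(parts[0]), float(parts[1])
        except ValueError:
            if lineno == 1:  # header line
                continue
            raise SpectrumValidationError(
                f"{path}:{lineno}: non-numeric row {line!r}"
            ) from None
        wn.append(w)
        inten.append(y)
    if not wn:
        raise SpectrumValidationError(f"{path}: no numeric data rows")
    wn_arr = np.asarray(wn)
    int_arr = np.asarray(inten)
    if wn_arr.size >= 2 and np.all(np.diff(wn_arr) < 0):
        logger.info("%s: descending wavenumber order; reversing", path)
        wn_arr = wn_arr[::-1]
        int_arr = int_arr[::-1]
    return Spectrum(wn_arr, int_arr, dict(meta or {}))


def write_spectrum(spectrum: Spectrum, path: str | Path, delimiter: str = ",") -> None:
    """Write a spectrum as two-column text with a header line."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["wavenumber_cm1", "intensity"])
        for w, y in zip(spectrum.wavenumber, spectrum.intensity):
            writer.writerow([f"{w:.6g}", f"{y:.8g}"])


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest CSV and validate its schema.

    Required columns are those written by the synthetic generator; unknown
    columns are preserved. An empty manifest (header only) is valid.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SpectrumValidationError(f"manifest missing column(s): {missing}")
    if len(df):
        bad_q = set(df["quadrant"].astype(str)) - set(VALID_QUADRANTS)
        if bad_q:
            raise SpectrumValidationError(f"invalid quadrant label(s): {sorted(bad_q)}")
        bad_l = set(df["locus"].astype(str)) - set(VALID_LOCI)
        if bad_l:
            raise SpectrumValidationError(f"invalid locus value(s): {sorted(bad_l)}")
        bad_t = set(df["treatment"].astype(str)) - set(VALID_TREATMENTS)
        if bad_t:
            raise SpectrumValidationError(f"invalid treatment value(s): {sorted(bad_t)}")
        if (df["distance_um"] < 0).any():
            raise SpectrumValidationError("negative distance_um in manifest")
        if (df["acq_min"] <= 0).any():
            raise SpectrumValidationError("non-positive acq_min in manifest")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    cols = MANIFEST_COLUMNS + [c for c in df.columns if c not in MANIFEST_COLUMNS]
    df.loc[:, cols].to_csv(path, index=False)


def load_spectra(manifest: pd.DataFrame, base_dir: str | Path) -> list[Spectrum]:
    """Load every spectrum listed in a manifest, attaching its metadata."""
    base = Path(base_dir)
    out = []
    for _, row in manifest.iterrows():
        meta = {k: row[k] for k in manifest.columns if k != "file"}
        out.append(read_spectrum(base / row["file"], meta=meta))
    return out
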