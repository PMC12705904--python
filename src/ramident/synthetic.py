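"""Synthetic dentine Raman spectra and micro-indentation records.

The generator emulates the statistical structure of point spectra taken
along transects from the root-canal lumen towards the cemento-dentinal
junction (CDJ) after NaOCl irrigation:

* four collagen/mineral bands (carbonate 1072, Amide III 1243, CH 1450,
  Amide I 1667 cm^-1) on a fluorescence background;
* an Amide III doublet (sub-bands at 1243 and 1270 cm^-1) whose contrast
  flattens towards the lumen;
* Amide amplitude attenuation confined within a few hundred micrometres
  of the lumen, controlled by a saturating-exponential degradation profile
  ``f(d) = floor + (1 - floor) * (1 - exp(-d / lambda))``;
* fluorescence-dominated (masked) spectra at inter-tubular loci;
* detector noise whose standard deviation scales as 1/sqrt(acquisition
  time);
* indentation depths following a logarithmic trend
  ``depth = a - b*ln(distance + c)``, deeper near the lumen for
  NaOCl-treated roots than for controls.

All outputs are deterministic functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Spectrum, VALID_QUADRANTS

# -- wavenumber grid: 1050-1750 cm^-1 at 1 cm^-1 spacing, endpoints included
GRID_LO = 1050.0
GRID_HI = 1750.0
GRID_STEP = 1.0

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class DegradationModel:
    """Spatial profile of NaOCl-induced collagen degradation.

    ``d_scale`` is the decay length lambda in micrometres; the ``*_floor``
    parameters are the fraction of the intact feature retained at the
    lumen (d = 0); ``broaden_max`` is the maximal fractional band-width
    increase at the lumen. The degradation factor
    ``f(d) = floor + (1 - floor)*(1 - exp(-d/lambda))`` rises monotonically
    from ``floor`` at the lumen to 1 far from it.
    """

    d_scale: float = 250.0
    amide1_floor: float = 0.35
    amide3_floor: float = 0.35
    doublet_floor: float = 0.35
    broaden_max: float = 0.30

    def __post_init__(self) -> None:
        if self.d_scale <= 0:
            raise ValueError("d_scale must be > 0")
        for name in ("amide1_floor", "amide3_floor", "doublet_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.broaden_max < 0:
            raise ValueError("broaden_max must be >= 0")

    def factor(self, distance_um: float, floor: float) -> float:
        """Degradation factor f(d) for a given floor."""
        return floor + (1.0 - floor) * (1.0 - np.exp(-distance_um / self.d_scale))


@dataclass(frozen=True)
class BandModel:
    """One spectral band: center and FWHM in cm^-1, amplitude in counts."""

    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, wavenumber: np.ndarray) -> np.ndarray:
        if self.shape == "gaussian":
            sigma = self.width / _FWHM_TO_SIGMA
            return self.amplitude * np.exp(-0.5 * ((wavenumber - self.center) / sigma) ** 2)
        gamma = self.width / 2.0  # Lorentzian half-width at half-maximum
        return self.amplitude * gamma**2 / ((wavenumber - self.center) ** 2 + gamma**2)


@dataclass(frozen=True)
class SpectrumSpec:
    """Metadata identifying one acquired spectrum."""

    tooth_id: str
    quadrant: str
    distance_um: float
    acq_min: float = 24.0
    locus: str = "intra_tubular"
    treatment: str = "naocl"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.quadrant not in VALID_QUADRANTS:
            raise ValueError(f"quadrant must be one of {VALID_QUADRANTS}")
        if self.distance_um < 0:
            raise ValueError("distance_um must be >= 0")
        if self.acq_min <= 0:
            raise ValueError("acq_min must be > 0")
        if self.locus not in ("intra_tubular", "inter_tubular"):
            raise ValueError("locus must be intra_tubular or inter_tubular")
        if self.treatment not in ("naocl", "control"):
            raise ValueError("treatment must be naocl or control")


# Default band set (amplitudes relative to carbonate = 100 counts). Equal
# default widths keep normalized band-height ratios unbiased through the
# fixed-width smoothing step. The CH 1450 cm^-1 band receives contributions
# from both organic phases and is left unmodulated by degradation.
DEFAULT_BANDS: dict[str, BandModel] = {
    "carbonate": BandModel(1072.0, 18.0, 100.0),
    "amide3": BandModel(1243.0, 18.0, 60.0),
    "amide3_secondary": BandModel(1270.0, 18.0, 40.0),
    "ch_1450": BandModel(1450.0, 18.0, 50.0),
    "amide1": BandModel(1667.0, 18.0, 70.0),
}

#: Quadratic fluorescence background coefficients in u = (wn - 1050)/700.
BACKGROUND_AMPLITUDE = 250.0
BACKGROUND_COEFFS = (1.0, -0.55, 0.12)
#: Inter-tubular loci: fluorescence dominates and the Raman bands are
#: largely absent, so the background is scaled up and bands suppressed.
INTER_TUBULAR_BG_SCALE = 20.0
INTER_TUBULAR_BAND_SCALE = 0.15
#: Base noise sd in counts at 1 min acquisition; noise scales with the
#: background scale (fluorescence-dominated spectra are noisier) and
#: decreases as 1/sqrt(acquisition minutes).
NOISE_SIGMA0 = 12.0


def wavenumber_grid() -> np.ndarray:
    return np.arange(GRID_LO, GRID_HI + 0.5 * GRID_STEP, GRID_STEP)


def fluorescence_background(wavenumber: np.ndarray, scale: float = 1.0) -> np.ndarray:
    u = (wavenumber - GRID_LO) / (GRID_HI - GRID_LO)
    c0, c1, c2 = BACKGROUND_COEFFS
    return scale * BACKGROUND_AMPLITUDE * (c0 + c1 * u + c2 * u**2)


def _degraded_bands(
    bands: dict[str, BandModel], spec: SpectrumSpec, model: DegradationModel
) -> dict[str, BandModel]:
    if spec.treatment != "naocl":
        return dict(bands)
    d = spec.distance_um
    f1 = model.factor(d, model.amide1_floor)
    f3 = model.factor(d, model.amide3_floor)
    fc = model.factor(d, model.doublet_floor)
    widen = 1.0 + model.broaden_max * np.exp(-d / model.d_scale)
    out = dict(bands)
    out["amide1"] = replace(
        bands["amide1"], amplitude=bands["amide1"].amplitude * f1,
        width=bands["amide1"].width * widen,
    )
    out["amide3"] = replace(
        bands["amide3"], amplitude=bands["amide3"].amplitude * f3,
        width=bands["amide3"].width * widen,
    )
    out["amide3_secondary"] = replace(
        bands["amide3_secondary"],
        amplitude=bands["amide3_secondary"].amplitude * f3 * fc,
        width=bands["amide3_secondary"].width * widen,
    )
    return out


def generate_spectrum(
    spec: SpectrumSpec,
    model: DegradationModel | None = None,
    bands: dict[str, BandModel] | None = None,
    noise_sigma0: float = NOISE_SIGMA0,
    amplitude_scale: float = 1.0,
) -> Spectrum:
    """Generate one synthetic point spectrum.

    ``amplitude_scale`` multiplies all band amplitudes (used for
    per-quadrant random effects). Identical arguments give bit-identical
    output.
    """
    model = model or DegradationModel()
    bands = dict(bands or DEFAULT_BANDS)
    wn = wavenumber_grid()

    eff = _degraded_bands(bands, spec, model)
    if spec.locus == "inter_tubular":
        bg_scale = INTER_TUBULAR_BG_SCALE
        band_scale = INTER_TUBULAR_BAND_SCALE
    else:
        bg_scale = 1.0
        band_scale = 1.0

    y = fluorescence_background(wn, bg_scale)
    for b in eff.values():
        y = y + band_scale * amplitude_scale * b.profile(wn)

    sigma = noise_sigma0 * bg_scale / np.sqrt(spec.acq_min)
    if sigma > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, sigma, wn.size)

    meta = {
        "tooth_id": spec.tooth_id,
        "quadrant": spec.quadrant,
        "distance_um": spec.distance_um,
        "acq_min": spec.acq_min,
        "locus": spec.locus,
        "treatment": spec.treatment,
    }
    return Spectrum(wn, y, meta)


def generate_transect(
    tooth_id: str,
    quadrant: str,
    n_points: int,
    spacing_um: float,
    model: DegradationModel | None = None,
    treatment: str = "naocl",
    seed: int = 0,
    acq_min: float = 24.0,
    locus: str = "intra_tubular",
    cdj_offset_um: float | None = None,
    quadrant_effect_sd: float = 0.02,
    noise_sigma0: float = NOISE_SIGMA0,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Generate a transect of equidistant point spectra.

    Point k (1-based) lies at ``k * spacing_um`` from the canal wall; an
    additional point at ``cdj_offset_um`` is appended when requested. A
    per-transect multiplicative amplitude effect (log-normal, sd
    ``quadrant_effect_sd``) emulates between-quadrant variability.

    Returns the spectra and the matching manifest rows.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if spacing_um <= 0:
        raise ValueError("spacing_um must be > 0")
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _stable_hash(tooth_id, quadrant)])
    base_seed = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
    rng = np.random.default_rng(base_seed)
    amp = float(np.exp(rng.normal(0.0, quadrant_effect_sd))) if quadrant_effect_sd > 0 else 1.0

    distances = [k * spacing_um for k in range(1, n_points + 1)]
    if cdj_offset_um is not None:
        distances.append(float(cdj_offset_um))

    spectra: list[Spectrum] = []
    rows = []
    for i, d in enumerate(distances):
        spec = SpectrumSpec(
            tooth_id=tooth_id,
            quadrant=quadrant,
            distance_um=float(d),
            acq_min=acq_min,
            locus=locus,
            treatment=treatment,
            seed=(base_seed + 1 + i) & 0x7FFFFFFF,
        )
        spectra.append(
            generate_spectrum(spec, model, noise_sigma0=noise_sigma0, amplitude_scale=amp)
        )
        rows.append(
            {
                "file": f"{tooth_id}_{quadrant}_{int(round(d)):04d}um.txt",
                "tooth_id": tooth_id,
                "quadrant": quadrant,
                "distance_um": float(d),
                "acq_min": acq_min,
                "locus": locus,
                "treatment": treatment,
            }
        )
    return spectra, pd.DataFrame(rows)


def _stable_hash(*parts: str) -> int:
    h = 2166136261
    for part in parts:
        for ch in str(part):
            h = ((h ^ ord(ch)) * 16777619) & 0x7FFFFFFF
    return h


# ---------------------------------------------------------------------------
# Indentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndentationParams:
    """Logarithmic depth-vs-distance model: depth = a - b*ln(d + c) + noise."""

    a: float
    b: float
    c: float = 1.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError("b must be >= 0")
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def mean_depth(self, distance_um) -> np.ndarray:
        return self.a - self.b * np.log(np.asarray(distance_um, float) + self.c)


# Defaults frozen from a least-squares fit of depth = a - b*ln(d + 1) to the
# published per-100-um bin mean depths (test and control arms); noise sd is
# the mean of the reported per-bin standard deviations.
TEST_INDENTATION = IndentationParams(a=97.337, b=5.838, c=1.0, sigma=6.22)
CONTROL_INDENTATION = IndentationParams(a=81.533, b=3.635, c=1.0, sigma=2.25)


def default_indentation_params(group: str) -> IndentationParams:
    if group == "test":
        return TEST_INDENTATION
    if group == "control":
        return CONTROL_INDENTATION
    raise ValueError("group must be 'test' or 'control'")


def generate_indentation(
    tooth_id: str,
    group: str,
    distances,
    params: IndentationParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate indentation records along a transect.

    Depths follow ``a - b*ln(distance + c)`` plus Gaussian noise, floored
    at zero. Sites are assigned to quadrants A-D cyclically.
    """
    params = params or default_indentation_params(group)
    distances = np.asarray(list(distances), dtype=float)
    if (distances < 0).any():
        raise ValueError("distances must be >= 0")
    rng = np.random.default_rng(seed)
    depth = params.mean_depth(distances)
    if params.sigma > 0:
        depth = depth + rng.normal(0.0, params.sigma, distances.size)
    depth = np.maximum(depth, 0.0)
    return pd.DataFrame(
        {
            "tooth_id": tooth_id,
            "quadrant": [VALID_QUADRANTS[i % 4] for i in range(distances.size)],
            "distance_um": distances,
            "depth_um": depth,
            "group": group,
        }
    )


# ---------------------------------------------------------------------------
# Study-patterned dataset
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    """Sampling design mirroring the irrigation study.

    NaOCl-treated teeth: 18 points at 50 um spacing in each of four
    quadrants; the water-irrigated control: 6 points at 150 um spacing in
    the buccal quadrant only.
    """

    n_test_teeth: int = 7
    n_control_teeth: int = 1
    test_points: int = 18
    test_spacing_um: float = 50.0
    control_points: int = 6
    control_spacing_um: float = 150.0
    acq_min: float = 24.0
    quadrant_effect_sd: float = 0.02
    indentation_sites_per_tooth: int = 18
    indentation_max_um: float = 900.0


def generate_study(
    seed: int = 0,
    design: StudyDesign | None = None,
    model: DegradationModel | None = None,
) -> tuple[list[Spectrum], pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic study: spectra + manifest + indentation.

    Returns ``(spectra, manifest, indentation_records)``.
    """
    design = design or StudyDesign()
    model = model or DegradationModel()
    spectra: list[Spectrum] = []
    manifests = []
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 91])

    for t in range(design.n_test_teeth):
        tooth = f"T{t + 5:02d}"  # treated teeth
        for quadrant in VALID_QUADRANTS:
            sp, mf = generate_transect(
                tooth, quadrant, design.test_points, design.test_spacing_um,
                model=model, treatment="naocl", seed=seed,
                acq_min=design.acq_min, quadrant_effect_sd=design.quadrant_effect_sd,
            )
            spectra.extend(sp)
            manifests.append(mf)
    for t in range(design.n_control_teeth):
        tooth = f"C{t + 12:02d}"
        sp, mf = generate_transect(
            tooth, "A", design.control_points, design.control_spacing_um,
            model=model, treatment="control", seed=seed,
            acq_min=design.acq_min, quadrant_effect_sd=design.quadrant_effect_sd,
        )
        spectra.extend(sp)
        manifests.append(mf)
    manifest = pd.concat(manifests, ignore_index=True)

    indent_frames = []
    for t in range(design.n_test_teeth):
        d = rng.uniform(0.0, design.indentation_max_um, design.indentation_sites_per_tooth)
        indent_frames.append(
            generate_indentation(
                f"T{t + 5:02d}", "test", d,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    for t in range(design.n_control_teeth):
        d = rng.uniform(0.0, design.indentation_max_um, design.indentation_sites_per_tooth)
        indent_frames.append(
            generate_indentation(
                f"C{t + 12:02d}", "control", d,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    indentation = pd.concat(indent_frames, ignore_index=True)
    return spectra, manifest, indentation
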