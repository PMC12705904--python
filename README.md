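# ramident

Micro-mapping of NaOCl-induced collagen degradation in root dentine:
Raman band analysis, spectral quality-index filtering, spatial gradient
regression with boundary estimation, and reference-point indentation
statistics — driven by a synthetic-data generator so the whole analysis
is testable at desk scale.

## The problem

Sodium hypochlorite (NaOCl), the standard root-canal irrigant, chemically
degrades the type-I collagen matrix of dentine. The question is *how far*
into the root wall the damage reaches. Point Raman spectra taken along
transects from the canal lumen towards the cemento-dentinal junction
(CDJ) report collagen state through the Amide I band (~1667 cm^-1,
intensity loss = degradation) and the Amide III doublet (~1243 cm^-1,
doublet flattening = denaturation), normalized to the mineral carbonate
band (1072 cm^-1). Cyclic reference-point indentation along the same
geometry gives a microhardness surrogate (total indentation distance).

The package implements, as tested library code:

* a synthetic generator of transect spectra (four-band mixture on a
  fluorescence background, degradation profile
  `f(d) = floor + (1-floor)(1-e^(-d/lambda))`, fluorescence-masked
  inter-tubular spectra, noise sd ∝ 1/sqrt(acquisition time)) and of
  logarithmic indentation-depth records (`depth = a - b ln(d + c)`);
* preprocessing: ALS baseline, 8-point smoothing, carbonate
  normalization, zero offset;
* band descriptors: heights, positions, FWHM, chord-corrected areas,
  doublet contrast, SNR (with the printed truncate-to-one-decimal
  convention);
* the quality index `QI = (r_AmideIII + r_AmideI + r_1450) x general`
  with the QI <= 6 inclusion filter;
* tooth morphometry (maturity index MI = RT/CW, Archimedes canal
  volume, extent of instrumentation);
* distance-binned OLS of band area on distance (per 100 um), a
  saturating-exponential decay fit of Amide I height with the boundary
  of effect at `lambda ln 20`, and the indentation statistics (binned
  ANOVA + Bonferroni, near-lumen Welch comparison, logarithmic trend).

See `docs/methods.md` for the model details and design choices.

## Worked example

Run the four analysis stages (a full synthetic study: 7 NaOCl-irrigated
teeth sampled at 18 x 50 um points in four quadrants, one control tooth
at 6 x 150 um points, plus indentation records):

```
python analysis/01_simulate_study.py
python analysis/02_spectral_features.py
python analysis/03_degradation_gradient.py
python analysis/04_indentation_analysis.py
```

which prints (seed 1):

```
processed 510 spectra; 510 accepted (QI <= 6)
mean accepted Amide I height: 0.395 near the lumen (<=100 um) vs 0.704 far (>=800 um)
Amide I area gradient (normalized area units per 100 um):
    Entire thickness:   0.536 [0.502, 0.570]  n=510
        Up to 100 um:   2.830 [2.172, 3.489]  n=56
        > 100-200 um:   1.516 [0.680, 2.352]  n=57
        ...
        > 800-900 um:   0.069 [-0.725, 0.863]  n=57
Amide I decay: y0=0.283, y_inf=0.719, lambda=248 um (r2=0.987)
estimated boundary of effect: 743 um from the lumen
test: depth = 96.4 - 5.63 ln(d + 1), r2 = 0.42
control: depth = 76.5 - 2.90 ln(d + 1), r2 = 0.40
within 200 um of the lumen, test indentations are 8.0 um deeper than control
```

Reading this: the band-area gradient is steepest in the first 100 um
from the lumen and decays to a flat background by ~600 um, mirroring the
degradation profile built into the generator (true lambda = 250 um,
recovered as 248 um); the 95%-recovery boundary lands at ~743 um
(analytically, 250 ln 20 ≈ 749 um). Indentations are deeper (softer
dentine) near the lumen in treated roots, following the logarithmic
trend, with the control trend shallower and flatter. Tables land in
`results/`.

The same stages are scriptable through the CLI
(`ramident simulate|features|quality|morphometry|gradient|indent|run`),
e.g. `ramident run --seed 1 --out-dir out/`.

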