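# Methods

`ramident` implements a desk-scale twin of a micro-mapping experiment:
point Raman spectra taken along transects from the root-canal lumen
towards the cemento-dentinal junction (CDJ) quantify how sodium
hypochlorite (NaOCl) irrigation degrades dentinal collagen, and cyclic
reference-point indentation along the same geometry quantifies the
accompanying microhardness gradient. Because the original specimens are
physical teeth, the package ships a synthetic-data generator that encodes
the statistical structure the analysis assumes; every analysis stage is
exercised and validated against that generator plus closed-form oracles.

## Synthetic spectra

Spectra live on a 1 cm^-1 grid over 1050-1750 cm^-1 (701 samples,
endpoints included). Each spectrum is

    intensity = fluorescence background + band mixture + noise

* **Bands.** Gaussian by default (Lorentzian available); carbonate
  1072 cm^-1 (amplitude 100 counts, the internal mineral reference),
  Amide III sub-bands at 1243 (60) and 1270 cm^-1 (40), CH deformation
  1450 cm^-1 (50), Amide I 1667 cm^-1 (70). All default FWHMs are
  18 cm^-1: equal widths make the carbonate-normalized peak heights
  invariant to the fixed-width smoothing step, so relative band metrics
  are unbiased through the pipeline. The second Amide III sub-band
  position (1270 cm^-1) is a modeling choice inside the 1215-1302 cm^-1
  window; the "doublet contrast" is 1 - valley/lower-peak.
* **Degradation profile.** For NaOCl-treated spectra the Amide
  amplitudes are multiplied by
  `f(d) = floor + (1 - floor)(1 - exp(-d/lambda))` with decay length
  `lambda = 250 um` and floors 0.35, confining pronounced change within
  roughly 300-500 um of the lumen. The doublet's secondary sub-band is
  additionally multiplied by the same saturating form (doublet floor
  0.35), flattening the doublet near the lumen, and band widths grow by
  up to 30% at the lumen. The CH 1450 cm^-1 band, which receives
  contributions from both organic phases, is left unmodulated; this also
  keeps one stable organic reference for the quality rating.
* **Background and masking.** The fluorescence background is a quadratic
  in (wavenumber - 1050), amplitude 250 counts. Inter-tubular loci are
  fluorescence-dominated: background x20, Raman bands suppressed to 15%
  (so the carbonate peak is far below 25% of the background range), and
  noise scaled with the background. Such spectra reliably fail carbonate
  normalization and receive the worst quality score.
* **Noise.** Zero-mean Gaussian with sd `12 x bg_scale / sqrt(acq_min)`
  counts. The 1/sqrt(time) law gives the published direction of the
  SNR-versus-acquisition-time comparison; at 24 min the synthetic SNR
  (~18) sits in the published range. Per-quadrant variability is a
  multiplicative log-normal amplitude effect (sd 0.02); no published
  between-quadrant variance estimate exists, so this default is a
  deliberate small guess.
* **What is *not* emulated:** instrument optics, confocal depth response,
  cosmic-ray spikes, wavenumber miscalibration, and real
  tooth-to-tooth chemistry differences. Passing tests therefore show the
  *analysis* recovers the structure it assumes, not that the generator
  reproduces any particular tooth.

## Preprocessing

Fixed order: baseline -> 8-point smoothing -> carbonate normalization ->
zero offset.

* **Baseline.** Default is asymmetric least squares (Whittaker smoother,
  second-difference penalty `lam = 1e7`, asymmetry `p = 0.01`, <= 20
  reweighting iterations, solved by banded Cholesky). The stiff penalty
  was chosen so the narrow carbonate band near the grid edge loses < 1%
  of its height. An iterative-polynomial fallback (degree 5) is exact on
  polynomial backgrounds and serves as the reproducibility oracle.
* **Smoothing.** "8-point smoothing" is implemented as a centered
  moving average over samples k-4..k+3 (edges shrink), with
  Savitzky-Golay as an option.
* **Normalization.** Intensities are divided by the carbonate peak
  height (maximum within 1072 +/- 15 cm^-1) so the reference peak equals
  1; normalization by band area is an option. A spectrum is declared
  fluorescence-masked when the peak's prominence above the local window
  median does not exceed 3x the noise sd estimated from a detrended
  band-free window (1500-1580 cm^-1).
* **Idempotence.** Stages stamp `meta` flags and the pipeline
  short-circuits on already-processed spectra, so re-running it is a
  numerical no-op; this is a provenance design, not an algebraic property
  of the moving average.

## Band features and quality index

Peak height is the window maximum (ties resolve toward the nominal
center, then to the lower wavenumber); FWHM uses linearly interpolated
half-maximum crossings; band areas are trapezoidal after subtracting the
local chord between window endpoints (robust to residual background;
negative areas floor at 0). SNR = peak height / peak-to-peak detrended
quiet-window residual; printed SNR values truncate (not round) to one
decimal, matching the published fractions.

Each spectrum's three regions (Amide III 1215-1302, Amide I 1615-1719,
CH 1450) are rated 1-3 against the unit carbonate reference: rating 3
when the main band lies outside [0.25, 0.75] (closed bounds) or an
accessory peak exceeds it; rating 2 when an accessory peak itself lies
in [0.25, 0.75]; rating 1 otherwise. The general quality is 1 with no
unacceptable region, 3 when all three are unacceptable, 2 otherwise
(the two-of-three case is a documented choice). The quality index is
`QI = (sum of ratings) x general` with inclusion at QI <= 6; the
operator precedence follows the published worked examples (10 and 6).
One published text passage swaps the Amide I/III window labels; the
assignment consistent with the band centers is used.

## Gradient, boundary and indentation statistics

* **Binned linear models.** OLS of band area on distance (scaled per
  100 um — the published coefficient scale is unstated) within half-open
  (lo, hi] 100-um bins plus an entire-thickness pseudo-bin, optionally
  stratified by the integer-floor maturity group, with
  extent-of-instrumentation as covariate when it varies within the
  group. Confidence intervals are plain OLS; within-tooth clustering is
  not modeled (caveat: intervals are anti-conservative under strong
  clustering). Bins with < 3 accepted sites, or no distance variation,
  are flagged rather than fitted.
* **Decay fit.** `y(d) = y_inf - (y_inf - y0) exp(-d/lambda)` by
  multi-start nonlinear least squares (starts lambda in {50, 100, 250,
  500, 1000} um). The published analysis names no functional form; the
  saturating exponential is adopted, and the boundary of effect is the
  95%-recovery distance `lambda ln 20` (~749 um for lambda = 250 um).
  Flat (control-like) data are detected by an F-test of the decay
  against a constant mean (alpha 0.05) and reported as unidentifiable
  instead of returning a meaningless decay length.
* **Indentation.** Depth summaries per 100-um bin (sample SD), one-way
  ANOVA across bins with Bonferroni-adjusted pairwise t-tests
  (`p_adj = min(1, m p)`, family = all pairs of non-empty bins), a Welch
  comparison of treated-vs-control depths within 200 um of the lumen,
  and the logarithmic trend `depth = a - b ln(d + c)`, linear in
  `ln(d + c)` with c fixed at 1 um by default (admitting d = 0) or fit
  freely. Generator defaults were frozen once by least squares on the
  published per-bin means: test a = 97.34, b = 5.84; control a = 81.53,
  b = 3.64 (shallower and flatter); noise sd 6.22 / 2.25 um from the
  published per-bin SDs.

## Monte-Carlo problem sizes

Stochastic validation uses: 50 single-transect replicates (18 points,
50 um) for decay-length recovery (median relative error ~6%, well inside
the 20% requirement); 100 full-study replicates (7 treated teeth x 4
quadrants x 18 points) for the binned-gradient pattern and 100
six-point control transects for null coverage; 200 null replicates for
ANOVA type-I calibration; and a balanced 10-vs-10-teeth design (18
sites/tooth) for the near-lumen sensitivity check — chosen by an
a-priori power computation because a single-control-tooth arm (the
published design) has ~3 near-lumen sites and cannot support a
high-power detection claim, whatever the method.

## Known limitations

* The generator's degradation is separable (amplitude x spatial factor);
  real chemistry couples band shape, position and mineral changes.
* OLS intervals ignore tooth/quadrant clustering (see above).
* The quality rating is a deterministic operationalization of a visual
  rubric; borderline behavior at exactly 25%/75% follows the documented
  closed-interval rule.
* Published regression coefficients and indentation tables derive from
  the physical specimens and are intentionally not reproduced
  numerically; only their qualitative structure (steep near-lumen
  gradient, flat control, deeper near-lumen indentations) is validated.
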