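# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Measurement model and processing chain

A point measurement is a series of short exposures (nominally 1000 spectra,
400–4000 cm⁻¹) at one spot on the water surface of a stirred beaker. The
per-measurement chain is:

1. **Averaging.** Pointwise arithmetic mean of the single spectra. The mean
   (rather than the bare sum) is used; the correlation features are invariant
   to the 1/N factor in any case.
2. **Smoothing.** Centered 11-point boxcar. At the spectrum ends the window
   shrinks symmetrically (width `2·min(5, i, n−1−i)+1`) instead of padding,
   so no data are fabricated outside the measured range.
3. **Baseline estimation.** Moving-window scheme, default width 150 cm⁻¹:
   rolling minimum, then rolling maximum of the same width (together a
   morphological opening), then a centered boxcar of the same width. The
   opening step matters: a bare rolling minimum sits below any sloped
   background by roughly `slope × window`, which biases the corrected
   spectrum and its correlation features; the opening reconstructs smooth
   backgrounds to within curvature-limited error (≲0.2% of range for
   backgrounds varying on >1000 cm⁻¹ scales) while still cutting completely
   under peaks narrower than the window. Alternative estimators can be
   registered in `preprocess.BASELINE_METHODS`. Because of the final
   smoothing the estimate is not constrained to lie below the spectrum
   pointwise.
4. **Correction.** Corrected = averaged − baseline; both stored, so the sum
   reconstructs the input to machine precision.

Window widths are interpreted in cm⁻¹ and converted to points via the median
grid spacing, so non-uniform and non-integer grids are handled by
interpolation rather than assumed away.

## Features

`R` correlates the smoothed, uncorrected average with the standard polymer
spectrum; `R_b` correlates the baseline-corrected average with the
(identically processed) standard. Correlations use the full 400–4000 cm⁻¹
overlap with the reference linearly interpolated onto the sample grid; no
band masking. The reference is baseline-corrected by default — for a clean
standard the effect is negligible, and the flag `correct_ref=False` is
exposed. Peak heights `H_b@k` are windowed maxima over `k ± 5 cm⁻¹`
(configurable tolerance; the band positions are nominal). Detection
statistics process every single spectrum with the measurement-level
configuration (vectorised 2-D filters) and threshold per-spectrum R_b at
0.2; `m_b` is NaN-flagged when no spectrum qualifies.

## Isotherm calibration

The fit is to per-concentration mean R_b (13 design concentrations,
0–0.94 mg/ml, unweighted; weighting by replicate precision is available).
Seven model forms are implemented exactly as tabulated in the module
docstring. Numerical notes:

* **Optimizer.** `scipy.optimize.least_squares` (TRF, bounded), multi-start
  over affinity `b2 ∈ {0.1, 1, 10, 100}` × amplitude `b1 ∈ {0.5, 1}`, offset
  initialised at the response at the lowest concentration, `b3 = 1` where
  present; tolerances 1e−12. The affinity direction is the multi-modal one,
  hence the log-spaced grid. Monte-Carlo replications can warm-start from a
  known solution with `multistart=False`.
* **Bounds.** `b1, b2 ≥ 0`, exponent `b3 ∈ [0.1, 10]`, offset `c`
  unbounded. `b1` is deliberately *not* capped at 1: near saturation the
  monolayer assumption breaks (multilayer chunks form), and the empirical
  curve may exceed the correlation bound while remaining the best
  description of the calibrated range.
* **Dubinin–Radushkevich** is implemented as printed in its source form,
  `b1·exp(−b2·ln(1+1/C)) + c = b1·(1+1/C)^(−b2) + c`, with the C = 0 value
  defined by continuity as `c` (no squared-log Polanyi term).
* **Statistics.** `MSE = RSS/(n−p)`, `RMSE = √MSE`, `R² = 1 − RSS/TSS`,
  `R²_adj = 1 − (1−R²)(n−1)/(n−p)`; `AIC = 2p − 2lnL` and
  `BIC = p·ln n − 2lnL` with the Gaussian log-likelihood at `σ̂² = RSS/n`.
  No small-sample AICc. A perfect fit (RSS = 0) gets −∞ information criteria
  as an explicit sentinel. The modified Temkin form is fitted with four raw
  parameters but counted with **3 effective parameters** by default: its
  `b3` and `c` are nearly collinear (`b1·ln(b2C+b3)+c` ≈ reparameterisable
  offset), so four-parameter counting overstates its complexity; the
  alternative count is exposed (`temkin_p4=True`).
* **Selection.** AIC ascending, ties by BIC then parameter count. The
  Langmuir curve is the default calibration regardless of rank (it is the
  mechanistically motivated form); `select="best"` picks the AIC winner.
* **Inversion.** Closed form for Langmuir; generic monotone bracketing +
  Brent otherwise. R_b at or below the fitted floor `c` returns 0 with a
  `below_floor` flag; at or above saturation `b1 + c` raises an error.
* **Prediction interval.** Delta method for a new observation:
  `ŷ ± t_{n−p,1−α/2}·√(MSE·(1 + gᵀ(JᵀJ)⁻¹g))` with `g` the parameter
  gradient of the curve (central differences) and `J` the Jacobian at the
  data. Concentration intervals invert the band edges by root finding,
  returning 0 / +∞ when an edge never crosses the measured R_b.
* **Center-point sensitivity.** `sensitivity_c0` compares the full design
  (9 measurements per level) with the beaker-center subset (3 per level):
  per-level means, their Pearson correlation, both Langmuir fits, and a flag
  per parameter for whether the center-only estimate lies within one
  standard error of the full-design estimate.

## Stage geometry

Two plate markers with known plate-frame coordinates are located on the
stage; the unique planar rigid transform (rotation from the marker-pair
direction, translation from the midpoints — the two-point least-squares
solution) maps the plate frame onto the stage and carries the plate and
beaker centers with it. A measured marker separation deviating >5% from the
design separation raises a warning with the scale residual rather than being
silently absorbed — two points cannot distinguish scale error from marker
misidentification, so the operator must check. The plate-frame coordinates
are a configuration object: the default `PlateLayout` uses placeholder
marker positions consistent with the legible plate dimensions (hole radius
13 mm, beaker inner radius 11.25 mm) and the required ordering (plate center
between marker B and beaker center); a physically measured plate should
override them. Sampling points C1/C2 are placed 1000 and 2000 µm from the
measured center along a configurable direction (default stage +x; the
protocol leaves the direction free), sharing the center's focus height, and
must fall inside the beaker's inner radius.

## Synthetic-data generator

The simulator emulates the validation experiment's structure:

* **Reference spectrum**: Gaussian peaks at the seven PE bands on a
  near-zero floor; the 2844/2878 cm⁻¹ C–H doublet dominates (amplitudes
  1000/750 vs 90–320 for the fingerprint bands), widths 6–12 cm⁻¹.
* **Water background**: a broad fluorescence hump (amplitude 600, center
  1300 cm⁻¹, σ 900 cm⁻¹, offset 200) plus the O–H stretch band (amplitude
  800, center 3420 cm⁻¹, σ 160 cm⁻¹). The O–H band is wide enough that the
  150 cm⁻¹ baseline window assigns it to the background, as it should.
* **Hit process**: each exposure independently catches a particle with
  probability `θ(C) = θ_max·K·C/(1+K·C)` (defaults θ_max = 0.9, K = 8 ml/mg
  — K chosen to match the affinity scale of the calibration examples, and
  θ_max < 1 because even a saturated surface leaves the laser sometimes
  between clusters). A hit adds `signal_fraction` (default 0.6) of the
  reference to the background. Additive Gaussian noise, default σ = 20
  counts; optional shot-noise scaling.
* **Design**: 13 concentrations (0–0.94 mg/ml in steps of 0.5 mg in
  6.37 ml) × 3 sampling points × 3 repeats = 117 measurements, default 1000
  spectra each. One master seed expands into per-measurement
  `SeedSequence` spawn keys, so any subset is independently reproducible.

What the simulator does **not** emulate — and what passing tests therefore
do not establish for real data: correlated hit runs as a cluster transits
the laser spot (hits are i.i.d. here), partial/defocused hits with variable
signal fraction, cosmic-ray spikes, wavenumber miscalibration, fluorescent
contaminants and dissolved organic matter, multi-polymer mixtures, and the
dependence of R_b(C) shape on particle size. In particular the simulated
R_b–C relation is only approximately Langmuir: R_b is a nonlinear function
of the hit fraction, so even at zero detector noise the fitted curve differs
slightly from the hit-probability curve (the fitted `b2` is larger than the
generator's K, and binomial fluctuation across measurements persists).
Qualitative conclusions (saturation shape, monotonicity, the linear model's
inadequacy, center-point robustness) are what the simulation supports.

## Problem sizes

The test suite and the acceptance script keep simulations small enough for
routine runs while preserving the statistical structure: most unit tests use
a 4 cm⁻¹ grid with 40–60 spectra per measurement; the end-to-end study uses
the full 1 cm⁻¹ grid with 300 spectra per measurement (the binomial standard
error of f_b at 300 spectra is < 3%, so monotonicity and calibration
behaviour are unaffected); Monte-Carlo studies use 50–500 replicates as
stated per test. Package defaults remain the full protocol (1000 spectra).

## Known limitations

* The wide-CSV reader loads a whole measurement into memory (~30 MB at full
  protocol size); no streaming.
* Two-marker registration cannot estimate scale; a stage with anisotropic
  axis calibration would need a third marker.
* The delta-method interval is first-order; for strongly nonlinear fits at
  small n a bootstrap band (cross-checked in the tests) is more defensible.
* `estimate` (CLI) refits the curve from the feature table rather than
  deserialising the fitted object; exact round-tripping of fit state is not
  implemented.
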