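# Methods

## Scope and model

The package estimates per-condition cell viability from single-cell Raman
spectra of mixed (viable + non-viable) drug-treated populations, and an
IC50 from the resulting dose ladder. Its analysis chain is: wavelength and
intensity calibration → cosmic-spike removal → third-order EMSC background
correction → Savitzky–Golay smoothing → area normalization → region
selection → empty-row rejection → PCA → linear SVM → per-condition viable
percentages → log-logistic dose–response fit. The canonical order of the
preprocessing steps is enforced by `preprocess_pipeline` and recorded in
an append-only provenance log; `predict_viability` refuses inputs whose
preprocessing parameters differ from the training data's.

## Synthetic data generator

`synthdata` emulates a high-content Raman screen of drug-treated
monocytes:

- **Components.** Protein, lipid, nucleic-acid and drug spectra are sums
  of Lorentzian bands (FWHM 13–28 cm⁻¹) at standard cell-spectrum
  positions (e.g. nucleic acids 783/813/830/1096, phenylalanine 1004,
  amide I 1660, lipid CH₂ 1441/2851, drug 1086/1215/1247 cm⁻¹). Water is
  a broad OH-bend/OH-stretch continuum; drug fluorescence a smooth ramp
  plus a broad fingerprint-region hump whose amplitude scales linearly
  with dose. All components are clipped non-negative and normalized to
  unit area so mixture weights read as composition fractions.
- **Populations.** Each well draws labels Bernoulli(viable_fraction) and
  an empty-row indicator Bernoulli(empty_rate, default 0.1 — one in ten
  detections hits no cell). Viable and non-viable cells differ in their
  protein/lipid/nucleic-acid/drug weights (contrast ‖Δw‖ ≈ 0.22, shifting
  nucleic acid and drug up and protein down in non-viable cells, with a
  mild dose-dependent drift in both classes). Cell-to-cell biological
  variability is Gaussian jitter on the weights (SD 0.05, renormalized to
  the simplex); this low-rank variance is what concentrates spectral
  variance in the leading principal components, as in real single-cell
  data. Nuisance processes: per-spectrum multiplicative gain
  (CV 0.05), additive detector noise (SD 1.5e-4 against band peaks of
  ~3e-3 after unit-area mixing), and Poisson cosmic spikes (rate
  0.05/spectrum, single-channel, 5–50× the local signal).
- **Defaults as study conditions.** With these defaults the pipeline's
  measured operating point is: first two PCs carry ≈ 81–84 % of variance,
  10-fold CV cost ≈ 7–9 % (dominated by the impurity of condition-level
  training labels), per-condition viable-percentage recovery within ~2
  points, end-to-end IC50 ≈ 0.20–0.28 µM on the standard ladder. The
  defaults were fixed once when the generator was designed and are not
  tuned per experiment.
- **What is not emulated.** Instrument drift between batches, focus- and
  morphology-dependent sampling volumes, fluorescence photobleaching
  kinetics (saturation is at most a clip), correlated (pink) detector
  noise, multi-channel cosmic events, and any real biological band-shape
  changes beyond linear re-weighting of fixed components. Passing tests
  therefore demonstrate correctness of the algorithms under the stated
  statistical model, not performance on real cells.

## Calibration

- Reference peak detection: local maxima above 5 % relative prominence;
  centers refined by a 3-point parabola on the *reciprocal* intensities —
  exact for an isolated Lorentzian at any sampling phase — with three
  iterations of neighbor-tail subtraction, giving sub-10⁻⁹-pixel accuracy
  on clean references. Detected peaks are matched to the known band list
  in order; a count mismatch is an error.
- Polynomial degree default 3; the fitted map must be strictly increasing
  over the pixel range and the per-band residuals below 2 cm⁻¹ (both
  enforced by `CalibrationModel`).
- Instrument response: smoothed (Savitzky–Golay, window 31, order 2)
  ratio of measured lamp to true irradiance, rescaled to unit mean,
  strictly positive.
- Resampling onto the common analysis grid is linear (monotone, no
  overshoot); no extrapolation outside the calibrated range. The forward
  renderer in `synthdata` samples the continuous spectrum with a cubic
  spline, since a detector samples a physically smooth spectrum.

## Preprocessing

- **Despiking** (window 7, z-threshold 8): a channel is corrected when its
  residual against the running median exceeds 8 robust SDs (1.4826·MAD of
  that spectrum's residuals) *and* dominates both immediate neighbors
  2-fold. The isolation criterion encodes that a cosmic-ray hit is
  narrower than the instrument lineshape; without it, band crests of
  high-SNR spectra are falsely flagged. Corrections are reported per
  spectrum. The detector assumes single-channel spikes (the generator's
  model); a two-channel event would need two passes.
- **EMSC** (order 3): per-spectrum OLS on [reference | water |
  fluorescence | 1, t, t², t³] with t the axis rescaled to [−1, 1] for
  conditioning; full column rank is checked at basis construction. Rows
  with reference coefficient ≤ 1e-6 are flagged `no_cell_signal` and left
  undivided. The fluorescence interferent has no canonical functional
  form; the basis uses the generator's broad-hump shape, and in a real
  deployment would be replaced by a measured drug-fluorescence spectrum.
- **Smoothing**: Savitzky–Golay window 9, order 3 (edges by polynomial
  fit on the truncated window). **Area normalization** divides by the
  trapezoidal integral of |y| over the analysis windows — computed before
  cropping, so the silent region never influences the norm; zero-integral
  rows are flagged, not divided. **Region selection** keeps
  [615, 1800) ∪ [2790, 3010) cm⁻¹, half-open intervals compared on axis
  values.
- **Empty-row rejection**: a row is dropped if flagged by EMSC or its
  cell coefficient falls below 0.05× the median of its *well* (anchoring
  per well tolerates dose-dependent intensity shifts) or below an
  absolute floor of 0.05 in units of the reference spectrum — the floor
  exists so a well containing no cells at all (well median ≈ 0) is still
  fully rejected, with a warning-level report entry.

## Chemometrics

- PCA is a mean-centered SVD; explained-variance ratios are against the
  total variance. Loading signs follow the largest-|element|-positive
  convention, making scores deterministic across platforms.
- The SVM is a linear soft-margin classifier (box constraint C = 1) on
  the first two PC scores; decision f(z) = w·z + b with f > 0 ⇒ viable.
  Because area-normalized spectra give PC scores of order 10⁻³, the
  hinge/regularization balance at C = 1 would otherwise degenerate to the
  majority class; training therefore standardizes each score column by
  its training SD before solving the QP and maps the hyperplane back to
  raw-score units. The returned model is still a plain linear function of
  the raw scores, and `standardize=False` exposes the plain QP for
  oracle comparisons. The historical "alpha = 0.5" initialization of the
  dual variables is carried as metadata (`alpha_init`); any convergent
  solver reaches the same hyperplane.
- Training labels are condition-level: all control cells "viable", all
  highest-dose cells "non-viable", accepting the known impurity of both
  populations. Cross-validation is stratified, seeded, and pools errors
  over folds (not averaged per fold).
- Reconstruction is scores × loadings, with the dataset mean added only
  on request; the boundary crossing of a PC1-parallel line is solved in
  closed form from w·z + b = 0 and errors when w₁ = 0 or the crossing
  leaves the requested range.

## Dose–response

The fit is v(d) = L + (U − L)/(1 + (d/IC50)^s). A log-dose model cannot
take d = 0 as a fitted point, so the control wells (two per batch,
averaged per batch, then averaged across batches) anchor U and leave the
residuals. L is bounded in [0, min(30, U)] %, s in [0.1, 10], IC50 in
[1e-4, 1e3] µM. A deterministic multi-start grid (5 slopes × 12
logarithmically spaced IC50 starts, trust-region least squares) makes the
fit reproducible; the best start by RSS wins. Percent scale is arbitrary
(0–1 inputs fit identically up to asymptote units). Fits whose IC50
leaves [min dose/10, max dose×10] are flagged extrapolated; a positive
viability-vs-log-dose trend flags the fit non-inhibitory with a warning.
Pooling both batches into one fit and anchoring to the mean control are
conventions of this package; with only four positive doses the IC50 is
accordingly soft (the bundled published table gives 0.208 µM under these
conventions).

## Problem sizes

The bundled simulations use a 1340-channel detector axis (300–3112 cm⁻¹
at ~2.1 cm⁻¹), 400 cells/condition in the examples and 1000
cells/condition × 10 seeds in the recovery studies — sizes at which every
statistic of interest (binomial fractions, CV cost, IC50) is stable to
well under its assessment tolerance.

## Known limitations

- The spike detector and the fluorescence basis shape are package
  conventions, not published algorithms; both are validated only against
  the generator's model of those processes.
- Condition-level training labels bias the SVM when class impurity is
  asymmetric; the CV cost absorbs this rather than correcting it.
- The IC50 convention (anchored upper, bounded lower, pooled batches)
  materially affects the estimate when only a few dose levels exist.
- `reject_empty`'s absolute floor assumes the EMSC reference is scaled
  like a typical single cell.
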