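# Methods

This note documents the models, defaults and numerical choices behind
`volatilofp`, and what the synthetic-data validation does and does not show.

## Chromatogram model and conventions

A chromatogram is a matrix of detector intensities, one row per modulation
event. With modulation period P_M = 4 s and detector rate 100 Hz (the
defaults throughout), a row holds 400 points. First-dimension retention
(¹t_R, reported in minutes) of row *i* is the period **start** time
`t0 + i·P_M` — a fixed convention to avoid off-by-one drift between wrapping
arithmetic and peak coordinates; second-dimension retention (²t_R, seconds)
of column *j* is `j / rate`. Pixel indexing is 0-based. When a raw trace
does not divide evenly into modulations, the trailing partial period is
dropped with a warning (or zero-padded on request).

Grid interchange is deliberately plain text: `*.meta.json` +
`*.grid.csv` + an optional `*.spectra.msp` sidecar with sparse per-pixel
stick spectra keyed `pixel_i_j`. Mass-spectral libraries use the NIST MSP
text dialect; intensities are renormalized to base peak 999 on read.

## Peak detection

- **Noise.** Per modulation slice: 1.4826 × median(|x − m| for x < m), with
  m the slice median. Restricting to sub-median pixels makes the estimate a
  peak-free proxy (peaks only push pixels above the median); for Gaussian
  noise the estimator is consistent for σ. It is floored at machine epsilon
  times the grid maximum so SNR is always finite.
- **Apexes.** Local maxima of the baseline-corrected grid (slice median
  subtracted) above `snr_min × noise`, with non-maximum suppression over a
  window of 3 modulations × ±5 detector points. The wide second-dimension
  window matters: ²t_R peaks span tens of points, and pixel noise would
  otherwise split their flat tops into duplicate apexes. Residual fragments
  in adjacent modulations within 1 point in ²t are merged (idempotent,
  union-find).
- **Footprints and volume.** Pixels are assigned to apexes by watershed on
  the negated signal (descent), then cut at 10% of the apex height. A
  bivariate Gaussian truncated at its 10% level contains exactly 90% of its
  mass, so volumes (footprint sum × pixel area, in intensity·s²) are
  corrected by 1/(1 − 0.1). On noise-free isolated peaks this recovers
  planted volumes to ~2%.
- The apex-pixel spectrum is used as the peak spectrum; deconvolution of
  co-eluting spectra is out of scope.

## Spectral similarity and annotation

Match factors use the Stein–Scott identity-search weighting
`w(m, I) = I^0.6 · m^3` and score 999 × squared cosine of the weighted
vectors, rounded to integer. The reverse match factor deletes query-only
m/z first, so RMF ≥ DMF always (property-tested). The exact composite
formula of commercial NIST search (with its ratio-of-adjacent-peaks term)
is unpublished; the weighted-cosine core is implemented and the exponents
are configurable.

Retention indices use the van den Dool–Kratz linear form on ¹t_R only,
calibrated on the n-C9…n-C25 alkane ladder; extrapolation beyond the ladder
is disabled by default and such peaks are simply not RI-annotatable. The
targeted gate is `DMF ≥ 950 ∧ RMF ≥ 950 ∧ |Iᵀ_exp − Iᵀ_tab| ≤ 20`
(inclusive thresholds; sources differ between "> 950" and "≥ 950", and the
inclusive reading is used, configurably). Spectral-only passes are reported
`class_only`, mirroring the convention of reporting just the compound class
when the retention index falls outside tolerance.

## Template fingerprinting

- **Cross-sample matching** is greedy one-to-one against a reference sample
  (the table with median total volume): candidate pairs within the
  retention window (default 0.25 min × 0.25 s, sized to cover the drift the
  generator produces) must satisfy DMF ≥ 700 ∧ RMF ≥ 700; ties prefer
  higher DMF, then smaller scaled retention distance.
- **Reliability** keeps correspondences present in ≥ 50% of samples,
  boundary inclusive (3 of 6 survives).
- **Registration** fits ¹t_R through a quadratic polynomial and ²t_R
  through a constant offset, least squares on the matched anchors; inverse
  coefficients are fitted from the same anchors for grid resampling.
  Too-few or ¹t-degenerate anchors fall back to a shift-only model with a
  warning; coincident anchors short-circuit to the exact identity. The
  anchor RMS after warping never exceeds the RMS before (the model class
  contains the identity).
- **Template.** One feature per reliable set: apex = median member apex;
  consensus spectrum = per-m/z intensity median of normalized member
  spectra; region = convex hull of member footprints dilated by one pixel
  (built in pixel space so dilation is isotropic, then scaled to retention
  units). Overlapping regions are trimmed along the perpendicular bisector
  of the apexes, measured in pixel units.
- **Extraction** is total by construction: a peak whose apex lies in the
  region — or within one modulation / three detector points of the expected
  apex, protecting against single-pixel jitter across trimmed boundaries —
  and whose DMF against the consensus is ≥ 700 contributes its volume;
  otherwise the baseline-corrected region integral is used (configurable to
  zero-fill instead). The fallback is what keeps partially co-eluting or
  sub-threshold features in the matrix.
- **Normalization** divides each sample by the mean response of its two
  internal standards (the combining rule when two ISs are spiked), then
  converts to percent of the total normalized response over non-IS features.
  Percent rows sum to 100 exactly (floating-point tolerance).

## Chemometrics

- **Fisher ratio** per feature = between-class mean square / within-class
  mean square — identically the one-way ANOVA F (cross-checked against an
  independent ANOVA implementation to 1e-9). Selection is strict, F > 6;
  nominal ANOVA p-values are reported alongside since a fixed threshold and
  a significance level only coincide at particular degrees of freedom.
- **Modeling matrix.** Statistics run on the **ISTD-normalized** view, not
  the percent view. The percent view is compositional: a genuine effect in
  a few features mechanically shifts every other feature's share (closure),
  which inflates Fisher false positives several-fold in simulation. The
  percent view is kept for profiling and chord export, where shares are the
  quantity of interest.
- **PLS-DA** is NIPALS PLS2 on the mean-centered matrix against 0/1 class
  dummies (no autoscaling — mean-centering only), default 3 latent
  variables capped by rank; prediction is argmax over class columns with
  exact ties going to the training majority. Successive X-scores are
  orthogonal to machine precision, and predictions agree with an
  independent PLS2 implementation to 1e-10 on random data.
- **VIP** follows the standard formula
  `VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)`; mean(VIP²) = 1
  by construction.
- **Monte-Carlo CV**: stratified random holdout (default 10%, ≥1 sample
  per class, class counts preserved to rounding), 100 repetitions,
  deterministic under the seed. Fisher selection is recomputed inside each
  calibration split — the leakage-safe ordering — with a global
  pre-selection available for compatibility with simpler workflows; if a
  split selects nothing, all features are used. Note a known small-sample
  effect: with labels permuted, selecting noise features on the calibration
  split biases holdout accuracy *below* chance (anti-learning), so the
  permutation null is judged against the spread of repetition accuracies,
  not against an exact 0.5.
- **Chord export** emits (group, feature, mean %) edges strictly above 2%
  (a group mean of exactly 2.0% produces no edge). Rendering is left to
  dedicated chord-diagram tools.

## Fuzzy-ratio image comparison

For each pixel the reference value is taken as the analyzed value clamped
into the min–max range of the (2r+1)² neighborhood of the other image
(r = 1 by default) — the interval form of nearest-value matching, which
absorbs sub-radius misalignment without dipole artifacts. The signed
normalized difference `(a − r*) / max(a, r*, floor)` is zeroed where both
images sit below the floor (default 1% of the global maximum, keeping the
field invariant under joint rescaling) or within the relative tolerance
(default 0.2) of each other. Because one-directional fuzzy matching is not
symmetric, the reported field is the antisymmetrization
`s = (f(A,B) − f(B,A))/2`, making `compare(A,B) = −compare(B,A)` exact.
Rendering maps s > 0 to green and s < 0 to red over a neutral background.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: two arms
(VP0/VP1) × two timepoints (T1/T2), default 6 samples per cell, 60
compounds per chromatogram on a 240-modulation (16 min) window at
P_M = 4 s / 100 Hz.

- **Peaks** are bivariate Gaussians, σ₁ = 4 s (one modulation period) and
  σ₂ = 60 ms, the desk-scale surrogate for modulated peak shapes. Apexes
  are rejection-sampled with an elliptical minimum separation of 6.5 σ so
  the 10%-height contours of neighbors stay disjoint — the generator models
  *resolvable* features; heavy co-elution is exercised separately through
  the region-integration path.
- **Spectra** are random 5–40-stick patterns on m/z 40–350, base peak 999,
  summed linearly where footprints overlap; ion-statistics noise is
  omitted (additive Gaussian noise on the total signal only), the simplest
  model that still separates DMF from RMF behavior.
- **Intensities.** Per-compound target SNR is log-uniform in the configured
  range (default 80–500); true volumes then vary per sample by lognormal
  biological variability (σ_ln = 0.3). Discriminant compounds multiply
  VP1 volumes by 2^(±log2FC) (sign random per compound, default magnitude
  1.5). Two internal standards sit at fixed apexes far from all analytes
  with constant true response. Baseline = 8 × noise_sd offset plus
  N(0, noise_sd) noise.
- **Drift** per sample: ¹t shift quadratic in retention time (max 6 s,
  smooth and monotone) plus a constant ²t offset (max 60 ms) — mimicking
  inter-run retention shifts without modeling thermodynamics. The drift
  field is stored and invertible to sub-pixel accuracy.
- An n-C9…n-C25 alkane ladder with mild retention curvature accompanies
  every study; compound tabulated Iᵀ values are the ladder-consistent true
  indices plus a small jitter within the ±20 gate.

**What passing tests show — and don't.** The synthetic model validates the
pipeline's bookkeeping, thresholds, alignment and statistics against exact
ground truth. It does not emulate real NIST spectra, detector saturation,
tailing/fronting peak shapes, ion-statistics noise, matrix-dependent
extraction efficiency, or heavy co-elution beyond the region-fallback path;
quantitative figures (recall, accuracy) therefore characterize the
implementation under the stated conditions, not expected performance on
instrument data. Study sizes used in the tests (6–48 samples, 30–60
compounds, 240×400 grids) were chosen as the smallest that exercise every
code path with stable statistics.

## Degenerate inputs and tie-breaks

Zero-variance features get F = 0 (0/0 guarded); constant slices get the
noise floor; empty blank tables make blank subtraction the identity;
plateau maxima keep their highest pixel; exact PLS-DA score ties predict
the majority class; features matched to no peak always receive the region
integral (or zero, by option); samples with zero internal-standard response
raise an error naming the sample rather than propagating infinities.
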