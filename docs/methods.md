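# Methods

This note documents the models, numerical choices and limitations behind
each stage of the pipeline, and what the synthetic generators do and do
not emulate.

## Leakage quantification model

An angiogram pair consists of a vessel-reference channel `R` (a
high-molecular-weight intravascular dye: vessels only) and a fluorescein
channel `F` (vessels plus extravasated dye). The analysis assumes:

1. the two channels differ geometrically by a similarity transform
   (same camera and session; only pose and zoom change);
2. photometrically, on vessel pixels `F ≈ g·R + b` for an acquisition gain
   `g > 0` and offset `b`;
3. extravasated dye is additive, nonnegative, and appears only in `F`.

Under these assumptions `max(F − (g·R + b), 0)` on the analyzable region
isolates extravasation, and its mean per analyzable pixel is the per-eye
leakage statistic. Percent inhibition is `100·(1 − leakage/control mean)`;
it is invariant to any common rescaling of both channels because the
normalization absorbs gain.

### Registration

Landmark-based least-squares similarity estimation (Umeyama closed form,
via scikit-image), with the transform family configurable to affine or
rotation-only. Images are resampled bilinearly under the inverse map;
pixels whose source location falls outside the moving frame are carried as
an explicit invalidity mask and excluded from every downstream area
statistic rather than zero-filled, so the per-area leakage is unbiased.
Coordinates are 0-based `(row, col)` with pixel centers at integers. The
RMS landmark residual is the registration QC metric (default threshold
2 px); the condition number of the centred landmark configuration is
reported to flag near-collinear landmark sets.

### Photometric normalization

The gain is fitted only on vessel pixels — the one structure present in
both channels — segmented from the reference by Otsu threshold and eroded
by one pixel so that boundary pixels, which mix vessel signal with
perivascular extravasation, stay out of the fit. A Huber M-estimator
(statsmodels RLM) is used by default; on exactly linear data the fit is
exact.

Two forms are available. The two-parameter fit `F ≈ g·R + b` is the
module-level default and recovers a genuine DC offset exactly. The batch
pipeline defaults to the gain-only form `F ≈ g·R`: vessel interiors are
bright and nearly uniform, so the gain/offset split is poorly conditioned
there, and a mis-attributed intercept extrapolates to the dark background
— exactly where the leakage statistic lives — with large effect. Use
`normalization_offset=True` for acquisitions with a real uncorrected dark
level.

### Resampling-bias control

Two pipeline steps exist purely to keep the pixel-wise subtraction
unbiased; both are configurable:

- **Blur equalization** (`blur_equalize`, default on): the reference is
  passed through the same warp/inverse-warp round trip as the registered
  fluorescein channel, so both images carry identical interpolation blur.
  Subtracting a sharp image from a resampled one otherwise leaves
  clipped-positive residuals concentrated at vessel edges.
- **Common pre-smoothing** (`presmooth_sigma`, default 1 px): the same
  Gaussian applied to both channels after alignment. Because negative
  residuals are clipped at zero (dye cannot be negative), zero-mean pixel
  noise would otherwise rectify into a positive pseudo-leak floor of about
  `σ√(2)/√(2π)` per pixel; smoothing shrinks `σ` before the clip. The leak
  field itself is spatially smooth and essentially unaffected.

With both enabled, the end-to-end pipeline recovers a 70% ground-truth
leak reduction to within ~1–2 percentage points on average over 20
synthetic cohorts at noise σ = 0.01 (see `tests/test_acceptance.py`); the
residual negative bias is the remaining rectified noise floor, which is
inherent to the clipping rule.

### ROI accounting

Exclusions (registration-invalid, optic-nerve disk, outside the
medullary-ray band, manual artifact regions) are attributed disjointly in
that priority order, so analyzable + excluded pixel counts always equal
the frame area. The "per unit area" denominator is all analyzable pixels,
vessels included; after normalization vessel pixels contribute ≈ 0.

## Lesion grading

Mean of the available rater scores (1–4 integer scale), binned
I: [1, 1.5), II: [1.5, 2.5), III: [2.5, 3.5), IV: [3.5, 4]. The half-open
extension of the published decimal bin edges (1–1.4, 1.5–2.4, …) is
conservative: with four integer raters the mean moves in quarter steps and
never falls in a decimal gap, while non-quarter averages from missing
raters remain classifiable. Lesions with missing scores are averaged over
the available raters and flagged, not dropped.

## Ocular pharmacokinetics

Unit conversions are exact arithmetic: a protein of `k` kDa weighs `k` ng
per pmol, so `pmol = ng/kDa`, `amount = conc(ng/ml)·V(ml)/kDa`, and
`dose(pmol) = 1000·µg/kDa`. Rabbit vitreal volume defaults to 1.25 ml.
The reporting helper for "approximately" values rounds percentages to 1
significant figure and molar amounts to 2–3; source reports are not fully
consistent in this convention, so the helper takes the precision as an
argument.

The half-life estimator is OLS of `ln(amount)` on day (log-linear fit):
standard for sparse terminal data, exact on clean exponentials, with a
closed-form 95% CI on `t½` propagated from the slope standard error.
Nonlinear least squares on the raw scale weighs early time points more;
for 2–5 terminal points the log-linear choice is the more stable one. On
the printed day 21–31 terminal series of the hyaluronan-binding Fab it
gives `t½ = 6.09` days with r² = 0.92 — the series is not perfectly
mono-exponential, and no tighter claim is made.

The 4PL standard curve is
`Y = Bottom + (Top−Bottom)/(1 + 10^((LogEC50−X)·HillSlope))`,
`X = log10(conc)`, fitted by Levenberg–Marquardt in log-concentration
space from data-driven starting values (asymptotes from the response
range, LogEC50 from the median log-concentration, Hill sign from the
rank correlation); fitted curves are canonicalized so Top is the upper
asymptote. Inversion is closed-form and only defined strictly between the
asymptotes; out-of-range responses raise rather than extrapolate. The
LLOD is `blank mean + m·SD` (default m = 3, configurable) pushed through
the inverse curve and flagged when it falls outside the fitted standard
range.

## Carrying-capacity arithmetic

`nmol units/eye = conc(µg/ml)·V(ml)/(unit MW Da/1000)`;
`capacity(mg) = sites(nmol)·stoichiometry·drug MW(kDa)/1000`. The human
vitreal volume defaults to 4.0 ml (standard anatomical value) and is
echoed in every report. The hyaluronan binding footprint — disaccharide
units occluded per bound drug molecule — is a required explicit input for
hyaluronan capacity: it is not measurable from concentration data alone,
so no silent default is provided and capacity is reported as a function
of it.

## Synthetic generators

`generate_vessel_scene` emulates the merangiotic rabbit retina: a random
binary branching tree grown from the optic-nerve disk along a horizontal
medullary band, dilated to the vessel width and rendered with a 1 px
Gaussian profile; extravasation as an isotropic blur of the vessel mask
(σ = 6 px) restricted to extravascular pixels and scaled by λ; a known
similarity mis-registration applied to the fluorescein channel; per-pixel
additive Gaussian noise; landmark pairs at vessel bifurcations with
Gaussian picking jitter. Defaults, chosen once as plausible for a 30°
scanning-laser-ophthalmoscope field at 256×256: 6 trunks, 7 px vessel
width, λ = 0.5 for challenged control eyes, noise σ = 0.01, jitter
σ = 0.25 px. Every generator is a pure function of its config including
the seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real angiograms: photorealistic fundus texture and optics
(PSF, flare), frame-averaging artifacts, non-rigid eye motion, intensity
nonuniformity across the field, pathology other than diffuse perivascular
leak, and vessel segmentation difficulty (the reference channel is
near-bimodal by construction; real vessel segmentation is out of scope).
PK series use mean-one lognormal multiplicative noise; rater tables use
additive Gaussian noise rounded half-up and clipped to 1–4.

## Degenerate inputs and tie-breaks

Fewer than 2 landmark pairs, duplicated points, empty analyzable masks,
non-positive amounts in decay fits, constant-response standards and
out-of-range scores all raise descriptive `ValueError`s rather than
propagating NaNs. Grade-bin edges are half-open with the top edge closed
at 4.0. Rounding of synthetic rater scores is half-up. The fold-difference
helper reports plain ratios and deliberately does not reconcile
externally reported round numbers with the ratios of the underlying
table values.

## Problem sizes

Default test and acceptance runs use 256×256 scenes, cohorts of 6 control
+ 6 treated eyes, 20 cohorts for the end-to-end recovery estimate, 200
replicate fits for the decay-recovery property, and 1,000 perturbations
for the registration brute-force optimality check — sizes at which the
stochastic assertions are stable across seeds while the full suite runs
in well under a minute.
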