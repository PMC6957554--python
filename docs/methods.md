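# Methods

`mpus` implements an automated multiparametric ultrasound pipeline for
per-pixel localization of prostate cancer from three co-registered
transrectal modalities of one imaging plane: a 2-minute dynamic
contrast-enhanced ultrasound (DCE-US) cine loop after a microbubble bolus, a
shear-wave elastography (SWE) Young's-modulus map, and a fundamental B-mode
image. This note records the models, the tunable parameters and their
defaults, the numerical choices, and what the bundled simulator does and
does not emulate.

## Motion compensation

The frame nearest 30 s after injection — mid wash-in, when the gland is well
delineated — is the spatial reference. Every 5th frame is rigidly registered
to it (translation ±5 mm, in-plane rotation ±10° about the image center) by
maximizing normalized cross-correlation: a 1° rotation grid with an FFT
translation search at each rotation, then a 0.1° refinement and parabolic
sub-pixel/sub-degree interpolation of the correlation peak. Intermediate
frames get componentwise linearly interpolated `(tx, ty, θ)`; frames outside
the first/last anchor reuse the nearest anchor. Flat (zero-variance) frames
return the identity with a warning. Estimates below one milli-pixel /
milli-degree are snapped to the exact identity so static loops pass through
bit-equal up to interpolation. On smooth speckle with sinusoidal drift
within 3 mm / 8°, the median residual at the anchors is well below 0.5 px
and 0.5°.

## Time-intensity-curve quantification

Per-pixel TICs are baseline-corrected (median of the first 10 s), clipped at
zero, and low-pass filtered at 0.5 Hz (4th-order zero-phase Butterworth) —
bolus kinetics live well below 0.5 Hz. Curves shorter than 20 samples or
60 s are flagged invalid.

The bolus model is a modified local density random walk (LDRW) curve

    C(t) = α √(κ / 2π(t−t0)) · exp(−κ (t−t0−μ)² / 2(t−t0)),   t > t0,

with mean transit time μ (s), dispersion-related κ (1/s), area α (a.u.·s)
and arrival offset t0 (s). The transit-time density integrates to one, so
the curve area equals α exactly — used as an internal consistency check
(fitted α vs. numerical quadrature, within 1 %). Fitting is bounded
trust-region least squares with an analytic Jacobian, moment-based
initialization (t0 ← AT − 1 s, μ ← intensity-weighted mean of t − t0,
α ← trapezoidal area, κ ← μ/variance), relative tolerance 1e-8, at most 500
function evaluations. t0 is free within [0, AT]; a fit ending at a shape
parameter bound is flagged unconverged and the pixel invalidated. Noiseless
refits over α ∈ {50, 100}, μ ∈ {10, 20, 40}, κ ∈ {0.25, 1, 4} recover all
parameters within 1 %; at 20 dB SNR the median error of μ stays within 5 %.

Heuristic bolus descriptors are read off the smoothed curve: PI (peak), PT
(time of first maximum), AT (first crossing of 5 % of PI), WIT (10 %→90 %
rise time on the rising limb). Crossing times are linearly interpolated
between samples. The 5 % / 10–90 % conventions are common DCE-US choices and
are configuration-exposed.

## Dispersion estimators

A ring kernel (defaults 0.5–2.0 mm, thinned deterministically by polar angle
to at most 12 members, at least 8 required) defines each pixel's
neighborhood.

**Spatiotemporal correlation r** — mean zero-lag Pearson correlation between
the center TIC and each ring TIC over the bolus-transit window (AT − 5 s to
AT + 60 s, clipped to the record). Zero-lag is used; r and ρ are invariant
to per-pixel affine intensity scaling.

**Spectral coherence ρ** — mean magnitude-squared coherence (Welch, 32-sample
Hann segments, 50 % overlap, per-segment detrending) averaged over 0–0.5 Hz
and over neighbors. Records must be ≥ 64 samples.

**Local system identification (v, D, Pe)** — the center→neighbor impulse
response is estimated per neighbor by Tikhonov-regularized least-squares
deconvolution over a 20-s causal support, λ = 0.05 · tr(CᵀC)/L. Because the
bolus spectrum decays fast, CᵀC is severely ill-conditioned and the
regularization visibly distorts ĥ; fitting the convection–dispersion
Green's function

    g(t; d, v, D) = d / √(4πDt³) · exp(−(d − v t)² / 4Dt)

directly to ĥ would therefore be biased for any usable λ. Instead the
candidate model is passed through the same resolution operator
S = (CᵀC + λI)⁻¹CᵀC before comparison, which removes the bias exactly in
the noiseless limit. The fit is joint across neighbors over (v, D) with one
shared amplitude nuisance, seeded by a coarse log-spaced (v, D) screen with
the amplitude solved in closed form, refined from the two best distinct
velocity basins. Only neighbors with a resolvable causal delay — estimated
by cross-correlating the raw curves, since the regularized ĥ is too smeared
to localize its peak — enter the fit (delay > half a frame interval): under
directional flow, upstream neighbors lead the center and carry no causal
response. Fewer than four such members, or a solution at the
velocity/dispersion bounds, invalidates the pixel. Pe = v·L/D with L the mean fitted-member distance, an exact identity
of the output. Forward-simulated rings with v ∈ {0.5, 1, 2} mm/s,
D ∈ {0.1, 0.5} mm²/s are inverted within 10 % (v) and 20 % (D).

## Radiomics and calcification detection

Every base map (12 DCE-US parameters + E + G = 14) yields five derivatives:
`rel` (value minus the per-image median of valid in-mask values — difference
rather than ratio, since ratios are undefined for zero or negative medians;
a ratio mode exists for strictly positive maps), `ent1/ent2/ent3` (Shannon
entropy, bits, of the value histogram in circular kernels of 1/2/3 mm;
32 bins fixed per image over the robust 1st–99th percentile range,
out-of-range values clipped into the edge bins; fewer than 10 valid members
invalidates a pixel) and `var2` (unbiased sample variance in a 2-mm kernel;
at least 2 members). Entropy counts are computed exactly via per-bin
indicator convolutions; variance and medians via NaN-aware neighborhood
stacks. A pixel invalid in the base map is invalid in all derivatives. The
census is 14 × 6 = 84 features in a fixed manifest order.

Calcifications are hyperechoic B-mode spots: Gaussian responses at σ = 0.6
and 1.8 mm (matched to ~1.2 and ~3.6 mm diameters) are each thresholded 3
robust SDs (median + 3·1.4826·MAD) above the in-mask median. Robust moments
are essential — the bright spots being sought inflate plain mean/SD past
their own edges. The union is gated by the same robust threshold on the raw
image (the smoothing skirt around a spot passes the response threshold but
not the raw one) and components under 3 px are dropped. On a speckle phantom
with 5× contrast disks this yields ≥ 90 % pixel sensitivity at ≤ 1 %
false-positive area; a featureless image yields an empty mask.

## Zonally stratified random forest

Healthy transition-zone tissue is stiffer and differently perfused than
peripheral-zone tissue, so the classifier's first split is forced to be the
zone. This is realized exactly as two independent forests, one per stratum,
each seeded from (seed, zone): the model is bit-identical to two separately
trained per-zone forests, and a structural check verifies it. Per tree: six
training patients are discarded entirely (drawn per stratum-tree from the
patients present in that stratum), then ⌈N/1000⌉ rows — at least 100 — are
bootstrapped with replacement from the survivors; trees split on
cross-entropy, depth ≤ 50, min leaf 5, ⌈√p⌉ features per split. Two
balancing rules keep the ensemble's prior for an unseen patient neutral,
mirroring the balanced benign/malignant pixel design of the training ROIs:
the per-tree discard is stratified so the surviving patients split as
evenly as possible between benign- and malignant-contributing patients
(random side for the odd survivor), and each bootstrap draws half its rows
per class. Without them, leave-one-patient-out folds in which the held-out
patient's class is underrepresented drift systematically toward the
majority class — measurably inverting null-data cross-validation. Calcified
pixels are excluded from training but scored at inference (they carry a
flag). The multiparametric score is the signed vote ratio
(malignant − benign)/trees ∈ [−1, 1]; a leaf with an exactly tied class
fraction contributes half a vote to each side, which makes the score exactly
anti-symmetric under label swap. Score maps are cleaned by a median filter
over a circular 15-px kernel (≈ 2.5 mm at the default 0.167 mm/px spacing,
roughly half the radius of a clinically significant lesion), valid pixels
only.

## Evaluation

Leave-one-patient-out: each patient is scored by a forest trained on all
others; held-out maps are median-filtered; pixels and per-ROI mean scores
are pooled across folds before computing rank-based (Mann–Whitney, midrank)
ROC-AUCs — pooling matches reporting a single dataset-level AUC; per-fold
diagnostics remain available from the result tables. Single-parameter AUCs
are computed from raw feature values and reported orientation-free
(max(AUC, 1−AUC)), since a parameter that is systematically lower in cancer
discriminates equally well. The Wilcoxon rank-sum test enumerates all
assignments exactly up to n = 12 and otherwise uses a normal approximation
with continuity correction plus an Edgeworth kurtosis term computed from the
exact permutation moments of the midranks — plain mean/variance
approximation is off by up to 0.015 at n = 12, the corrected one by < 0.002.
Significance is flagged at 0.05 and 0.005. The feature correlation matrix is
Pearson with per-entry t-distribution p-values and a mask of entries not
significant at 0.05.

## Synthetic cohorts

The simulator provides ground-truth-bearing cohorts so every stage runs
without clinical data. Each plane: a prostate ellipse with an inner,
upward-shifted transition zone; one lesion per plane, alternating between PZ
and TZ across patients/planes so ROI class and zone provenance stay balanced
(equal-sized ROI disks, fully inside one zone; the malignant ROI sits at the
lesion center, the benign ROI in the opposite zone). Per-pixel TICs follow
the same LDRW family the fitter assumes (a gamma-variate mode exists to
probe model mismatch); bolus arrival propagates from an inflow origin —
drawn randomly inside the TZ per plane, the true inflow not being at a fixed
landmark — at the local velocity, so neighbor TICs are delayed copies: a
deliberately simple, unidirectional transport structure. The base arrival
delay (14 s) keeps the 10-s baseline window strictly pre-arrival, and
benign/malignant ROI placement follows one symmetric margin rule, so a null
cohort carries no positional label information. SWE is tissue mean plus smooth
and pixel noise; B-mode is gamma speckle on tissue echogenicity with bright
calcification disks (which also stiffen the SWE map); optional sinusoidal
rigid drift (zero at the 30-s reference) moves the DCE loop.

Default tissue parameters (benign PZ / benign TZ / lesion): μ = 25/22/18.5 s,
κ = 0.5/0.6/0.8 s⁻¹, α = 60/80/90 a.u.·s, v = 0.8/1.0/1.4 mm/s,
D = 0.20/0.25/0.28 mm²/s, E = 25/45/55 kPa. Lesion offsets are applied
relative to the host zone and scaled by `malignant_effect_scale` (0 gives a
null cohort with uninformative labels, including the B-mode echogenicity).
Between-patient biology is emulated by independent per-parameter lognormal
patient multipliers (SD 0.10), lognormal per-patient effect-size multipliers
(SD 0.5, independent across parameters — some tumors barely differ in any
one parameter), an additive SWE offset (SD 8 kPa) and a B-mode gain factor
(SD 0.10). These variabilities are calibrated so that each single parameter
discriminates only partially at the region level while the multiparametric
combination reaches a high AUC — the regime in which a multiparametric
classifier is worthwhile, and the package's central qualitative claim. The
simulator does not attempt acoustic wave propagation, realistic speckle
physics, attenuation/shadowing, recirculation, elastic deformation, or
histology synthesis; passing end-to-end tests therefore demonstrates
correctness and internal consistency of the pipeline, not clinical
performance.

## Problem sizes

The full-scale simulator defaults are 144×192 px at 0.167 mm/px, three
planes per patient, 5 Hz for 120 s. The bundled demonstrations, the test
suite and the acceptance script use the reduced profile
`SimConfig.small()` — 72×96 px, one plane per patient, 2 Hz for 96 s,
prostate semi-axes 0.36/0.38 of the grid — with 12 patients, which keeps a
full double-cohort (effect + null) extraction-plus-cross-validation run in
the ten-minute range while preserving every structural property of the
full-scale setting (the mm-specified kernels resolve to the same pixel
sizes; the 15-px median kernel is large relative to these small synthetic
lesions, which post-filtering must and does survive).

## Known limitations

* At desk scale the cohort is small: 12 patients give 24 pooled regions, so
  the *best* single-feature AUC is a maximum over 84 noisy estimates and on
  some cohort seeds a strongly expressed parameter saturates at 1.0. The
  multiparametric-beats-single comparison is therefore meaningful in
  expectation and at the documented study seed, not guaranteed for every
  cohort realization.

* The convection–dispersion inversion assumes isotropic radial transport;
  under the simulator's unidirectional flow only the causal half-ring
  informs the fit, and (v, D) maps on such planes are noisy, weakly
  informative features — the forest weights them accordingly.
* The per-image entropy binning makes entropy comparable across pixels of
  one plane but not across planes with very different value ranges.
* Coherence from ~11 Welch segments carries a finite-sample positive bias
  (mean ≈ 0.1–0.3 under independence); it is used comparatively, never as an
  absolute dispersion measure.
* Model persistence uses joblib and is version-bound to the training
  scikit-learn.
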