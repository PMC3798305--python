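# Methods

This note documents the models and numerical choices behind `vastex`: the
texture features, the synthetic speckle cohort that stands in for animal
data, the screening and classification procedure, and what the shipped
tests do and do not establish.

## Texture features

All features operate on a `GrayImage`: a 2-D grid of integers in
`[0, L−1]`, row-major, 0-based, with ROIs as half-open rectangles. ROI-level
feature vectors are the arithmetic mean of per-frame vectors (frames of one
ROI are repeated acquisitions of the same site).

**Quantization.** Co-occurrence-type statistics at L = 256 are sparse and
noisy on 64×128 ROIs, so SGLDM, GLDS and NGTDM default to 64 gray levels
(`floor(p·64/256)`); FOS, FDTA and SFM use the image as given. The levels
are configurable per family (`FeatureConfig`).

**FOS.** `AGL = Σ i·p_i`, `SD = sqrt(Σ (i−AGL)²·p_i)` over the gray
histogram — identical to the per-pixel mean and population SD.

**FDTA.** For a fractional-Brownian intensity surface,
`E|I(p) − I(q)| ∝ r^H` with `r = ‖p − q‖`. The estimator computes the mean
absolute difference over all horizontal and vertical pixel pairs at exact
integer distances `r = 1..8` (fewer on small images; at least two distances
are required, otherwise a validation error is raised) and takes the
least-squares slope of `log E|ΔI|` vs `log r`. The fractal dimension is
`D_f = 3 − H` at full resolution, clipped to the admissible surface range
[2, 3]; block-averaged resolutions w = 2, 3 give diagnostic `H(w)` values
only, since there is no canonical way to combine them into one dimension.
Distances with a zero mean difference are dropped; a constant image is
treated as the smooth limit (H = 1, D_f = 2).

**SGLDM.** Symmetric co-occurrence matrices (each ordered pair counted in
both the +θ and −θ directions) at d = 1 for θ ∈ {0°, 45°, 90°, 135°}
(counterclockwise, y up). Per angle: contrast `Σ (i−j)²·P`, correlation
`(Σ i·j·P − μxμy)/(σxσy)` with the moments taken from the marginal
distributions, energy `Σ P²`, homogeneity `Σ P/(1+|i−j|)`, entropy
`−Σ P·log10 P`. Each measure is collapsed to the unweighted mean over the
four angles. A constant image leaves the correlation undefined; it is
returned as 0 with a warning.

**GLDS.** For each displacement γ ∈ {(0,3), (3,3), (3,0), (3,−3)} (written
(Δx, Δy)), the probability vector `f(i)` of `|I(x,y) − I(x+Δx, y+Δy)|`
yields contrast `Σ i²f(i)`, angular second moment `Σ f(i)²`, entropy
`−Σ f·log10 f` and the L-normalized mean `(1/L)·Σ i·f(i)`; values are
averaged over the four displacements.

**NGTDM** (d = 2). For each interior pixel (margin d) the average of the
24 surrounding pixels (center excluded) is subtracted; `s(i)` accumulates
absolute deviations per gray level, `p_i` is the occurrence fraction among
the `(H−2d)(W−2d)` interior pixels. Coarseness `1/(ε + Σ p_i s_i)` with
ε = 1e−8; contrast, busyness, complexity and strength follow the standard
perceptual definitions with all pairwise sums restricted to levels actually
present (`p > 0`) — this makes a constant image yield exactly
CON2 = BUS = COM = STR = 0 (flagged degenerate) and coarseness saturate at
1/ε.

**SFM.** Per lag δ ∈ {(1,0), (0,1), (1,1), (1,−1)}: contrast
`E[(I(p) − I(p+δ))²]` and the Pearson correlation of the two aligned pixel
sets. The reported values are `CON3 = mean_δ sqrt(contrast(δ)) / SD(image)`
(dimensionless) and `COV = mean_δ correlation(δ)`. Zero image variance sets
the degenerate flag.

All entropies use log10: at 64 levels this puts the SGLDM entropy in the
~1–2.5 range and the GLDS entropy near 1, the magnitudes conventional for
these features. Every vectorized implementation is verified against an
independent double-loop reference to 1e−9 on random images, and the
co-occurrence counting against `skimage.feature.graycomatrix`.

## Fractional Brownian synthesis

Interface profiles (1-D) and test surfaces (2-D) are synthesized by Fourier
filtering of white Gaussian noise with power spectra `f^−(2H+1)` and
`f^−(2H+2)`. Two refinements matter at pixel scale: the spectrum is
**alias-folded** (replicas at ±1, ±2 sampling frequencies summed back in),
restoring the sub-Nyquist power a truncated filter discards — without this
the lattice structure function is too smooth at r = 1–2 and Hurst estimates
are biased upward by ~0.12 at H = 0.3 — and fields are synthesized on a
doubled domain and cropped to weaken FFT periodicity. With both, the
estimator above recovers H ∈ {0.3, 0.5, 0.7} on 64×64 8-bit surfaces with a
mean absolute error under 0.05 (tested at ≤ 0.1).

## Synthetic cohort

Each ROI frame is built as: (1) a wall–lumen interface row per column,
drawn once per ROI as fBm with exponent `rough_hurst` scaled to SD
`rough_amp` pixels around 10% of the ROI height; (2) a two-band template —
wall 1.0 below the interface, lumen 0.70 above; (3) a smooth multiplicative
gain field `1 + heterogeneity·g` (unit-variance Gaussian noise smoothed at
~1/3 of the ROI size, drawn per ROI); (4) multiplicative speckle
`1 + speckle_scale·(E/mean(E) − 1)` where E is a Rayleigh envelope smoothed
by an anisotropic Gaussian PSF `(σ_ax, σ_lat)`, drawn per frame; (5) an
affine rescale so the wall-band mean hits `mean_echo` plus the subject's
Gaussian offset (SD `subject_sd` = 11 gray levels), then clipping to
[0, 255] and rounding. The speckle amplitude is a unit-mean modulation
weight rather than a raw Rayleigh scale because the wall-mean rescale would
cancel any pure scale factor.

Subjects additionally receive log-normal factors (relative SD
`texture_jitter` = 0.25) on the five texture amplitudes/scales and a small
perturbation of the interface Hurst exponent. This emulates
animal-to-animal texture variability; without it the within-class variance
of per-subject feature means collapses to frame-sampling noise and *every*
feature becomes FDR-significant at n = 15 vs 28, which no real cohort
shows.

The default layout mirrors the emulated study design: 15 normal and 28
abnormal subjects, 3 ROIs per subject plus 4 extra abnormal ROIs assigned
round-robin (45 + 88 = 133 ROIs), 100 frames per ROI, 64×128-pixel ROIs.
The first ROI of every subject trains the classifiers (43 train / 90 test),
so a subject's remaining ROIs are evaluated with that subject seen in
training — this mirrors the emulated design and inflates absolute accuracy;
a leakage-free `split_by="subject"` mode is provided.

**Class parameters** were calibrated once, against the directional contract
in `check_calibration`, and shipped as defaults:

| parameter | normal | abnormal | effect |
|---|---|---|---|
| mean_echo | 202 | 143 | wall brightness (AGL ≈ 199 vs 137 after lumen mix) |
| speckle_scale | 0.25 | 0.72 | speckle contrast → SD, GLCM contrast, energy |
| psf σ_ax × σ_lat | 0.70 × 1.00 | 0.95 × 1.30 | speckle grain → covariance, coarseness |
| rough_amp (px) | 0.5 | 5.0 | interface roughness → edge contrast |
| rough_hurst | 0.70 | 0.30 | interface jaggedness |
| heterogeneity | 0.04 | 0.16 | low-frequency gain → SD, entropy, complexity |

The contract requires the class-mean AGL inside [185, 210] (normal) and
[120, 155] (abnormal) and the sign of (normal − abnormal) to match the
diseased-wall signature for the 11 separating features: AGL +, SD −, GLCM
contrast −, energy +, entropy −, GLDS ASM +, coarseness −, busyness +,
complexity −, strength −, covariance −. These hold across seeds with the
shipped defaults.

**Model properties worth knowing.** GLCM contrast and NGTDM contrast rise
monotonically with `rough_amp` and GLCM energy falls (tested over five
amplitudes). NGTDM *strength* instead falls with roughness: its denominator
`Σ s(i)` grows linearly with local deviations while its numerator (a
histogram-spread term) barely responds; the between-class strength contrast
(abnormal higher) is driven by histogram spread, not the interface. The
cohort-level fractal dimension sits near 2.6–2.8 rather than ~2.0: with a
speckle correlation length of 1–2 pixels, `E|ΔI|` saturates within a few
pixels and the r = 1..8 slope is necessarily small; recovering H near 1
over that range would require variance growth far beyond the frames' total
SD, so D_f is validated on true fBm surfaces instead of on the cohort.

## Screening, classification, evaluation

Screening operates on per-subject feature means (the subject is the unit of
replication; n = 15 vs 28), using a pooled-variance Student's t-test and
Benjamini–Hochberg step-up at q = 0.05 across all 19 p-values
(`statsmodels` implementation, verified against the step-up rule and null
permutations). Flags on per-ROI values or the training split only are
available. The selected ("optimal") subset keeps the fixed report order.

Both classifiers consume z-scores computed from the training split only
(feature scales span ~1e−2 to ~1e4, which would otherwise dominate
distances); zero-variance features are dropped with a warning. The SVM is
`sklearn.svm.SVC` with penalty C = 1.0 and an RBF kernel whose bandwidth
follows the median-pairwise-distance heuristic `γ = 1/(2m²)` (a linear
kernel is available). The KNN is implemented directly: Euclidean distances,
stable sort so distance ties resolve by training index, k = 5 (odd k makes
vote ties impossible; even k defers to the nearest neighbor), and the
abnormal vote fraction as a graded score for ROC.

Evaluation treats abnormal as positive. ROC curves sweep the unique scores
in descending order with equal scores grouped into single steps, from
(0, 0) to (1, 1); AUROC is the trapezoidal area and equals the
tie-corrected Mann–Whitney `U/(n₁n₂)` exactly (tested to 1e−12). The
evaluation grid covers 7 feature selections × 2 classifiers.

## Reproducibility and problem sizes

A single integer seed determines every artifact: the cohort seed feeds a
`SeedSequence` tree (subject → ROI → frame), classifiers are deterministic,
and all stage outputs are plain CSV, so a rerun at the same seed is
byte-identical. The default problem sizes — 13,300 synthetic frames
featurized in ~25 s, fBm recovery at 30 surfaces, 200 null permutations —
were chosen to keep a full run around one minute on a single CPU while
leaving the statistical checks comfortably powered.

## Limitations

- The generator models envelope statistics only (no RF phase, attenuation,
  shadowing, motion, or curvilinear geometry); passing tests show the
  pipeline's statistical machinery works, not that it transfers to scanner
  data with different gain or dynamic-range settings.
- Synthetic class separation is stronger than in real cohorts; absolute
  accuracies near 1.0 reflect the calibrated contrast plus the ROI-level
  split, and only orderings between feature sets should be interpreted.
- The SVM kernel and penalty for the emulated study are unknown; the RBF +
  median-heuristic default is a reasonable convention, not a reconstruction.
- The ROC for a hard-voting KNN requires a graded score; the vote fraction
  used here yields at most k + 1 distinct thresholds.
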