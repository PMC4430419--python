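# Methods

## Scope and data model

`mitomorph` analyzes single-channel fluorescence stacks of
mitochondrially-targeted GFP in *C. elegans* body-wall muscle, plus the
tabular readouts of companion assays (qPCR Ct values, O₂ traces, HPLC
peak areas). The in-memory containers are thin dataclasses around numpy
arrays (`ImageStack`, `ProjectedImage`, `LabeledObjects`) and pandas
DataFrames for all tables. Coordinates are row-major, 0-based, with
pixel-center geometry; the default lateral pixel size is 0.2 µm.

## Segmentation pipeline

Stages, in order, with defaults in parentheses:

1. **Slice triage** — the per-slice quality statistic is the
   pixel-intensity variance in squared native gray units; slices with
   variance ≤ 1.0 are discarded. The statistic's exact formula in the
   original ImageJ implementation is not recoverable (the plugin is no
   longer hosted); plain variance is this package's interpretation, is
   logged per slice, and the threshold is configurable. Rejecting every
   slice raises `EmptyTriageError` rather than returning an empty stack.
2. **Maximum-intensity projection** over the retained slices.
3. **Rolling-ball background subtraction** (radius 15 px), via
   `skimage.restoration.rolling_ball`; output is clipped at 0 and is
   everywhere ≤ the input. A radius exceeding the image degenerates to
   subtracting the global minimum, with a warning.
4. **Local contrast enhancement** — CLAHE over 15-px tiles. The clip
   limit uses the ImageJ slope convention (default 3.0) and is mapped to
   the underlying normalized clip fraction (slope/256). Oversized blocks
   fall back to global histogram equalization.
5. **Multi-scale Laplacian enhancement** — pixel-wise maximum over
   scales {1, 2, 4} px of the scale-normalized negative LoG response
   −s²·∇²G_s, clipped at 0. The operator is applied to the
   mean-subtracted image so a constant image yields an exactly zero
   response despite kernel truncation.
6. **Yen autothresholding** on a 256-bin histogram of the response. The
   criterion TC(t) = 2 ln(P₁P₂) − ln(G₁G₂) (class masses P, squared
   probability masses G) is evaluated for every split; ties break toward
   the lowest maximizing threshold; the mask is `image > threshold`.
   Whether Yen binarizes the Laplacian response or the contrast-enhanced
   image is ambiguous in the original description; the response is the
   default, with a `threshold_on="enhanced"` switch.
7. **Noise floor** — on a structure-free image Yen still returns a split
   inside the noise distribution, which would label noise clumps as
   mitochondria. The pipeline therefore requires the Yen threshold to
   exceed median + 2.5·(1.4826·MAD) of the response; otherwise the image
   is declared empty. The constant 2.5 sits in the middle of the gap
   measured on the generators (signal-free images reach robust-z ≈ 1.9,
   real structures at SNR 5 start at ≈ 3.1); it applies only in the
   response-thresholding mode it was calibrated for, and can be disabled.
8. **Object extraction** — 8-connected components strictly larger than
   12 px (a 12-px component is removed), relabeled 1..n in scan order.

The unenhanced projection is carried through so intensity and texture are
measured on original gray values, never on enhanced intermediates.

## Shape and texture descriptors

Per object: Mean gray (original image), Area (px and µm²), AR, Feret,
Solidity, Circularity, Roundness. The ellipse is fitted from second-order
central moments and both axes are rescaled by a common factor so the
ellipse area matches the pixel area (the ImageJ "Fit Ellipse"
convention); Roundness = 4A/(π·major²) then reduces to minor/major and is
bounded by 1. Circularity is capped at 1.0. The perimeter uses the
4-direction Crofton estimator: boundary-step counting (straight 1,
diagonal √2) overestimates smooth digital contours by ~5% and the bias
grows with size (disk r=20 circularity 0.946, r=40 0.929), while Crofton
stays within ~1% — an accuracy-driven choice this package makes
deliberately. Feret is the exact maximum pairwise distance between
boundary-pixel centers (convex-hull pruned, equal to the O(n²) maximum).
Degenerate objects (single pixel, zero minor axis) get flagged
conventional values rather than NaNs.

Texture: the GLCM is counted over ordered pixel pairs at a one-pixel
offset (asymmetric by default; the original description averages two
directions but does not state symmetry), with linear quantization of the
full bit-depth range into 256 levels for 8-bit and 64 otherwise (the
original plugin's level count is unstated; it is exposed as config).
Entropy uses natural logs with 0·ln 0 ≡ 0. The printed correlation
formula in the source description contains an apparent typo
((i−μᵢ)(i−μⱼ)); the standard Haralick correlation (i−μᵢ)(j−μⱼ)/√(σᵢ²σⱼ²)
is implemented. Correlation is NaN (flagged, not zero) when a marginal
variance vanishes. Per-image records average object metrics with equal
weights ("average values" semantics; area-weighting is behind a flag) and
average texture over the (0,1) and (1,0) offsets.

## Clustering and condition comparison

Features are z-scored column-wise (sample SD, ddof=1); constant columns
raise an error naming the column. The clustergram applies UPGMA (average
linkage, Euclidean distance) to rows and columns via
`scipy.cluster.hierarchy`; merge heights are mean inter-cluster
distances, leaf orders come from the standard recursive ordering, and
trees export to Newick with branch lengths from merge heights. Whether
the original figure clustered per-image rows or per-condition means is
unstated; the CLI defaults to condition means with a `--per-image`
switch. k-means (Lloyd, best of 10 seeded restarts) defaults to k = 3:
two drug classes plus control. Metric-wise comparisons gate on
Shapiro-Wilk normality at α = 0.05 per group (groups of n < 3 cannot be
tested and are not rejected): both normal → Welch t-test (the
unequal-variance test used in the original figure legends), otherwise
two-sided Wilcoxon rank-sum. No multiple-testing correction by default
(per-metric significance stars were reported uncorrected); Holm is
available behind a flag.

## qPCR quantification

The standard curve is OLS of Ct on log₁₀(copies) over a 7-point tenfold
plasmid dilution series. Absolute quantification inverts the mean Ct
through the curve and scales by the lysis design: ×40 dilution,
lysate/2 µl template, ÷5 worms per lysate. The lysate volume is not a
published constant and is a required user input — absolute copies per
worm are only defined relative to it. Relative quantification computes
the log₁₀ ratio (ΔCt/slope) against the unexposed reference; its CI
pools the replicate Ct dispersion of both groups (t quantile at
df = n₁+n₂−2, matching the published df = 16 for a 9+9 design) and
back-transforms to the percent scale. How the original 95% CIs were
derived from "linear regression" is ambiguous; this pooled prediction
approach is a documented choice, verified by Monte-Carlo coverage
(≈95/100 at σ_Ct = 0.2, n = 9). The pooled-variance t-test follows the
textbook formula the printed (typo-ridden) equation uniquely determines;
the F-test is two-sided with the larger variance in the numerator.

## Respiration and redox

The O₂ consumption rate is the negative slope of the straight portion of
the trace, normalized to protein. "Straight portion" is operationalized
as: among all contiguous windows covering ≥ 50% of the trace, pick the
highest-R² window with R² ≥ 0.99, breaking ties toward longer (then
earlier) windows — an exact line therefore selects the full trace, while
an equilibration transient is excluded; if nothing qualifies the full
trace is used with a warning. Prefix sums make each window fit O(1).
Quinone redox state is 100·reduced/(reduced+oxidized) on pre-integrated
HPLC peak areas; peak detection itself is out of scope.

## Synthetic data generators

Goal: every downstream stage testable with exact ground truth, since no
imaging data is deposited.

* **Network stacks.** Tubular and control phenotypes are persistent
  random walks (heading noise sd 0.8·(1−persistence) per unit step)
  dilated to a 3-px tubule width; control walks share a common mean
  heading (semi-aligned network) and intermediate lengths (mean 28 px vs
  75 px tubular); fragmented networks are mildly eccentric ellipses of
  radius ≈ 4 px. Structures land on one of 3 in-focus slices; the
  ground-truth mask is their union and ground-truth objects are its
  connected components (touching structures merge, exactly as a
  segmenter sees them). Rendering applies a 1-px Gaussian PSF; noise
  splits the budget between Poisson shot noise and Gaussian read noise
  so that the peak-signal-to-noise ratio equals `snr` (default 10;
  recovery experiments use 5). Two defocused slices (heavy blur toward
  the background with 20× attenuation) flank the focus band so triage
  has something to reject; their variance lands far below the QC
  threshold by construction. Intensities are 8-bit, background 20,
  peak 220, image 256², pixel 0.2 µm. Structure counts (12–26 per image)
  are free parameters chosen to give realistically crowded but resolvable
  networks; the original study reports only "at least 10 worms" per
  condition.
* **Feature tables** add per-class mean shifts and iid Gaussian noise to
  baseline metric values — the fixture for clustering tests.
* **Ct tables** draw replicates from the log-linear curve plus
  N(0, σ_Ct); **O₂ traces** are lines plus noise with an optional
  exponential equilibration bump over the initial fraction.

What the generators do *not* emulate: 3-D network topology, anisotropic
PSFs, photobleaching, autofluorescence, reflections, motion, or
between-animal variability. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated noise model, not
performance on real micrographs.

## Problem sizes and determinism

The standard validation experiment is 10 images per phenotype at SNR 5
(object-detection F1 ≥ 0.9 per phenotype, k-means ARI against the
generating classes, clustergram top-split separation); test calibration
uses 10,000 null replicates; CI coverage uses 100 simulated experiments.
All randomness flows through explicitly seeded `numpy.random.Generator`
instances — same seed, bit-identical output — and `scripts/acceptance.py`
derives every sub-seed from its `--seed` argument.

## Known limitations

* The pipeline is 2-D by design (projections), so overlapping structures
  merge; ground truth adopts the same convention.
* Exact ImageJ bit-reproduction of rolling-ball and CLAHE is not
  promised; those stages are validated by properties (bounds, shift
  invariance, separation) rather than pixel identity.
* The noise-floor constant was calibrated on these generators; images
  with strongly non-Gaussian backgrounds may need `noise_floor_z`
  adjusted or disabled.
* Amplification efficiency is assumed log-linear (no efficiency
  correction or ΔΔCt variants); chromatogram peak integration and MIC /
  husbandry protocols are out of scope.
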