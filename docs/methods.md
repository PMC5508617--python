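# Methods

## Problem and scope

`livertex` implements a 2-D region-of-interest (ROI) texture-analysis
pipeline of the kind used to discriminate focal liver lesions — hepatic
hemangioma, hepatic metastasis and hepatocellular carcinoma — on
fat-suppressed T2-weighted MRI slices.  The unit of analysis is one image
slice with a binary lesion mask; everything outside the mask is ignored by
every feature.  Because no patient cohort ships with the package, a
synthetic phantom generator reproduces the *statistical shape* of such a
study (three texture-distinct classes, a 162-subject cohort split
112 training / 50 validation, 15 paired test-retest acquisitions) so that
every downstream stage is exercised end to end.

## Preprocessing

1. **Adaptive Wiener denoising** of the full slice: local mean `m` and
   variance `v` over a `w × w` window (default 3×3), noise power `ν` =
   mean of the local variances, output `m + max(v−ν,0)/v · (I−m)`.  Local
   statistics use *reflected* boundaries so that a constant image is a
   fixed point of the filter; the mask is untouched.  The filter runs on
   the whole slice before masking (configurable off).
2. **Gray-level discretization** (fixed bin number): with min/max taken
   over in-mask pixels only,

       level(x) = floor( Range · (I(x) − min) / (max − min + 1) ) + 1

   for Range ∈ {16, 32, 64, 128}, default **32**.  The bracket is read as
   floor (the only reading that keeps levels integral), and the +1 shift
   puts levels in 1..Range because the run-length and size-zone
   low-gray-level emphases divide by the squared level — a level of 0
   would be undefined.  The mapping is monotone in intensity and invariant
   under affine intensity rescaling up to floor-boundary ties; a constant
   ROI maps to level 1.

## Texture matrices and features (233 per ROI)

See `docs/formulas.md` for every formula.  Family breakdown: 3 IHF +
80 GLCM + 15 GLGCM + 44 GLRLM + 80 GWTF + 11 ISZM = 233, of which the
142 IHF/GLCM/GLGCM/GLRLM features describe local gray-level variation.

* **GLCM** — ordered in-mask pixel pairs at distance d ∈ {1,2,4,8} and
  direction θ ∈ {0°,45°,90°,135°} (0° = +column axis, 90° = image "up";
  diagonal steps are unit Chebyshev steps).  The transpose is added, which
  is exactly equivalent to also scanning the four opposite directions, and
  the matrix normalized.  Ten Haralick statistics per matrix are
  aggregated as mean and *population* variance (divisor 4) over the four
  directions at each distance.
* **GLGCM** — per-pixel joint histogram of gray level and Sobel gradient
  magnitude.  The gradient is computed on the denoised (unquantized)
  intensities with out-of-mask neighbors replicated from the nearest
  in-mask pixel, then discretized to 16 gradient levels by the same floor
  min-max rule.  Sobel and G = 16 are conventional choices (neither is
  forced by the method definition); G = 16 keeps the matrix well populated
  for small ROIs.  Note the gradient scale is *per-ROI relative*: features
  describe how gradient mass distributes over the ROI's own gradient
  range, not absolute edge strength.
* **GLRLM** — maximal same-level runs along each of the four directions;
  runs are truncated at mask boundaries (a run never spans an out-of-mask
  pixel).  The eleven descriptors are emitted separately per direction.
* **ISZM** — connected iso-level zones (8-connected by default, matching
  the 8-connexity used for GLCM; 4-connectivity selectable), counted by
  level and size.
* **GWTF** — a 5-scale × 8-orientation complex Gabor bank, center
  frequencies geometrically spaced from 0.4 cycles/pixel (scale 0) down to
  0.05 (scale 4), orientation μπ/8, isotropic envelope σ = 0.56/f
  (≈ one octave), truncated at 3σ, mean-subtracted so every kernel is
  DC-free.  The ROI bounding-box patch (out-of-mask pixels replaced by the
  in-mask mean; zero-fill selectable) is padded with the same fill value
  by each kernel's half-width before FFT convolution — this boundary
  convention makes a constant image yield numerically zero response, which
  zero-padded convolution would violate at the patch edge, and it also
  handles ROIs smaller than a kernel's support (with a logged warning that
  low-frequency responses are then fill-dominated).  Gabor features are
  computed on raw (denoised) intensities: discretization is motivated only
  by the counting matrices.
* **Degenerate inputs** (e.g. a constant ROI) produce documented limit
  values (Energy 1, entropies 0, Contrast 0, Correlation 0, Homogeneity 1,
  variances 0) rather than errors, so cohort feature tables stay complete.

## Synthetic phantoms

Each phantom is a 256×256 slice holding one elliptical lesion (radii
8–30 px) on a background at half the dimmest class's base intensity.
In-ROI texture is the sum of: the class base intensity; a Gaussian random
field smoothed with `blur_sigma` and scaled to `intensity_sd` (local
heterogeneity → GLCM/GLRLM); a Voronoi blob field with mean cell diameter
`blob_scale` and i.i.d. per-cell offsets of the same amplitude (regional
zone structure → ISZM); an optional linear ramp `gradient_slope`
(gradient structure → GLGCM); and i.i.d. pixel noise (`noise_sd`,
default 5).  Pixels are rounded to integers, making generation
bit-deterministic across platforms and PNG round trips exact.

The three default classes are deliberately strongly texture-distinct
(A: bright, nearly homogeneous, hemangioma-like, base 180/sd 8/blur 2.5;
B: base 140/sd 25/blur 1/blobs 4 px/ramp 0.6; C: coarse, base 140 lowered
to 120/sd 40/blobs 10 px/ramp 1.5).  No quantitative inter-class effect
size is available from real cohorts, so these amplitudes are free design
parameters chosen once to represent a clearly separable study; a
`null_class_params()` preset provides the matched no-signal control.
Consequently, passing tests demonstrate that the pipeline *recovers
planted structure and stays calibrated under the null* — not that any
particular accuracy is attainable on clinical images.  The phantoms have
no MR physics: no bias fields, partial-volume effects, fat signal or
acquisition-dependent intensity scales.

Randomness: one root `SeedSequence` per cohort with per-subject spawned
sub-streams, so enlarging a cohort never perturbs earlier subjects;
test-retest replicates share their subject's geometry/texture stream and
differ only in the noise stream (`retest_noise_sd`).

## Feature selection

* **CCC** — Lin's concordance correlation coefficient between test and
  retest values (population moments), threshold 0.9.  Two constant
  sequences return 0 (no concordance information).
* **DR** — dynamic range, `1 − mean|test−retest| / (overall max − min)`,
  clipped to [0,1], threshold 0.9.  The ratio-of-ranges definition follows
  the reproducibility literature the metric comes from.
* **Redundancy pruning** — survivors are ranked by DR (descending) and
  accepted greedily iff their pairwise Pearson R² with every
  already-accepted feature stays below 0.95.  The threshold and the
  DR-based ordering are recorded in the `SelectionReport`; the procedure
  is deterministic given its inputs.  Constant-on-cohort features are
  treated as fully redundant.

Survivor counts are data-dependent outputs, not targets.  An empty
survivor set is a legal result and is reported, not raised.

## Statistical analysis and classifiers

Class discrimination is posed as three one-vs-one tasks.  Per task:

* **Screening** — Kruskal-Wallis rank test per feature (tie-corrected H,
  χ² p-value); significance is flagged at raw p < 0.05, the convention of
  this study design, with Benjamini-Hochberg adjusted p-values reported
  alongside for the cautious reader.
* **ROC** — AUC by the rank (Mann-Whitney) formulation; the operating
  point maximizes Youden's J with the cut-off placed midway between
  adjacent observed scores; SE and 95% CI by Hanley-McNeil.
* **Classifiers** — KNN (k = 5, Euclidean), a one-hidden-layer
  back-propagation neural network (logistic activations; hidden units
  from {3, 5, 10} by inner CV; L-BFGS optimization, deterministic given
  the seed), C-SVM with RBF kernel (C ∈ {0.1,1,10} × γ ∈ {0.01,0.1,1} by
  inner CV), and unpenalized maximum-likelihood logistic regression.
  Hyperparameters are chosen by stratified 10-fold CV on the training
  cohort; the tuned model is refit on the full training cohort and scored
  on the held-out validation cohort (Acc, Sens, Spec, Matthews correlation
  coefficient, AUC).  Features are z-scored with training-fitted
  statistics inside every fit, so no validation information leaks.
* **Stability** — B = 100 bootstrap rounds (B is a package choice): each
  round makes a stratified random half-split of the training cohort,
  trains on one half and computes AUC on the other; the relative standard
  deviation RSD = σ/μ × 100 of the AUC sample (sample standard deviation,
  ddof = 1) is the stability score, with median ± std also reported.
  Degenerate splits are skipped and logged; ≥ 90% of rounds must succeed.

## Problem sizes used by the test suite and acceptance script

The bundled study runs at the full cohort geometry (55/67/40 subjects →
112/50 split, 15 retest pairs, 233 features, B = 100).  The no-signal
control is run at a reduced geometry (20 cohorts of 12/12/12 subjects on
128×128 slices, logistic classifier) — under the null a single
small-validation AUC is binomially noisy with SD ≈ 0.12, so the
across-seed mean carries the calibration statement.  Null-calibration
checks use 10⁴ label permutations (Kruskal-Wallis rejection rate) and
n = 2000 scores (permuted-label AUC).  The discretization-sensitivity
experiment compares feature values at Range 16 vs 128 on 20 phantoms:
regional ISZM low-intensity/large-zone features shift significantly more
than the local GLCM/GLRLM statistics (paired Wilcoxon), the qualitative
signature expected of zone-based features under coarser binning.

## Known limitations

* 2-D single-slice analysis only; no 3-D matrices or inter-slice offsets.
* Phantoms carry no MR acquisition physics; absolute feature values are
  not comparable to scanner data.
* The GLGCM gradient scale is per-ROI relative (see above), so
  gradient-emphasis features compare distributions, not absolute edge
  strengths, across subjects.
* Survivor counts and significant-feature counts depend strongly on the
  synthetic effect sizes; only their qualitative behavior (reproducible
  features kept, planted noise removed, null calibrated) is claimed.
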