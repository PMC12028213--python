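# Methods

This note documents the models, numerical choices and limitations of
`robustrad`, in the order the pipeline runs them.

## Phantom cohort

Each synthetic patient carries one ellipsoidal lesion (axis radii drawn
uniformly from 5–8 mm, i.e. diameter ≥ 1 cm) centered near the middle of
a 64×64×32 voxel grid at 1×1×3 mm spacing — a deliberately reduced
matrix chosen for desk-scale runtime; lesions keep a 2-voxel margin from
the grid border so all ROI perturbations stay in bounds. The default
cohort is 15 pleomorphic adenomas, 10 Warthin tumors and 18 malignant
lesions (18 malignant vs 25 benign).

Per-lesion kinetic and diffusion parameters are drawn from class
Gaussians (resampled until all invariants hold — volume fractions in
[0, 1], v_e + v_p ≤ 1, D* > D, geometry within margin; an error is
raised after 100 failed draws):

| parameter | adenoma | Warthin | malignant |
| --- | --- | --- | --- |
| K^trans (min⁻¹) | 0.08 ± 0.02 | 0.50 ± 0.08 | 0.22 ± 0.08 |
| v_e | 0.35 ± 0.05 | 0.12 ± 0.03 | 0.22 ± 0.06 |
| v_p | 0.02 ± 0.008 | 0.04 ± 0.012 | 0.03 ± 0.012 |
| D (mm²/s) | 1.6e−3 ± 1.2e−4 | 0.85e−3 ± 0.8e−4 | 0.95e−3 ± 1.0e−4 |
| D* (mm²/s) | 9e−3 ± 2e−3 | 14e−3 ± 3e−3 | 11e−3 ± 3e−3 |
| f | 0.08 ± 0.02 | 0.25 ± 0.03 | 0.10 ± 0.03 |

The pattern (adenoma: low permeability, large extracellular space, high
diffusivity; Warthin: fast wash-in/wash-out, high perfusion fraction;
malignant: intermediate with larger spread) follows the qualitative
physiology of these tumors, but the means and spreads were chosen to
make the classes clearly separable: they are a pipeline test fixture,
not clinical estimates. Passing classification tests on this phantom
demonstrates that the pipeline machinery is correct and leak-free, not
that real parotid tumors are separable to the same degree.

**Acquisition** mirrors the modelled protocol: one pre-contrast plus ten
post-contrast DCE frames at 38 s spacing, and DWI at the eleven b-values
0, 10, 20, 30, 50, 80, 100, 200, 300, 400, 800 s/mm².

**Signal models.** DCE voxels follow S(t) = S0·(1 + α·Ct(t)) with Ct from
the extended Tofts model and baseline-only background; the
signal-to-concentration proportionality α (default 4.0 per mmol/L)
corresponds to the low-concentration spoiled-gradient-echo linearization
with the relaxivity and baseline T1 folded into one constant; with the
Weinmann population AIF it yields peak lesion enhancements around
50–150%, matching clinical parotid DCE. DWI lesion voxels follow the
IVIM biexponential (perfusion term with its own decay rate e^{−bD*},
stated explicitly because conventions differ); the background decays
monoexponentially at 1.0e−3 mm²/s as a generic parenchyma stand-in.
Noise is additive Gaussian with sd = 2% of the baseline signal,
independent per voxel and frame — adequate at this SNR; a Rician option
is a possible extension. The phantom contains no anatomy, motion, bias
fields or partial-volume gradients; robustness results on it therefore
bound segmentation-induced variability only.

## Arterial input function

The study data include no measured AIF, so a population model is used:
the Weinmann biexponential Cp(t) = dose·(a1·e^{−m1 t} + a2·e^{−m2 t})
(a1 = 3.99, a2 = 4.78 kg/L; m1 = 0.144, m2 = 0.0111 min⁻¹; dose
0.1 mmol/kg) with a configurable bolus-arrival delay (default 19 s) so
that Cp(0) = 0; the Parker mixed-Gaussian/sigmoid population AIF is
available as an alternative. For exponential-mixture AIFs the Tofts
convolution is evaluated in closed form; for arbitrary AIFs a 0.1 s
discrete convolution with trapezoid end-correction is used.

## DCE parametric maps

Relative enhancement E(t) = (S(t) − S0)/S0 uses frame 0 as S0; voxels
with S0 ≤ 0 are excluded and counted in QC. Model-free descriptors, per
voxel, with the peak defined as the global maximum of E over
post-contrast frames (ties to the earliest frame) and TTP measured in
seconds from the first post-contrast frame:

* MRE = max E × 100 (%)
* TTP (s)
* WIS = MRE/TTP (%/s); when the peak sits on the first post-contrast
  frame (TTP = 0), the chord over one frame interval MRE/Δt is used
* WOS = (E_peak − E_last)/(t_last − t_peak) × 100 (%/s); 0 when the peak
  is the last frame
* WOR = (E_peak − E_last)/E_peak, clipped to [0, 1]. The raw ratio
  diverges for voxels whose peak barely exceeds baseline (pure noise);
  a wash-out ratio is a fraction of the peak lost, so values above 1
  (signal ending below baseline) are clipped and QC-counted
* WIO = WIS/WOS. As WOS → 0⁺ the ratio diverges, so WIO is capped
  (default 100, configurable); capped voxels are QC-counted. A very
  large cap would also destroy the fixed-bin-width discretization of the
  WIO map — one sentinel voxel would swallow the whole gray-level range.

The Tofts maps come from a bounded nonlinear least-squares fit of
α·Ct(t; K^trans, v_e, v_p) to E(t), with bounds K^trans ∈ [0, 3] min⁻¹,
v_e ∈ [10⁻³, 1], v_p ∈ [0, 1] and multi-start from three fixed initial
points — seed-free and deterministic. `fit_tofts_curve` uses
`scipy.optimize.least_squares` with the analytic Jacobian;
`fit_tofts_maps` runs the same model, bounds and starts for all masked
voxels simultaneously with a box-projected Levenberg–Marquardt (fixed 60
damped iterations per start, best-of-starts), which matches the scalar
path to ~1e−6 and is ~25× faster. Fitting operates on relative
enhancement (no T1 mapping), so recovered parameters are exact only up
to the correctness of α — consistent with the phantom's forward model.

At 2% noise the canonical lesion (K^trans = 0.2 min⁻¹, v_e = 0.3,
v_p = 0.05) is recovered with ~5% median K^trans error. High-k_ep
regimes (Warthin-like K^trans/v_e ≈ 4 min⁻¹) are intrinsically
ill-conditioned at 38 s sampling and carry much larger voxel-wise
errors; their lesion-level medians remain class-separating.

## IVIM maps

The segmented fit uses b_split = 200 s/mm² (high-b set {200, 300, 400,
800}): a log-linear fit of the high-b signal gives D and, via the
intercept, f = 1 − exp(intercept − ln S(0)); D* is then the only free
parameter in a bounded 1-D least-squares refinement on the full curve
(D ∈ [1e−5, 4e−3], D* ∈ [D, 0.5] mm²/s, f ∈ [0, 1]; clipping is
QC-flagged). Because exp(−200·D*) ≈ 0.14 for typical D*, a single pass
is biased (≈ 4% on D, 16% on f); the two steps are therefore iterated,
subtracting the estimated perfusion signal from the high-b points before
re-estimating D and f. Iteration stops as soon as the correction
magnitude falls below the residual noise level of the current fit
(residual RMS of the biexponential), because corrections smaller than
the noise only chase noise: noiseless voxels iterate to convergence
(errors < 0.4%), noisy voxels stop after one or two passes. At 2% noise
the voxel-wise D estimator operates near its statistical floor (the
four-point high-b regression has a theoretical sd of ~10–12% at this
SNR), giving ~9% median |D error|; D* is substantially noisier, as is
well known for IVIM. The batched map fitter vectorizes the same
algorithm with a golden-section D* search and matches the scalar fit to
~1e−8.

## Artificial ROIs

Fifteen variants per mask: in-plane rotations of ±10°, ±20°, ±30° about
the barycenter (slice-wise about the (x, y) projection of the 3D
barycenter, reading "axial rotation" as in-plane; linear interpolation
of the binary mask re-thresholded at 0.5, the standard mask-rotation
recipe, so results are bit-stable); one dilation each with the
connectivity-1 (6-neighbour) and connectivity-2 (18-neighbour) 3D
elements; one erosion (connectivity 1); and single-voxel translations
along ±x, ±y, ±z. A positive angle is counterclockwise in the (x, y)
index plane viewed from +z; clockwise variants carry negative angles.
Erosions that empty the mask and translations or rotations that exit the
grid raise errors naming the variant. Parametric maps are fitted over
the union of all 16 masks so every variant can be sampled from the same
map.

## Radiomic features

Gray levels come from fixed-bin-width discretization anchored at the ROI
minimum: level = floor((v − min)/w) + 1. Bin widths are per-map (the
maps live on wildly different scales — TTP in seconds, v_e a fraction);
the defaults target roughly 10–40 levels on each map's working range.
No resampling or filtering is applied; features are computed on the
original maps only, and there is no shape family. Conventions, stated
because implementations differ:

* GLCM: symmetric matrices over the 13 unique 3D directions; features
  computed per direction and averaged (directions with no voxel pairs
  are skipped). Level weights are the actual level values; Ng in
  Idmn/Idn is the number of distinct levels present in the ROI.
* GLRLM: maximal same-level runs per direction, averaged over the 13
  directions.
* GLSZM: zones are 26-connected components of equal level.
* NGTDM: per-voxel absolute difference from the mean level of its
  in-mask 26-neighbours; voxels with no in-mask neighbour are excluded.
* GLDM: dependence size = 1 + number of in-mask 26-neighbours with
  |level difference| ≤ α (α = 0), so an isolated voxel has dependence 1.
* Entropies sum −p·log2 p over non-zero probabilities.
* First order: population moments (Kurtosis is the non-excess fourth
  standardized moment, ≈ 3 for a Gaussian; both skewness and kurtosis
  are 0 for a constant region); Entropy and Uniformity use the same
  fixed-bin-width histogram; the robust MAD uses values inside the
  10th–90th percentile band (0 if the band is empty).

Single-voxel ROIs raise a documented degenerate-input error for the
families whose matrices are undefined there (GLCM, NGTDM); the others
return values. The whole 93-feature vector is cross-checked in the test
suite against an independent, deliberately naive loop-based
re-derivation of the same definitions, plus hand-computed matrix
examples.

## Robustness screening

For each of the 1116 features, the 43×16 (lesions × ROI variants) value
matrix is scored with ICC(2,1) — two-way random effects, absolute
agreement, single measurement — computed from the ANOVA mean squares.
Absolute agreement is the defensible form here: a systematic offset
introduced by a perturbation (e.g. dilation diluting the lesion with
background) is a real reproducibility failure, not rater style to be
forgiven. The original ROI counts among the 16 "raters" (configurable).
Zero-variance matrices are defined as ICC = 1 (trivially perfect
agreement, flagged); negative estimates are reported as computed and
categorized "poor". Categories: < 0.5 poor, 0.5–0.75 moderate, 0.75–0.9
good, > 0.9 excellent; the robust set keeps ICC strictly greater
than 0.9.

## Selection and classification

Labels travel in two forms: the three tumor classes drive feature
selection (the class structure carries information the binary labels
collapse), while training and evaluation of the final classifiers use
the binary malignant-vs-benign task, with sensitivity = malignant recall
and specificity = benign recall.

A fold plan — stratified 5-fold partitions, repeated (10 by default for
desk-scale runs; 100 reproduces the full protocol) — is drawn once and
shared by every selector × classifier pair. Within each training fold:

* **AUC filter**: per feature, the mean orientation-corrected one-vs-one
  AUC over the three class pairs; keep if strictly above 0.8 (constant
  features score 0.5).
* **ReliefF**: multi-class weights (k = 10 neighbours, all samples,
  misses weighted by class prior, range-normalized Manhattan distance);
  a feature is kept when its weight exceeds the 95th percentile of its
  own null distribution from 500 label shuffles (per-feature nulls, not
  a pooled null — the per-feature reading matches the permutation
  logic). The distance matrix is label-free and shared across shuffles.
* **LASSO**: L1-penalized multinomial logistic regression on
  standardized features, penalty chosen by inner 3-fold CV over a
  log-spaced grid; features with any non-zero coefficient are kept. If
  everything shrinks to zero, the single largest-coefficient feature at
  the weakest penalty is returned, flagged.
* **Backward elimination**: starts from the top 30 features by the
  univariate AUC ranking (greedy elimination over hundreds of features
  at n ≈ 43 would be statistically degenerate and quadratically
  expensive), then repeatedly drops the feature whose removal maximizes
  repeated (5×) 3-fold inner-CV accuracy of a ridge-stabilized linear
  discriminant, while no removal decreases it; ties are resolved by
  dropping the weakest-ranked feature. Removal on ties is required for
  a sane limit (four identical features must reduce to one) and the
  rank-based tie-break keeps strongly informative features through
  accuracy plateaus. Deterministic given the fold seed.

Selectors that return an empty set fall back to their own top-ranked
feature (flagged) so every fold yields a model. Classifier grids, tuned
by inner 3-fold CV accuracy (ties to the first grid entry): k-NN
k ∈ {3, 5, 7, 9, 11} (clamped to the training size on tiny folds); RBF
SVM C ∈ {0.25, 0.5, 1, 2, 4}, γ = "scale"; neural network (one hidden
layer) size ∈ {1, 3, 5} × weight decay ∈ {0, 0.01, 0.1}, L-BFGS, seeded;
LDA has no grid. Features are standardized per training fold and test
folds transformed with the training statistics. Folds whose training
half lacks a class are flagged and skipped. Per-fold
accuracy/sensitivity/specificity are aggregated to means and 5th–95th
percentiles over all repetitions × folds; selection frequencies per
feature support the "selected in ≥ 80% of iterations" reporting rule.

`run_naive_cv` implements the biased protocol — selection once on all
rows before cross-validation — solely to quantify the optimism the
nested protocol avoids; on label-permuted noise data the nested estimate
sits at chance while the naive one inflates by ~0.2.

## Orchestration

`run_pipeline` runs phantom → perturb → maps → features → icc → classify,
writing each stage's outputs (NIfTI volumes with JSON sidecars for frame
times/b-values, CSV tables, QC JSON) under the run directory and
checkpointing a manifest with parameters, seeds, counts and timings;
`resume=True` skips completed stages. Masks must share the exact grid of
their series (no resampling); voxel indices are 0-based with world
coordinates via the NIfTI affine. All randomness derives from the config
seed through `numpy.random.SeedSequence` spawning, so a rerun with the
same config is bit-identical. A full default run takes roughly 3–4
minutes on one CPU; its stage sizes (43 lesions, 16 variants, 12 maps,
10 CV repetitions) are the package's desk-scale defaults.

## Known limitations

* The phantom's uniform lesions/background make boundary-sensitive
  features more reproducible than they would be on real texture;
  the robust-set size on phantoms is not a clinical estimate.
* D* estimates are ill-conditioned at clinical SNR; their errors are
  reported but not tightly bounded.
* The Tofts fit inherits any error in the assumed α and population AIF;
  only relative (not absolute) kinetic parameters are meaningful on
  real data without T1 mapping.
* Rotation of small masks on anisotropic grids (3 mm slices) is
  slice-wise by construction; true 3D rotation is out of scope.
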