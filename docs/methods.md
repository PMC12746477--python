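# Methods

## Problem

In MR-guided adaptive radiotherapy (MRgART) of the prostate, every treatment
fraction starts with a daily MR image acquired at the treatment position.
The clinical team must then choose between two adaptation strategies:
**ATP** (adapt to position — shift the existing plan, fast) and **ATS**
(adapt to shape — recontour and replan on the daily anatomy, slow but
dosimetrically superior when the anatomy has changed). The package
implements a multi-stage image-based pipeline that makes this call directly
from the reference CT / daily MR pair:

1. **DLIR** — an unsupervised deformable image registration network. A 3D
   U-Net `g_θ(f, m)` consumes the moving reference image `m` and the fixed
   daily image `f` as a 2-channel volume and emits a dense displacement
   field `u` on the fixed grid (voxel units; `x ↦ x + u(x)` maps fixed
   coordinates into the moving image). A trilinear spatial transformer
   produces the warped image `w(x) = m(x + u(x))`. Training minimizes

       L = −MI(f, w) + λ₁ · Σ‖∇u‖² + λ₂ · Σ‖u‖²

   where MI is mutual information over the binned joint intensity
   distribution — the similarity that survives a modality change, unlike
   intensity differences — and the two regularizers penalize non-smooth and
   large displacements.
2. **DLSP** — a strategy classifier. The trained encoder is copied,
   frozen, and used as a feature extractor over the ROI-masked image pair
   (ROI = PTV expanded by a uniform physical margin); the deepest feature
   maps are global-average-pooled and fed to two cascaded fully connected
   layers ending in a sigmoid P(ATS). Only the head trains (binary
   cross-entropy); the decision rule is strict: ATS iff P(ATS) > 0.64.
3. **Labeler** — the ground-truth engine: the per-fraction ATP and ATS
   plans' DVH metrics are scored against 12 per-structure clinical criteria
   with tolerances; a fraction is ground-truth ATP only when the ATP plan is
   acceptable.
4. **Evaluation** — Dice and symmetric surface Hausdorff distance (physical
   units) before/after registration, ROC/AUC, accuracy, sensitivity,
   specificity, F1 (ATS positive), threshold selection (Youden or
   sensitivity/specificity balance), and cohort aggregation with half-up
   percentage rounding.

## Numerical core

No deep-learning framework is assumed: the networks, spatial transformer,
Parzen-window MI and Adam run on a small reverse-mode autodiff engine
(`mrgart.autodiff`) written on NumPy. Convolutions iterate over the k³
kernel taps with one GEMM per tap (memory-flat, fast at narrow channel
counts); the trilinear warp and its analytic gradient with respect to the
field are a dedicated op. The engine is verified end to end by a
numeric-vs-analytic gradient check of the full registration objective
(1e−3 relative agreement on 8³ volumes).

### Mutual information estimators

The training estimator soft-assigns min–max-normalized intensities to
`mi_bins` (default 32) Gaussian kernels of width `mi_sigma_ratio` bin
widths and forms the joint distribution as the normalized product of the
two assignment matrices (ε = 1e−10 inside the logarithms; the
normalization constants of the warped image are treated as stop-gradient).
An exact hard-binned estimator with identical bin edges is the test oracle
and the reporting path; the soft estimate approaches it as the kernel
narrows (asserted in tests). MI identities (MI(f,f) = H(f),
0 ≤ MI ≤ min(H_f, H_w), permutation destroys MI) are asserted on random
images.

### Loss reductions and the desk-scale preset

The public `smoothness_loss` / `l2_penalty` are **sums** over voxels of the
squared forward-difference gradient (last voxel contributes a zero
difference) and of the squared displacement, matching the brute-force
oracles in the tests, and `total_loss` composes them with the clinical
weights λ₁ = 1e−2, λ₂ = 1e−5 exactly as written. A sum reduction makes the
λ values grid-size dependent, so inside the *training* objective the two
sums are divided by the voxel count (`normalize_regularizers=True`),
making the weights per-voxel quantities.

The default configuration keeps the clinical recipe (4 encoder/decoder
levels, kernel 3, stride 2, LeakyReLU α = 0.2, linear field head, Adam at
1e−4, 200 epochs, batch 1). For desk-scale runs (64×64×32 grids on one
CPU) `RegistrationConfig.desk_scale()` raises the learning rate to 1e−3
and shortens training (default 30 epochs over ten cases); its per-voxel
regularizer weights were chosen by probing the objective landscape on
synthetic pairs (direct per-case optimization of `u`): the weights must
satisfy λ₁ · mean‖∇u_true‖² < ΔMI(true vs identity), else the identity
beats the true deformation, while too-weak weights let free-form warps
inflate MI without aligning anatomy (the classic failure of unregularized
MI registration). The preset also sharpens the Parzen kernel
(`mi_sigma_ratio` 0.5) because at desk-scale intensity statistics a wide
kernel blurs away most of the MI gain of the true alignment, and smooths
both images by one voxel inside the MI term only (`mi_presmooth_vox`) —
this damps the well-known sub-voxel interpolation artifact of MI
registration (resampling at fractional offsets smooths the moving image
and spuriously sharpens the joint histogram) and widens the capture range.

### Amortization limit and instance-specific refinement

Networks of this family are normally trained for on the order of 10⁵
iterations; a desk-scale CPU run affords a few hundred. Controlled probes
(including a strictly easier supervised variant regressing the known true
fields) show that at this budget the amortized network alone does not
generalize the registration map to held-out pairs — training loss falls,
but predicted fields explain none of the true deformation. Per-case
optimization of the *same objective* does recover alignment. `register()`
therefore supports deterministic instance-specific refinement: the
amortized prediction initializes a per-case Adam optimization of the
identical soft-MI + regularizer objective (`refine_steps`, default 0 and
off; the desk preset uses 150 steps at `refine_lr` 0.1). This
predict-then-refine pattern is standard in learning-based deformable
registration when amortized training is limited; inference remains
deterministic. Desk-scale registration results (mean structure Dice up
from ~0.83 to ~0.92, Hausdorff down by ~2 mm, in-ROI field residual about
0.85 of the true magnitude) are produced by this refined path.

### Warping conventions

Out-of-grid samples clamp to the border (zero-fill would create artificial
joint-histogram structure at the boundary); the warp is exact at integer
grid points, so a zero field is the identity bit for bit. Gradients with
respect to the field vanish in the strictly clamped region, consistent
with the clamped forward map. Mask volumes are re-thresholded at 0.5 after
warping so they stay binary.

## Synthetic phantoms

The generator emulates one treatment fraction as a pair of 3D volumes of
the same pelvic-like anatomy — smooth overlapping ellipsoids (body
outline, prostate-, bladder- and rectum-like structures) rendered through
two fixed monotone intensity transfer functions: piecewise-linear ("CT",
the moving image) and saturating nonlinear plus Gaussian noise ("MR", the
fixed image). The two renderings are intensity-incommensurate (voxelwise
correlation < 1) but information-equivalent (high mutual information),
which is exactly the regime that requires an MI similarity.

The deformation is a Gaussian-correlated random vector field: white noise
smoothed to a correlation length (`deformation_smoothness`, default 12 mm)
and rescaled to a peak magnitude (`deformation_amplitude`, mm). The
daily image and its structure masks are the warped anatomy; the true field
is stored with the case. Default grid: 64×64×32 voxels at 2×2×3 mm
(physical extent 128×128×96 mm — a cropped pelvis at half resolution);
the clinical 256×256×128 grid is supported but not used in tests.

**Ground-truth rule.** A fraction is ATS when the mean displacement
magnitude inside the ROI (prostate + 3 mm PTV margin + `roi_margin_mm`,
default 20 mm at desk scale) exceeds `label_threshold` (default 2 mm) — a
geometric surrogate for the dosimetric decision. The generator also emits
DVH tables whose dosimetric labeling agrees exactly with the geometric
label: the ATS table always passes every criterion; the ATP table degrades
monotonically with the mean in-ROI deformation and crosses the
zero-tolerance rectum D_max limit exactly at the threshold.

**Cohorts.** `generate_cohort` scales each fraction's field so its mean
in-ROI displacement falls in a clearly-ATP band (0.30–0.85× threshold) or
a clearly-ATS band (1.15–2.20×), matching a requested ATS prevalence
(default 77%, the clinical cohort's value). The guard band around the
threshold means the synthetic task contains no borderline fractions — by
design: the phantoms validate the machinery, and a margin-free boundary
would make labels depend on sub-voxel noise. Fields whose central dip
would require an unsafe peak (> extent/3) are redrawn deterministically.
Patient ids support leakage-free patient-level splits.

**What the phantoms do not emulate:** CT/MR physics (beam hardening, bias
fields, T2 contrast mechanisms), organ-specific biomechanics (bladder
filling, rectal gas), sliding interfaces, borderline anatomical changes,
and the physician element of the clinical ground truth. Passing the
synthetic suite therefore demonstrates that the pipeline's machinery is
correct and that the method recovers controlled deformations — not
clinical-grade performance.

## Problem sizes in the test suite and acceptance script

Registration training uses ten 64×64×32 fractions for 30 epochs (batch 1,
~5 minutes on one CPU); registration quality is measured on three held-out
fractions spanning mean deformations of 2–4 mm, via the refined
registration path (150 refinement steps per case). Classification uses 36
patients × 5 fractions (the clinical fractionation) split 24/12 at patient
level; encoder features are extracted once (the encoder is frozen) and the
head trains 300 epochs at 1e−3, batch 8, with an L2 weight penalty of
3e−2 on the FC weights (`ClassifierConfig.desk_scale`; selected on a
validation split inside the training patients — the clinical recipe of
1e−5/300 epochs/batch 2 pairs with full-scale features and many more
optimization steps per epoch, and is the config default). Unit and
property tests use 32×32×16 or smaller grids.

## Design choices where the design was open

- **Decision-threshold ties** go to ATP (the rule is strictly
  "greater than").
- **Both-empty Dice** is defined as 1 (identity of emptiness).
- **Hausdorff flavour**: maximum symmetric surface distance; a
  95th-percentile variant is available.
- **Labeler boundary semantics**: criteria are strict inequalities; a value
  exactly at the relaxed limit is violated.
- **ATP-acceptable ⇒ ATP** is the deterministic codification of the
  clinical decision; when both plans violate criteria the case returns ATS
  with a flag (no better option exists in the strategy menu).
- **Encoder-to-head bridge**: flattening the deepest encoder feature maps
  is the default — on phantom cohorts it retains measurably more label
  signal than global average pooling, whose signed spatial averaging
  cancels the mismatch response (GAP remains available as the compact,
  shape-robust alternative). Head features are standardized with
  training-set statistics stored in the classifier.
- **ROI use in the classifier**: the binary ROI multiplies the input
  channels *before* normalization, giving a testable invariance — voxels
  outside the ROI cannot influence the probability. (Masking deep features
  instead would break this invariance.)
- **Rigid pre-alignment** is translation-only (intensity centroid, or an
  exhaustive integer-shift MI search), sufficient because the generator
  controls misalignment; full 6-DOF alignment is out of scope.
- **Class imbalance** is left unweighted in the BCE (a class-weight option
  exists but defaults off).

## Known limitations

- The desk-scale registration operates near the information floor of the
  phantoms: the anatomy is piecewise-smooth, so MI constrains the field
  only near intensity boundaries and the smoothness prior interpolates
  elsewhere; field recovery is therefore partial (residual below, but not
  far below, the true magnitude).
- Amortized registration (one network for all pairs) does not generalize
  at desk-scale iteration budgets; instance refinement carries the
  registration quality (see above). A consequence is that the *frozen
  encoder* transferred to the strategy classifier is far less informative
  than a fully trained registration encoder would be: held-out
  classification AUC on phantom cohorts plateaus around 0.7–0.8 rather
  than the ≥ 0.9 a converged encoder supports. The classifier machinery
  (frozen-encoder invariant, ROI invariance, strict threshold rule,
  patient-level splits) is exercised and verified regardless.
- MI registration exhibits a bounded sub-voxel bias on already-aligned
  pairs (refinement can drift up to ~1 voxel by exploiting interpolation
  smoothing); `mi_presmooth_vox` damps but does not eliminate it. The
  amortized network itself stays near the identity on aligned cohorts.
- The soft-binned MI underestimates the hard-binned value at wide kernels;
  comparisons across kernel widths should fix the bin count.
- Training determinism assumes a fixed BLAS thread configuration; results
  are reproducible per machine setup.
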