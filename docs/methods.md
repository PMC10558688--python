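# Methods

`fiberlearn` is a desk-scale pipeline for prior-informed, multi-task,
self-enhancing analysis of 3D second-harmonic-generation (SHG) images of
single striated muscle fibers. This note documents the models, the synthetic
data they are validated on, the numerical choices, and the limits of what the
test suite demonstrates.

## The synthetic fiber model

Because curated single-fiber SHG databases are not publicly deposited, every
stage of the pipeline is exercised against a generative model with known
ground truth (`fiberlearn.synthgen`). A fiber is an elliptical cylinder along
the `y` axis carrying quasi-periodic striation:

```
I(r) = envelope(r) · A · (1 + m · cos φ(r)) + ε,   m = 0.6,  ε ~ N(0, (mA/snr)²)
```

* **Sarcomere banding.** φ advances along the fiber axis with period equal to
  the sarcomere length (SL, default range 2.2–3.0 µm at 0.5 µm voxels). The
  Nyquist guard rejects periods below twice the axial spacing.
* **Myofibril dispersion.** The cross-section is partitioned into Voronoi
  "bundle" domains (default diameter 12 µm), each a prism along the axis
  whose banding is an exactly tilted plane wave; tilts are i.i.d. von
  Mises(κ). A smoothly varying pointwise tilt of the phase argument does
  *not* work: the local band normal is ∇φ, which is then dominated by the
  tilt field's own spatial derivative, so the planted orientation
  distribution never appears in the image. Piecewise-constant domains realize
  it exactly, at the cost of mixing artifacts in a thin border zone; 12 µm
  domains keep that zone small relative to the structure-tensor window.
* **Verniers.** Y-shaped striation defects are planted as 2π phase
  dislocations running the fiber's depth, one terminating band each, with
  alternating winding signs so the dislocations' net phase drift (an apparent
  SL shift of several percent with same-sign windings) cancels. Defects keep
  a minimum separation (two periods, capped by the placement region) so each
  Y-junction is distinct.
* **Labels.** Tasks link to ground-truth structure through linear or logistic
  models with per-task labelled fractions, emulating a sparse multi-study
  design (the default seven-task design labels two tasks at 5%). The
  mechanism-probe design drives its binary task through the fiber's realized
  axial alignment and its continuous task through cross-sectional area, with
  image SNR low enough that the raw voxels carry the signal much less cleanly
  than the handcrafted biomarkers.

What the generator does **not** emulate: SHG image formation physics
(polarization, phase matching, PSF), intensity vignetting, fiber curvature,
partial-volume boundary effects beyond linear sampling, or correlated
(structured) noise. Tests passing on these phantoms demonstrate the
*mechanics* of the pipeline — estimator identifiability, masking exactness,
selection behavior — not performance on real muscle data.

## Standardization

Pipeline order is fixed: resample to isotropic 0.5 µm (linear) → median
filter of physical size 1 µm (window = round(size/spacing), forced odd,
minimum 3) → Otsu background zeroing → contrast enhancement (3D CLAHE, 16 µm
tiles, clip limit 0.01, background zeros preserved) used *only* to estimate a
rigid transform → multi-resolution Euler registration (Mattes mutual
information, 32 bins, up to 6 levels, ≤600 iterations per level, moments
initialization) whose transform is applied to the non-enhanced volume →
presence-atlas crop (voxelwise mean of binarized registered masks, bounding
box of probability > 0.85) → sample-wise standard score.

Numerical notes:

* The standard score is computed over foreground voxels only; background is
  exactly zero after Otsu zeroing and would otherwise dominate the moments.
* The synthetic striation is periodic along the axis and the envelope is
  axially uniform, so axial translation is identifiable only up to the
  sarcomere period. The registration therefore evaluates the metric at the
  identity, at the moments initialization, and at the optimizer's solution,
  and returns the best — guaranteeing the similarity metric never degrades.
  A fast principal-axes fallback (`registration_method="principal_axes"`)
  serves cohort-scale tests.
* The registration reference is a deterministic synthetic canonical fiber
  (perfectly vertical, clean banding), generated on demand rather than
  shipped.

## Handcrafted priors

* **Cosine angle sum (CAS).** Structure-tensor eigenanalysis at Gaussian
  scale 1 µm on the foreground eroded away from the fiber surface (2×scale,
  falling back to lighter erosion for thin fibers). Gradients use
  derivative-of-Gaussian filters: central differences attenuate each axis by
  sin(kΔ)/(kΔ) and would tilt a plane-wave normal by several degrees at the
  2.5 µm band period, while Gaussian derivatives share one spectral
  attenuation across components and leave the direction unbiased. CAS is the
  mean |cos θ| between the dominant eigenvector (the striation normal) and
  the fiber axis, θ ∈ [0, π/2]: a striation image is invariant under
  θ → π − θ, so only the axial fold of the tilt is observable. For
  von-Mises(κ) dispersion the observable expectation is E|cos θ|
  (`expected_axial_mean_cosine`), which coincides with the Bessel ratio
  I₁(κ)/I₀(κ) to <0.005 for κ ≥ 4 and exceeds it at small κ (0.682 vs 0.446
  at κ = 1; 2/π at κ = 0). 2D-CAS restricts to one z-plane (default center).
* **Sarcomere length.** Averaged axial power spectrum over foreground lines
  (Hann window, 4× zero padding), peak search in 1.5–4 µm, parabolic sub-bin
  refinement; the peak must exceed 3× the median in-band power, otherwise SL
  is reported unavailable.
* **Vernier density.** Per z-plane, a difference-of-Gaussians band-pass at
  the measured sarcomere frequency isolates the striation; both the bright
  and dark band skeletons are searched for branch points (a terminating
  bright band makes the adjacent *dark* bands merge, so the Y may sit in
  either polarity), gated at 0.2× the band-pass amplitude to suppress
  noise-born junctions and restricted to an interior eroded by one period
  (the envelope edge bends ridges into spurious junctions). Detections are
  clustered across planes within one period — a dislocation line recurs at
  the same (y, x) — and the defect count is normalized by the projected
  fiber area in µm².
* **Cross-sectional area.** Three estimators per cross-section stack (top and
  bottom 10 slices excluded, at least 3 retained): (1) pixel counting after
  2D opening/closing with a 1 µm disk; (2) PCA ellipse with the
  uniform-ellipse second-moment radii a = 2√λ; (3) a robust elliptic envelope
  with contamination 0.2, implemented as iterated Mahalanobis trimming to the
  central 80% of pixels with the uniform-ellipse calibration (the trimmed
  covariance of a uniform ellipse is coverage × the full covariance), which
  makes a clean solid ellipse unbiased — a Gaussian (χ²) calibration would
  not. The *smart* combiner returns the mean of the two most concordant
  estimates and records the discarded one; a single surviving estimate is
  flagged low-confidence.

## Cohort assembly

Whole muscle bundles (groups) are allocated to train/dev/test (2/4, 1/4, 1/4
of groups) by greedy deficit allocation within strata; strata come from
per-sample keys in which continuous labels are median-dichotomized (ties to
"low"), binary labels pass through, and missing values form an "NA" stratum.
Dichotomized keys steer the split only and never become learning tasks.
Labels and priors are z-scored with train-only statistics (population sd);
zero-variance quantities are left unnormalized with a warning. Presence masks
align with the model outputs (tasks, then auxiliary prior heads).

## Multi-task training

The network family is a compact strided-convolution pyramid (2D for 2.5D
slice inputs, 3D for volumes) with global average pooling and a single fully
connected head; capacities C1–C6 scale width and depth with strictly
increasing parameter counts. This stands in for a large pretrained backbone
at desk scale: the claims exercised here concern representation and prior
integration, not ImageNet-scale capacity. The engine (`fiberlearn.nn`) is a
small numpy reverse-mode autodiff implementation, verified against numeric
differentiation; everything is float64 and bit-deterministic on CPU for a
fixed seed.

* **Representations.** Full 3D (optionally downsampled to 0.75 µm) or three
  z-slices — center ± d µm for d ∈ {1, 5, 10, 20}, offsets rounded to voxels
  and clamped to the volume — fed as three channels.
* **Augmentation.** Flips, ±10° in-plane rotation, ±2-voxel shifts, additive
  Gaussian noise (5% of the input sd); random erasing zeroes 1–3 rectangles
  of 2–10% each. Train-time only, seeded.
* **Loss.** Per output: logit binary cross-entropy (classification) or
  squared error (regression and auxiliary prior heads), averaged over the
  unmasked samples of the batch. Uncertainty weighting combines outputs as
  Σ L_k/σ_k² + log σ_k with learnable log σ (initialized at 0, i.e. σ = 1).
  Masked entries contribute exactly zero value and gradient; a fully masked
  batch takes no optimizer step.
* **Optimization.** SGD with momentum or Adam; learning rate log-uniform in
  [1e-4, 1e-2]; batch sizes {4, 8, 16}; optional global-norm gradient
  clipping at 1.0; gradient accumulation to an effective batch ≥ 8 in 3D
  mode; optional inverse-class-frequency sampling on the rarest-labelled
  classification task.
* **Early stopping.** The weighted total dev meta-loss is smoothed by a
  10-epoch moving average (using available history before epoch 10);
  "did not decrease" means no new strict minimum of the smoothed series. The
  50-epoch patience activates only after epoch 75, so a never-improving trial
  runs exactly 125 epochs. Per-task best snapshots are kept at each task's
  dev meta-loss minimum alongside a best-total snapshot.
* **Metrics.** AUC by pairwise concordance (ties 0.5) for classification, R²
  for regression, on labelled samples only; single-class tasks are excluded
  with a warning.

## Self-enhancement

Meta-losses are 1 − AUC and 1 − R² on dev. NSGA-II (population 50 by
default, crossover probability 0.9, per-gene uniform swap probability 0.5,
no mutation, binary tournament on rank then crowding distance, (µ+λ)
survival) searches the joint space of data representation, prior-integration
level, capacity, and optimizer settings. The PriorsOnly level participates
as the fifth value of the integration gene with its network genes inert:
repeated PriorsOnly genotypes reuse one evaluation, since the AutoML result
depends only on the data. That path searches top-k feature selection
(k ≤ 5) × {L2 linear, random forest, k-NN} — all with probability outputs —
under grouped two-fold cross-validation on the pooled train+dev samples.
Failed trials receive worst-observed + 10% objectives so the population size
stays fixed without letting failures into the Pareto fronts. Model
selection: tasks with ≥ 100 labelled samples take the trial with the lowest
task meta-loss; scarcer tasks take the lowest *total* (task-weighted)
meta-loss, which acts as a regularizing selector. Ties break toward the
earlier trial id. `top_trials_summary` reports the mean dev metric of the 50
best trials per task (all trials when fewer). Every trial appends one JSONL
labbook line with its full configuration, objectives, and status.

## Explanations

* **Model level.** A 500-tree random forest maps encoded configurations
  (ordinal for ordered genes, one-hot grouped per dimension otherwise) to the
  dev metric; out-of-bag R² is reported. Interventional Shapley values
  attribute the prediction to configuration dimensions — exact subset
  enumeration up to 10 dimensions, permutation sampling (default 30
  permutations, 20 background rows) beyond; permutation estimates are exactly
  additive per trial by telescoping. A stability check refits the forest
  across seeds and ensemble sizes and reports the rank overlap of the top
  dimensions.
* **Sample level.** Expected gradients over the image input and, for models
  with a prior branch, jointly over the prior inputs on the same scale: for
  each baseline the gradient is integrated along the straight path to the
  sample (midpoint rule) and paired with *that baseline's* displacement
  before averaging — averaging displacements and gradients separately breaks
  the completeness axiom. Exact for linear models at any step count; on
  trained ReLU networks 256 steps bring the attribution sum within a few
  percent of the output-minus-baseline gap. The default baseline is the
  train-sample average (zeros if none given).

## Problem sizes used in the shipped checks

The mechanism-recovery experiment runs 200-fiber cohorts at 16×32×24 voxels
(0.5 µm), 60 trials with population 10 and 6 training epochs per trial,
across 5 seeds in the test suite (3 in the acceptance script); estimator
oracles use full-size 64×192×96 fibers. These sizes were chosen so the full
suite runs on a single CPU while each check still has the statistical room
its tolerance needs.

## Known limitations

* The numpy engine trains small networks; it does not attempt the original
  study's scale (large pretrained backbones, GPU epochs, 1,500-trial
  searches).
* CAS accuracy degrades for fibers only a few µm across, where surface
  erosion leaves little interior; the estimator then falls back to lighter
  erosion and inherits some boundary bias.
* The vernier detector is tuned to the generator's dislocation morphology;
  real verniers with sub-period displacement or strong curvature would need
  re-validation. On dispersed fibers the bundle-domain borders themselves put
  bands out of register, so VD then counts planted dislocations *plus*
  border mismatches — directionally consistent with disordered fibers having
  more verniers, but planted-count recovery holds only for parallel fibers.
* Planted dislocations locally stretch/compress the banding and smear the
  axial spectral peak, drifting the SL estimate by up to ~5% on
  defect-dense fibers; the ±0.1 µm recovery guarantee applies to defect-free
  striation.
* Axial registration of a periodic, axially uniform fiber is ill-posed up to
  one sarcomere period; the metric guard prevents degradation but cannot
  recover an absolute axial offset.
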