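# fiberlearn

Prior-informed, self-enhancing multi-task analysis of 3D second-harmonic
generation (SHG) images of single striated muscle fibers.

Label-free SHG microscopy resolves the sarcomere striation of individual
muscle fibers, and decades of muscle research distilled that structure into a
handful of biomarkers: the **cosine angle sum** (CAS, myofibril alignment),
the **vernier density** (VD, Y-shaped striation defects per µm²), the
**sarcomere length** (SL) and the **cross-sectional area** (CSA). Studies
that pair such images with pathology labels (dystrophic/inflammatory
phenotypes) or biomechanical force readings are individually small and
sparsely labelled, which is hostile territory for deep learning.
`fiberlearn` is for researchers in that regime. It implements:

* a **synthetic fiber generator** with fully known ground truth (banding
  period, planted dispersion, planted defects, analytic cross-section, label
  links with controllable sparsity) so every downstream stage is testable
  without a proprietary database;
* **cross-study standardization** — isotropic resampling, median denoising,
  Otsu background zeroing, 3D CLAHE (used only to drive a rigid
  mutual-information registration to a canonical fiber), presence-atlas
  cropping, and per-sample standard scoring;
* the four **handcrafted priors** with availability flags, including the
  concordance-combined "smart" CSA (three estimators, mean of the two most
  agreeing);
* **leakage-safe cohort assembly**: whole muscle bundles are allocated to
  train/dev/test (2/4, 1/4, 1/4), stratified on median-dichotomized labels,
  with train-only normalization;
* a **multi-task trainer** in which missing labels are masked (zero loss,
  zero gradient) and tasks are balanced by learned uncertainty weights,

      L = Σ_i L_i/σ_i² + log σ_i ,

  with configurable data representation (3D, or three 2.5D slices at 1/5/10/20
  µm spacing), prior integration (NoPriors / AuxLosses / Branches /
  AuxLosses@Branches / PriorsOnly), capacity, augmentation and optimizer —
  on a compact, dependency-free numpy autodiff engine;
* **NSGA-II self-enhancement** over that configuration space with per-task
  meta-losses (1 − AUC, 1 − R²) as objectives, a weighted total meta-loss for
  scarce-task model selection, early stopping on its 10-epoch moving average
  (patience 50, active after epoch 75 — at least 125 epochs per trial), and a
  JSONL labbook of every trial;
* **two-level explanations**: Shapley attribution of configuration decisions
  through a random-forest surrogate, and expected-gradients maps over image
  voxels jointly with prior inputs.

## Worked example

```python
import math
from fiberlearn.synthgen import FiberSpec, generate_fiber
from fiberlearn import priors as pr

spec = FiberSpec(sarcomere_length=2.5, semi_axes=(20, 10),
                 dispersion_kappa=math.inf, n_verniers=6, snr=10.0)
img, truth = generate_fiber(spec, shape=(64, 192, 96), seed=11)

pv = pr.compute_priors(img, mask=truth["mask"])
print({k: round(v, 3) for k, v in pv.as_dict().items()})
```

prints

```
{'cas2d': 0.999, 'cas3d': 0.999, 'vd': 0.002, 'sl': 2.619, 'csa': 629.011}
```

against a fiber planted with perfectly parallel myofibrils (CAS → 1,
measured 0.999), an elliptical cross-section of π·20·10 ≈ 628.3 µm²
(measured 629.0), and six vernier dislocations: the detector finds exactly
6 junction lines over the 3840 µm² projected area (VD = 6/3840 ≈ 0.0016,
reported 0.002). The planted period is 2.5 µm; the six dislocations locally
stretch and compress the banding, which smears the spectral peak and drifts
the SL estimate to 2.62 µm — on defect-free fibers the estimate lands within
±0.05 µm (see the test suite's recovery checks).

A shell-level run of the whole loop:

```bash
fiberlearn simulate --n 64 --seed 0 --out cohort/ --shape 24,48,32
fiberlearn priors --in cohort/manifest.csv --out cohort/priors.csv
fiberlearn split --manifest cohort/manifest.csv --seed 42 \
    --out cohort/split.csv --tasks dystrophic:binary
fiberlearn optimize --manifest cohort/merged.csv --split cohort/split.csv \
    --trials 20 --population 10 --seed 42 --out run/ \
    --tasks dystrophic:binary,active_force:continuous
fiberlearn explain --labbook run/labbook.jsonl --task dystrophic \
    --out run/config_shap.csv
```

(`merged.csv` joins the manifest and priors tables on `sample_id`.)

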