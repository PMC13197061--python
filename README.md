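# icodiff

Conditional spherical diffusion models for cortical-surface normative
modeling.

## The problem

Normative modeling quantifies how far an individual deviates from a healthy
reference distribution, region by region — a key tool for characterizing
heterogeneous neurodegeneration such as Alzheimer's disease (AD). On the
cortical surface this is hard because folding patterns differ across people:
even after spherical registration, one subject's gyral crown is compared
against another's sulcal bank, inflating variance and masking disease effects.

`icodiff` addresses the mismatch generatively. A denoising diffusion
probabilistic model (DDPM) is trained on per-vertex cortical feature maps
(cortical thickness CT, shape index SI) of healthy controls, resampled to a
subdivided icosahedron and *conditioned on each subject's own anatomy*: the
gyral/sulcal segmentation mask is concatenated to the network input, and age
and sex enter through embedding MLPs added to the time embedding. For a test
subject, the observed maps are pushed part-way into the forward noising
process (`t_start` of `T` steps) and denoised back under the healthy-trained
dynamics, yielding *pseudo-healthy* reconstructions that keep the subject's
folding pattern. `N` such reconstructions form a personalized reference set,
and the abnormality of ROI `i` is the z-score

```
Z_i = (x_i − mean_j x_{i,j}) / std_j x_{i,j}
```

where `x_i` is the subject's mean feature value in ROI `i` and `x_{i,j}` the
same quantity in the j-th reconstruction. Strongly negative `Z_i` in a
thickness map flags atrophy. The per-subject vector of ROI scores feeds a
linear SVM for group classification (CN vs AD, etc.).

## What is inside

- `icodiff.geometry` — hierarchical icospheres (order k: `10·4^k+2` vertices;
  order 6 = 40962 for full cortical work) with a vertex-prefix hierarchy, a
  canonically ordered 1-ring neighbor table, prefix pooling / zero-pad
  up-pooling, barycentric resampling from arbitrary spherical meshes, and
  geodesic-Voronoi synthetic parcellations.
- `icodiff.diffusion` — cosine schedule, forward marginals, the
  v-parameterization (`v = √ᾱ ε − √(1−ᾱ) x₀`) with exact inversions,
  ancestral reverse sampling and partial-noise reconstruction.
- `icodiff.denoiser` — spherical UNet: 1-ring (7-tap) convolution, ResBlocks
  with FiLM conditioning, self-attention at the two coarsest levels, built on
  a compact numpy reverse-mode autodiff core (`icodiff.nn`) with Adam.
- `icodiff.normative` — ROI means, abnormality z-scores, age-matched template
  reference sets, stratified k-fold SVM evaluation.
- `icodiff.synthetic` — synthetic cortical cohorts: subject-specific folding
  fields, mask-correlated thickness, age/sex effects, ROI-confined atrophy.
- `icodiff.metrics` — MSE, SSIM with 1-ring windows on the sphere, Gaussian
  Fréchet distance between embedded sample sets.
- `icodiff.io` — FreeSurfer curv/annot I/O (via nibabel), channel
  standardization, YAML run configs, cohort persistence.
- `icodiff.estimators` — scikit-learn style estimators:
  `ConditionalSurfaceDDPM` (fit / sample / reconstruct) and
  `NormativeScorer` (fit / transform → z-score matrix).
- `icodiff.cli` — `icodiff synth|train|sample|reconstruct|score|evaluate|mesh-info`.

## Worked example

```python
import numpy as np
from icodiff import (CohortSpec, make_cohort, ConditionalSurfaceDDPM,
                     NormativeScorer)

# 100 healthy controls and a small test set with atrophy in 3 ROIs
train, _ = make_cohort(CohortSpec(n_subjects=100, order=2, seed=1))
test, _ = make_cohort(CohortSpec(
    n_subjects=10, order=2, seed=2,
    group_fractions={"CN": 0.5, "AD": 0.5}, delta=0.5,
))

model = ConditionalSurfaceDDPM(order=2, n_timesteps=250, n_steps=2000,
                               augment=True, random_state=1).fit(train)
scorer = NormativeScorer(model=model, reference="ddpm",
                         n_samples=10).fit(train)
z = scorer.transform(test)          # (10 subjects, 34 ROIs)

disease = [3, 11, 27]
ad = [i for i, s in enumerate(test) if s.group == "AD"]
cn = [i for i, s in enumerate(test) if s.group == "CN"]
print("AD mean Z in atrophied ROIs:", z[np.ix_(ad, disease)].mean().round(2))
print("CN mean Z in atrophied ROIs:", z[np.ix_(cn, disease)].mean().round(2))
```

Output (a few minutes on one CPU):

```
AD mean Z in atrophied ROIs: -2.48
CN mean Z in atrophied ROIs: 0.44
```

The atrophied regions of AD subjects sit several reference standard
deviations below the personalized healthy distribution, while held-out
controls score near zero everywhere.

## Scope notes

FreeSurfer preprocessing (surface extraction, registration, resampling with
`mris_surf2surf`) is upstream of this package: the real-data path starts from
curv/annot files on a spherical mesh. Only the left hemisphere is modeled;
the right is symmetric reuse. See `docs/methods.md` for the model details,
parameter defaults and limitations.
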