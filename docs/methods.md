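# Methods

## Data representation

All per-vertex data live on subdivided icosahedra projected to the unit
sphere. Order `k` has `10·4^k + 2` vertices, `30·4^k` edges and `20·4^k`
faces; twelve vertices (the base icosahedron's) have valence 5, the rest 6.
The base icosahedron is fixed with poles on the z-axis and two latitude rings
built from the golden-ratio construction, and each subdivision round appends
edge midpoints in lexicographically sorted edge order after the parent
vertices. Two consequences are load-bearing:

- **Prefix property.** The first `10·4^(k−1)+2` vertices of an order-`k`
  sphere are, by index and position, the order-`(k−1)` sphere. Pooling a
  signal one order down is therefore "keep the prefix", and up-pooling is
  "zero-pad the appended vertices". These two operators are exact adjoints
  and introduce no smoothing, which avoids grid artifacts that neighborhood
  averaging produces in generated samples.
- **Determinism.** Mesh construction involves no floating-point-order
  ambiguity, so meshes, neighbor tables and everything derived from them are
  bit-reproducible.

The 1-ring neighbor table orders each vertex's neighbors by azimuth after
rotating the vertex to the north pole (minimal rotation about `v × ẑ`; the
south pole uses a half-turn about x̂). The smallest azimuth starts the ring
and exact ties break toward the smaller index. Valence-5 vertices declare a
pad slot holding the vertex's own index, so convolution kernels always see
7 taps: `[center, n₁ … n₆]` with the pentagon pad repeating the center.

Resampling from an arbitrary spherical triangulation (e.g. a FreeSurfer
sphere) locates each destination vertex in a source triangle by central
projection and interpolates barycentrically; the locator widens its tolerance
(1e-10 → 1e-6 → 1e-3 with a growing candidate set) before failing. Nearest-
vertex resampling is kept for label maps. Barycentric resampling is exact for
fields linear in the embedding coordinates restricted to a source triangle.

## Diffusion model

The generative core is a standard DDPM: a forward Markov chain adds Gaussian
noise over `T` steps with variances `β_t` from the cosine schedule
(`ᾱ_t = f(t)/f(0)`, `f(t) = cos²(((t/T + s)/(1+s))·π/2)`, offset `s = 0.008`,
`β` clipped at 0.999 with downstream quantities recomputed from the clipped
values), and a learned reverse chain denoises.

The network predicts the *velocity* `v = √ᾱ_t ε − √(1−ᾱ_t) x₀`, an exact
orthogonal reparameterization of the (signal, noise) pair: given `x_t` and
`v`, both `x₀` and `ε` are recovered in closed form, and training minimizes
mean-squared error in v-space with `t` drawn uniformly per batch item. The
v-target is used because it is well-conditioned at both ends of the schedule
(pure ε-prediction degenerates as `ᾱ→0`, pure x₀-prediction as `ᾱ→1`).

Reverse sampling uses the exact forward-posterior mean evaluated at the
predicted `x̂₀` with fixed posterior variance `β̃_t = β_t(1−ᾱ_{t−1})/(1−ᾱ_t)`
(the variance is not learned; the simplified objective carries no variance
term). `x̂₀` is clipped to ±6 standardized units by default (configurable,
disable with `clip_x0=None`); the `t = 1` step adds no noise.

**Pseudo-healthy reconstruction.** For a test subject the observed maps are
noised to `t_start` with fresh noise and denoised back with the subject's own
conditions held fixed. `t_start` defaults to `T/2` — deep enough to detach
the trajectory from disease-related intensity detail, shallow enough that
the anatomical conditioning keeps the reconstruction aligned. `t_start`
indexes the full training schedule. `N` independent reconstructions form the
personalized reference set (default `N = 10`).

## Denoising network

A UNet on the icosphere hierarchy. Convolution gathers the 7 taps of each
vertex's 1-ring and contracts them with a learned `(out, in, 7)` kernel —
one large GEMM per layer. Each level has 2 ResBlocks
(GroupNorm → SiLU → conv, FiLM scale-shift injection of the embedding,
GroupNorm → SiLU → zero-initialized conv, residual path with a 1×1 projection
on width changes). Between levels, prefix pooling descends one mesh order and
zero-pad up-pooling ascends; decoder levels concatenate the encoder skip.
Single-head dot-product self-attention over vertices runs at the two
coarsest levels, where vertex counts are small. The output head is
zero-initialized so optimization starts at the predict-zero baseline.

Conditioning: the segmentation mask is encoded as a `{−1, +1}` channel
(multi-class masks would be one-hot) and concatenated to the input; age
(years/100) and sex (0/1) each pass through a two-layer MLP whose
(zero-initialized) output is added to the sinusoidal time embedding.

The full-cortex configuration is order 6 with widths (128, 256, 512),
`T = 1000`, Adam at 1e-5 with cosine annealing. The desk-scale defaults used
throughout the tests are order 2 (162 vertices), widths (16, 32, 48),
`T = 250`, Adam at 1e-3, batch 16, 2000 steps — sized so the full study runs
in minutes on one CPU while every mechanism (hierarchy, attention,
conditioning) is exercised. Level count must satisfy
`n_levels ≤ base_order + 1`.

**Symmetry augmentation.** At ~100 training subjects the conditional network
can memorize the mask → map association, which collapses reconstruction
diversity and makes the model ignore the subject information in `x_t`. The
desk-scale study therefore trains with icosahedral-symmetry augmentation:
the 60 rotations of the icosahedron map the subdivided vertex set onto
itself, so each acts on per-vertex data as an exact permutation
(`geometry.icosahedral_symmetries`), and the synthetic CN distribution is
invariant under them — permuting (features, mask) jointly is exact
augmentation. With it, train and held-out v-losses coincide and sample
dispersion recovers. The estimator's `augment` flag is off by default:
real cortical maps registered to a common template are *not*
rotation-invariant, so this augmentation is only valid for isotropic data.

The network and optimizer are implemented on a small reverse-mode array
autodiff core (`icodiff.nn`): a taped `Tensor` over float32 numpy arrays with
broadcasting-aware arithmetic, batched matmul, vertex gather/scatter (the
scatter uses a cached inverse-occurrence table), fused group normalization,
softmax, SiLU, concatenation/splitting and vertex-axis padding, plus Adam.
All gradients are verified against finite differences in the test suite.

## Normative scoring

Scores are computed on cortical thickness (channel 0) by default, as the
accepted AD atrophy biomarker; the channel is selectable. ROI means are
unweighted vertex means; empty ROIs yield NaN. The z-score uses the unbiased
(N−1) standard deviation — material at `N = 10` and exposed as `ddof`.
Zero-spread ROIs receive a signed-infinity sentinel, are recorded on the
score table, and must be excluded from classification features (the workflow
drops non-finite columns). For subjects drawn from the reference distribution
itself the scores are approximately t-distributed; at `N = 10` their variance
is inflated relative to 1 (roughly `(N−1)/(N−3) · (1 + 1/N)`), which the
calibration test tolerates.

Two reference sets are supported: `ddpm` (the diffusion reconstructions) and
`template` (the `k` training controls closest in age, ties toward the smaller
subject index). Classification uses a linear-kernel SVM on the raw z-vectors
with stratified k-fold cross-validation (default 10 folds, fold metrics
averaged, seeded shuffling).

## Synthetic cohorts

The generator emulates the statistical structure the pipeline relies on,
not cortical biophysics. Per subject, a smooth folding field `f` (iterated
1-ring mean-filtered white noise, re-standardized; default 10 iterations)
defines individual anatomy: the gyral/sulcal mask is `f > 0`, cortical
thickness is `γ(2·mask−1) + β_sex·sex − β_age·(age−60)/10 + σ·noise` with an
independent smooth noise field, and the shape-index analog is `tanh(f)` plus
noise at `σ/2`. Disease subtracts `δ` (AD) or `δ/2` (MCI) from CT inside the
designated ROIs of a geodesic-Voronoi atlas (34 ROIs by default, 3 disease
ROIs). Ages are uniform on 55–85, sexes Bernoulli(0.5).

The folding field is deliberately finer-scaled (3 smoothing iterations) than
the residual noise (10): folds vary at the mesh's finest usable scale, as
real folding does at millimeter resolution, while residual thickness
covariation is broad. This scale separation is what makes the segmentation
mask informative beyond a partially noised feature map — the signal the
anatomical-conditioning ablation measures; with a single scale the mask is
nearly redundant given `x_t` and the ablation margin degenerates to noise.

Defaults `γ = 0.5`, `β_age = 0.1`/decade, `β_sex = 0.1`, `σ = 0.3`,
`δ = 0.5` (standardized units) make the demographic and disease effects
detectable in cohorts of ~100 without being trivially separable. What
passing tests show: the pipeline recovers localized mean shifts against
subject-specific anatomy, and anatomical conditioning measurably improves
reconstruction fidelity. What they do not show: robustness to registration
error, scanner effects, spatially correlated disease topography, or any
claim about real cortical data.

## Metrics

SSIM on the sphere uses each vertex's 1-ring patch (7 members, 6 at
pentagons) as the local window — the canonical neighborhood on the mesh —
with the usual stabilizers `c₁ = (0.01·R)²`, `c₂ = (0.03·R)²` and `R` the
joint value range by default. Note the windowed luminance term makes some
sign intuitions hold only for maps with coherent local structure (patch
means near zero flip the luminance factor); the tests use piecewise and
smooth fields accordingly. The Fréchet distance is the Gaussian form
`‖μ_X−μ_Y‖² + tr(Σ_X + Σ_Y − 2(Σ_X Σ_Y)^{1/2})` with diagonal loading on
near-singular covariances; any embedding function can feed it (the natural
default here is the per-ROI mean vector), which generalizes FID-style
evaluation without a pretrained image embedder.

## The desk-scale study

`run_normative_study` (used by the acceptance script and the end-to-end
tests) runs: order-2 cohort of 100 CN (training) and 20 CN + 20 AD (test,
`δ = 0.5`); conditional and unconditional models trained identically
(2000 steps); reconstruction at `t_start = T/2 = 125`, `N = 10`;
per-subject per-ROI z-scores; a one-sided sign test that AD subjects' mean
z over the atrophied ROIs is negative; ablation MSE/SSIM of CT
reconstructions of held-out controls; and 10-fold CN-vs-AD classification.
Chains are executed with (sample × subject) flattened into the batch in
chunks of 200 rows, which changes nothing mathematically.

## Known limitations

- The reverse sampler is plain ancestral DDPM; no accelerated (DDIM-style)
  sampling, learned variances, or guidance.
- Per-step fixed posterior variance slightly underestimates the true reverse
  variance for non-unit data scales; the effect is below Monte-Carlo noise
  at the tested schedule lengths but is a known bias of the simplification.
- The numpy network is practical at synthetic scales (orders ≤ 4); full
  order-6 training at paper scale is out of reach without an accelerator.
- Pentagon handling (pad = center) slightly overweights the center tap at
  the 12 base vertices.
- The synthetic atrophy is a mean shift only; no shape or topology change.
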