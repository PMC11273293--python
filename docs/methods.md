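# Methods

## Model and assumptions

Harmonization here assumes batch effects act, conditional on biological
covariates, as (a) shifts of conditional means and (b) rescalings of
residual variation — the classical ComBat location/scale assumptions — but
applies them in three places rather than feature-by-feature only:

1. **Latent space.** A conditional variational autoencoder maps each
   subject's normalized feature vector, its biological covariates x, and its
   batch one-hot b to a Gaussian code z ~ N(μ, diag σ²). ComBat is fitted on
   the n × d matrix of latent means μ (with x and batch as the design), so
   multivariate batch structure that the encoder absorbed is removed by
   moment matching with empirical-Bayes shrinkage.
2. **Decoder conditioning.** At harmonization time the decoder receives the
   batch-adjusted latents together with a common target-batch indicator, so
   whatever batch dependence the decoder learned is evaluated at a single
   batch level for all subjects.
3. **Residuals.** The noiseless reconstruction decode(μ, x, b) never fits the
   data exactly; the residual r = y_norm − decode(μ, x, b) is kept, ComBat-
   corrected feature-wise, and added back. This preserves natural noise
   characteristics (no synthetic-looking output) and makes "harmonize to your
   own batch" exactly the identity map, because then neither the latents,
   the decoder conditioning, nor the residuals are altered.

The three-way split yields a useful robustness property: if the KL weight is
set so high that the latent code collapses toward the prior, the residuals
contain nearly all the batch signal and residual ComBat still corrects it;
if the weight is so low that the latents absorb everything, latent ComBat
does. The pipeline's quality is therefore insensitive to the exact KL weight
over more than an order of magnitude (exercised by the ×16 sweep in the
acceptance suite).

ComBat itself follows the standard empirical-Bayes pipeline: per-feature
least squares on the design [batch one-hot | covariates]; standardization
Z = (y − α̂ − x'β̂)/σ̂ with σ̂² the pooled mean squared residual (denominator
n); per-batch raw moments γ̂ (batch means of Z) and δ̂² (within-batch
variance of Z, denominator n_i); method-of-moments priors across features
(normal for γ, inverse-gamma for δ²; moments across features use ddof=1);
and iterated conditional posterior means for (γ*, δ²*). The identifiability
constraint is sample-size weighted, Σ_i n_i γ̂_ik = 0; an unweighted
constraint would change α̂ but not the adjusted values.

## Parameters

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `lambda_final` | 0.1 | final KL weight; large enough to regularize the latent geometry, small enough to keep subject-specific detail. The pipeline is robust to ×16 changes in either direction. |
| schedule | cyclic, 5+30+5 epochs | 5 pretrain epochs at λ=0, six 5-epoch linear ramps 0→λ_final, 5 epochs at λ_final; cycling lets the optimizer escape posterior collapse. `constant` is available. |
| optimizer | adam (internal), adamw (cross-fit) | learning rate 0.01; AdamW decoupled weight decay 0.01 (logged in the training config) regularizes models that must generalize out of fold. |
| `minibatch_size` | 64 subjects | loss is an *unaveraged* sum over features and subjects; averaging would silently rescale the effective λ. |
| `latent_dim` | 2^round(log2(p/4)) | ≈ p/4 rounded to the nearest power of 2 (p=62 → 16); overridable. Minimum 2 (with a warning) for very small p. |
| hidden widths | round(linspace(p, d)) interior points | four TanH layers per side, each approximately halfway between its neighbors (62 → 53, 44, 34, 25 → 16); decoder mirrors the encoder. |
| `eb` | True | empirical-Bayes shrinkage in the latent and residual ComBat fits; `False` uses the raw per-feature estimates (useful for oracle checks). |
| `reference_batch` | largest batch | the batch indicator handed to the decoder for pooled harmonization. The latent/residual ComBat steps target the pooled distribution; the decoder still needs *some* batch vector, and the largest batch is the best-estimated choice. Configurable. |
| ComBat EB iteration | tol 1e-4, max 500 | convergence on the maximum absolute parameter change. |
| kBET | k0 = max(10, ⌊0.1 n⌋), subset 0.1, 500 repeats | Euclidean neighbors on standardized features, excluding the query point; Pearson χ² with df B−1 per neighborhood. |

## Numerical choices

- The encoder scale head outputs log-variance (exponentiated to σ), clipped
  to |log σ²| ≤ 15 to keep `exp` finite; the clip's saturation zeroes its
  gradient where it binds.
- Weight initialization is the uniform fan-in scheme
  U(−1/√fan_in, 1/√fan_in) with a user-settable seed; minibatch shuffling
  and reparameterization draws are reseeded per epoch from the master seed,
  so training is bit-reproducible given the seed.
- Backpropagation through the CVAE is hand-derived and verified against
  central finite differences (relative tolerance 1e-4) in the test suite.
- Collapsed latent dimensions (variance ≤ 1e-10 across subjects) are
  excluded from latent ComBat and passed through unchanged, with a warning
  naming KL vanishing; if *all* dimensions collapse, latent ComBat is
  skipped entirely and residual ComBat carries the adjustment.
- Degenerate ComBat cases: features with (numerically) zero residual
  variance are flagged and cannot be standardized; zero cross-feature
  variance of δ̂² or an inverse-gamma shape λ ≤ 2 disables scale shrinkage
  for that batch with a warning.
- The kBET overall p-value is a label-permutation test on the full-data
  rejection rate. Rejection counts are discrete, so ties between observed
  and permuted rates are broken by the continuous mean χ² statistic; this
  keeps the permutation p exactly uniform under the null (the test suite
  verifies the empirical α at the nominal 0.05).
- Anderson–Darling two-sample p-values come from the published asymptotic
  interpolation and are clipped to [0.001, 0.25].
- The feature-wise batch test is a Gaussian likelihood-ratio statistic
  n·ln(RSS₀/RSS₁) against χ² with B−1 df; covariate p-values are per-
  coefficient t-tests in the full model. MANOVA uses Pillai's trace
  V = tr(H(H+E)⁻¹) with the standard F approximation.

## Synthetic data

The generator emulates a multi-scanner cortical-thickness study:
Y = α + Xβ + FΛ_b' + γ_b + δ_b·ε with rank-r latent factors F shared across
batches, optional per-batch loading perturbations (covariance batch effect)
and a batch-specific quadratic term in the first factor (nonlinear batch
effect), feature-wise additive shifts γ_b ~ N(0, scale²), multiplicative
noise effects δ²_b ~ InvGamma, and biological covariates (age, sex, 3-level
diagnosis) whose *distributions* may differ by batch — confounding is
induced only through demographics, never through a direct batch→outcome
path, so true biological coefficients stay well-defined. Defaults mirror a
three-scanner cohort scaled to n = 127/130/43 (~300 total; the full-size
280/287/96 profile is one keyword away), p = 62 features, age ≈ 77 (SD 6.6),
male fractions 0.60/0.66/0.52. Named fixtures (`null`, `additive-only`,
`additive+scale`, `covariance-effect`, `confounded`) fix seeds and effect
patterns for tests and docs.

What the generator does *not* emulate: spatial correlation structure beyond
low-rank factors, heavy-tailed or skewed feature distributions, site-specific
preprocessing artifacts, longitudinal correlation. Passing tests on this
generator show the pipeline removes the batch-effect classes it models
(additive, scale, low-rank covariance, mild nonlinearity) while preserving
linear covariate effects — they do not certify performance on real
image-derived features with structure outside this family.

## Design decisions

- Parametric empirical Bayes only; the nonparametric prior variant is out of
  scope.
- δ̂² uses denominator n_i (not n_i − 1); documented here and pinned by
  oracle tests so the choice is auditable. The Bioconductor reference uses
  n_i − 1 in the raw estimate, which is why the cross-implementation test
  compares final harmonized output at a few percent, not machine precision.
- "Harmonize to batch b" re-adds γ*_b and rescales by δ*_b after pooled
  adjustment; this realizes counterfactual decoding and the self-target
  identity.
- The encoder's μ and log-variance heads share the hidden trunk (the
  architecture is an hourglass with two linear heads); fully separate
  encoders would roughly double parameters for no observed benefit.
- Batch one-hot uses all B columns for the networks (no identifiability
  concern in a nonlinear model); regression designs drop a reference level.
- Cross-fit folds are stratified by batch and each batch must contain at
  least k subjects, so every training fold sees every batch.
- Covariate normalization at apply time reuses the training min/max;
  out-of-range values extrapolate with a warning rather than failing.

## Limitations

- One batch variable, cross-sectional designs only; no longitudinal or
  multi-way batch structure.
- The CVAE is a small fully connected network trained on CPU; for feature
  counts far beyond a few hundred, the architecture overrides (latent size,
  hidden widths) matter for run time.
- kBET and the kNN batch-prediction score depend on Euclidean geometry of
  standardized features; they are insensitive to batch effects that preserve
  local neighborhood composition.
- Problem sizes in the test and acceptance suites (n ≈ 100–300, p ≤ 62,
  50–800 Monte-Carlo replicates) were chosen to keep the suites desk-scale;
  all statistical checks are formulated so that larger runs only tighten
  them.
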