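# deepcombat

Multivariate batch-effect harmonization for subject × feature matrices,
combining a conditional variational autoencoder (CVAE) with the ComBat
empirical-Bayes model.

## The problem

Feature matrices pooled across acquisition batches — MRI scanners, sites,
protocols, sequencing runs — carry technical ("batch") variation on top of
the biology of interest. Classical ComBat removes batch effects one feature
at a time, as an additive shift in the conditional mean and a multiplicative
change in residual variance. That is often enough for mass-univariate
inference, but multivariate models (and modern ML classifiers) can still
recover batch from the joint distribution of features after univariate
correction.

This package harmonizes *multivariately*: a CVAE learns a low-dimensional
subject representation conditioned on biology and batch, and the ComBat
model is applied where batch information actually lives — in the latent
space, in the decoder's batch conditioning, and in the reconstruction
residuals. Residuals are added back, so harmonization never replaces data
with smooth synthetic reconstructions, and mapping a subject to its own
batch is exactly the identity.

## The model

ComBat models feature k of subject j in batch i as

    y_ijk = α_k + x_ij' β_k + γ_ik + δ_ik e_ijk,   e_ijk ~ N(0, σ_k²),

with empirical-Bayes shrinkage of the per-feature batch effects γ̂_ik, δ̂²_ik
toward cross-feature priors (normal and inverse-gamma, method-of-moments
hyperparameters), and adjustment

    y_ijk^ComBat = α̂_k + x_ij' β̂_k + (y_ijk − ŷ_ijk) / δ*_ik ,
    ŷ_ijk = α̂_k + x_ij' β̂_k + γ*_ik .

The CVAE encodes [y, x, b] (features, biological covariates, batch one-hot)
through four TanH hidden layers into z ~ N(μ, diag σ²) with latent width
≈ p/4 rounded to the nearest power of 2, and decodes [z, x, b] back to
feature space. Training minimizes, summed over subjects,

    L = Σ_k (y_k − ŷ_k)² + λ · D_KL( N(μ, diag σ²) ‖ N(0, I) ),

with λ cyclically annealed (5 epochs at 0, six 5-epoch linear ramps to
λ_final = 0.1, then 5 epochs at λ_final) to avoid posterior collapse; Adam,
learning rate 0.01, minibatches of 64.

Harmonization then (1) runs ComBat on the n × d matrix of latent means μ,
(2) decodes the harmonized latents conditioned on a common reference batch,
and (3) adds back ComBat-harmonized reconstruction residuals, inverting the
feature standardization at the end. External (out-of-sample) harmonization
uses 10-fold cross-fitting with AdamW.

## Worked example

```python
import numpy as np
from deepcombat import (DeepComBat, make_fixture, featurewise_batch_lrt,
                        manova_pillai, kbet)

# synthetic 3-batch cohort (n=300, p=62) with additive + scale batch effects
Y, covariates, batch, truth = make_fixture("additive+scale")

model = DeepComBat(lambda_final=0.1, seed=0).fit(
    Y, covariates=covariates.to_numpy(), batch=batch)
harmonized = model.transform(Y, covariates=covariates.to_numpy(), batch=batch)

X = covariates.to_numpy()
for label, data in [("raw", Y), ("harmonized", harmonized)]:
    lrt = featurewise_batch_lrt(data, X, batch)
    mv = manova_pillai(data, X, batch)
    kb = kbet(data, batch, rng=0)
    print(f"{label:>10}: batch LRT -log10 p = {lrt['batch_mean_neglog10_p']:.2f}, "
          f"Pillai -log10 p = {mv['batch']['neglog10_p']:.2f}, "
          f"kBET rejection = {kb.rejection_rate:.3f} (null {kb.expected_rate:.3f})")
```

Output:

```
       raw: batch LRT -log10 p = 8.43, Pillai -log10 p = 225.52, kBET rejection = 0.645 (null 0.041)
harmonized: batch LRT -log10 p = 0.07, Pillai -log10 p = 0.00, kBET rejection = 0.007 (null 0.040)
```

Reading this: on the raw data every batch test is overwhelmingly significant
(−log10 p ≫ 1.3, the 0.05 threshold) and local neighborhoods are batch-pure
(kBET rejects 64% of neighborhoods vs. 4% expected under perfect mixing).
After harmonization all batch tests drop below significance and kBET mixing
matches its null expectation, while covariate effects (age, sex, diagnosis)
remain essentially unchanged — e.g. the age −log10 p moves only from 8.69 to
8.44 in the same run.

A command-line interface mirrors the library:

```bash
deepcombat simulate --fixture additive+scale --out-prefix data/sim
deepcombat fit --features data/sim_features.csv --covariates data/sim_covariates.csv \
               --model-out model.npz --trace-out trace.csv
deepcombat apply --features data/sim_features.csv --covariates data/sim_covariates.csv \
                 --model model.npz --out harmonized.csv
deepcombat evaluate --features harmonized.csv --covariates data/sim_covariates.csv
```

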