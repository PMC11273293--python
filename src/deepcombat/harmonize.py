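"""The DeepComBat harmonization pipeline.

Pipeline (fit): (1) rescale biological covariates to [0, 1] and standardize
each feature to mean 0 / variance 1; (2) train the CVAE on [y, x, b];
(3) compute every subject's noiseless latent mean mu; (4) fit ComBat on the
n x d latent-mean matrix with batch and biological covariates; (5) compute
noiseless reconstructions decode(mu, x, b) and their residuals from the
normalized data; (6) fit ComBat on the n x p residual matrix.

Pipeline (transform): harmonize the latent means with latent ComBat, decode
them conditioned on the target batch indicator, add the ComBat-harmonized
reconstruction residuals, and invert the feature standardization.  Because
the residuals are reintroduced, harmonizing a subject back to its own batch
is exactly the identity, and harmonized output retains natural noise
characteristics rather than looking like synthetic decoder output.

The split of batch effects across latent space, decoder conditioning, and
residuals yields a form of double robustness: if the KL weight is so large
that the latent code collapses, residual ComBat still removes feature-wise
batch effects; if it is so small that the latent code soaks up everything,
latent ComBat removes them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import StratifiedKFold

from . import combat as cb
from .cvae import CVAE, plan_architecture
from .training import TrainingConfig, train_cvae

__all__ = [
    "NormalizationTransforms",
    "normalize_inputs",
    "DeepComBat",
    "deepcombat_fit",
    "deepcombat_apply",
    "crossfit_harmonize",
]

_LATENT_VAR_EPS = 1e-10


@dataclass
class NormalizationTransforms:
    """Invertible column transforms: min/max for covariates, mean/SD for
    features (population SD, ddof=0)."""

    cov_min: np.ndarray
    cov_max: np.ndarray
    feat_mean: np.ndarray
    feat_sd: np.ndarray

    def normalize_covariates(self, X, warn_out_of_range: bool = False,
                             n_rows: int | None = None) -> np.ndarray:
        if X is None or self.cov_min.size == 0:
            if X is not None and np.asarray(X).size:
                raise ValueError(
                    "model was fitted without covariates but covariates were given"
                )
            return np.empty((n_rows if n_rows is not None else 0, 0))
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self.cov_min.size:
            raise ValueError(
                f"expected {self.cov_min.size} covariate column(s), got {X.shape[1]}"
            )
        out = (X - self.cov_min) / (self.cov_max - self.cov_min)
        if warn_out_of_range and (out.min() < -1e-9 or out.max() > 1 + 1e-9):
            warnings.warn(
                "covariate values outside the training range; extrapolating",
                RuntimeWarning,
            )
        return out

    def normalize_features(self, Y) -> np.ndarray:
        return (np.asarray(Y, dtype=float) - self.feat_mean) / self.feat_sd

    def denormalize_features(self, Y_norm) -> np.ndarray:
        return np.asarray(Y_norm, dtype=float) * self.feat_sd + self.feat_mean

    def to_arrays(self, prefix: str = "norm/") -> dict:
        return {
            f"{prefix}cov_min": self.cov_min,
            f"{prefix}cov_max": self.cov_max,
            f"{prefix}feat_mean": self.feat_mean,
            f"{prefix}feat_sd": self.feat_sd,
        }

    @classmethod
    def from_arrays(cls, arrays: dict, prefix: str = "norm/") -> "NormalizationTransforms":
        return cls(
            cov_min=np.asarray(arrays[f"{prefix}cov_min"]),
            cov_max=np.asarray(arrays[f"{prefix}cov_max"]),
            feat_mean=np.asarray(arrays[f"{prefix}feat_mean"]),
            feat_sd=np.asarray(arrays[f"{prefix}feat_sd"]),
        )


def normalize_inputs(Y, X):
    """Scale covariates to [0, 1] and features to mean 0 / variance 1.

    Returns (Y_norm, X_norm, transforms).  Constant columns are rejected:
    they cannot be standardized invertibly.
    """
    Y = np.asarray(Y, dtype=float)
    feat_mean = Y.mean(axis=0)
    feat_sd = Y.std(axis=0)
    if np.any(feat_sd == 0):
        raise ValueError(
            f"constant feature column(s): {np.flatnonzero(feat_sd == 0).tolist()}"
        )
    if X is None:
        cov_min = cov_max = np.empty(0)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        cov_min = X.min(axis=0)
        cov_max = X.max(axis=0)
        if np.any(cov_max == cov_min):
            raise ValueError(
                f"constant covariate column(s): "
                f"{np.flatnonzero(cov_max == cov_min).tolist()}"
            )
    tf = NormalizationTransforms(cov_min, cov_max, feat_mean, feat_sd)
    return tf.normalize_features(Y), tf.normalize_covariates(X, n_rows=Y.shape[0]), tf


def _onehot(batch, levels) -> np.ndarray:
    pos = {lv: i for i, lv in enumerate(levels)}
    batch = np.asarray(batch)
    try:
        idx = np.array([pos[b] for b in batch])
    except KeyError as exc:
        raise ValueError(f"unseen batch level: {exc.args[0]!r}") from None
    out = np.zeros((batch.shape[0], len(levels)))
    out[np.arange(batch.shape[0]), idx] = 1.0
    return out


class DeepComBat(BaseEstimator, TransformerMixin):
    """CVAE + ComBat multivariate harmonizer.

    Parameters
    ----------
    lambda_final : float
        Final KL weight of the cyclic annealing schedule (default 0.1).
    schedule : {"cyclic", "constant"}
        KL-weight schedule over the 5 + 30 + 5 training epochs.
    optimizer : {"adam", "adamw"}
        Adam for internal harmonization; AdamW (decoupled weight decay 0.01)
        for external/cross-fit use.
    latent_dim, hidden_sizes : optional overrides of the architecture rule
        (latent ~ p/4 rounded to a power of 2; four TanH hidden layers whose
        widths interpolate between p and the latent width).
    eb : bool
        Empirical-Bayes shrinkage in the latent and residual ComBat fits.
    reference_batch : batch level or None
        The batch indicator handed to the decoder for pooled harmonization;
        defaults to the largest batch.
    seed : int
        Master seed for weight initialization, shuffling, and latent draws.

    Fitted attributes (trailing underscore): ``transforms_``, ``cvae_``,
    ``cvae_config_``, ``latent_combat_``, ``residual_combat_``,
    ``batch_levels_``, ``reference_batch_``, ``loss_trace_``, ``mu_``,
    ``residuals_``.
    """

    def __init__(self, lambda_final: float = 0.1, schedule: str = "cyclic",
                 optimizer: str = "adam", learning_rate: float = 0.01,
                 weight_decay: float = 0.01, minibatch_size: int = 64,
                 latent_dim: int | None = None, hidden_sizes=None,
                 eb: bool = True, reference_batch=None, seed: int = 0):
        self.lambda_final = lambda_final
        self.schedule = schedule
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.minibatch_size = minibatch_size
        self.latent_dim = latent_dim
        self.hidden_sizes = hidden_sizes
        self.eb = eb
        self.reference_batch = reference_batch
        self.seed = seed

    # ------------------------------------------------------------------ fit
    def fit(self, X, y=None, *, covariates=None, batch):
        Y = np.asarray(X, dtype=float)
        n, p = Y.shape
        batch = np.asarray(batch)
        levels, idx, counts = cb._batch_info(batch, n)
        if levels.size < 2:
            raise ValueError("harmonization requires at least 2 batches")
        if np.any(counts < 2):
            bad = levels[counts < 2]
            raise ValueError(
                f"every batch needs at least 2 subjects; too small: {list(bad)}"
            )
        Y_norm, X_norm, tf = normalize_inputs(Y, covariates)
        q = X_norm.shape[1]
        onehot = _onehot(batch, levels)

        config = plan_architecture(p, q, levels.size,
                                   latent_dim=self.latent_dim,
                                   hidden_sizes=self.hidden_sizes)
        tcfg = TrainingConfig(
            lambda_final=self.lambda_final, schedule=self.schedule,
            optimizer=self.optimizer, learning_rate=self.learning_rate,
            weight_decay=self.weight_decay, minibatch_size=self.minibatch_size,
            seed=self.seed,
        )
        model, trace = train_cvae(Y_norm, X_norm, onehot, config, tcfg)

        mu, _ = model.encode(Y_norm, X_norm, onehot)
        active = mu.var(axis=0) > _LATENT_VAR_EPS
        if not np.any(active):
            warnings.warn(
                "all latent dimensions are near-constant (posterior collapse / "
                "KL vanishing); latent ComBat is skipped and all batch "
                "adjustment falls to the residual step",
                RuntimeWarning,
            )
            latent_combat = None
        else:
            if np.count_nonzero(active) < mu.shape[1]:
                warnings.warn(
                    f"{np.count_nonzero(~active)} latent dimension(s) collapsed "
                    "(KL vanishing); they are passed through unadjusted",
                    RuntimeWarning,
                )
            eb_latent = self.eb and np.count_nonzero(active) >= 2
            latent_combat = cb.fit_combat(mu[:, active], X_norm, batch,
                                          eb_enabled=eb_latent)

        recon = model.decode(mu, X_norm, onehot)
        resid = Y_norm - recon
        residual_combat = cb.fit_combat(resid, X_norm, batch, eb_enabled=self.eb)

        self.transforms_ = tf
        self.cvae_ = model
        self.cvae_config_ = config
        self.training_config_ = tcfg
        self.latent_combat_ = latent_combat
        self.latent_active_ = active
        self.residual_combat_ = residual_combat
        self.batch_levels_ = levels
        self.loss_trace_ = trace
        self.mu_ = mu
        self.residuals_ = resid
        self.n_features_in_ = p
        if self.reference_batch is not None:
            if self.reference_batch not in levels:
                raise ValueError(
                    f"reference_batch {self.reference_batch!r} not among "
                    f"batch levels {list(levels)}"
                )
            self.reference_batch_ = self.reference_batch
        else:
            self.reference_batch_ = levels[np.argmax(counts)]
        return self

    # ------------------------------------------------------------ transform
    def transform(self, X, *, covariates=None, batch, target_batch="pooled"):
        """Harmonize a feature matrix.

        ``target_batch="pooled"`` removes batch effects toward the pooled
        distribution (decoder conditioned on ``reference_batch_``);
        ``target_batch=<level>`` maps subjects into that batch's
        distribution; ``target_batch="self"`` is the identity map.
        """
        if not hasattr(self, "cvae_"):
            raise RuntimeError("DeepComBat instance is not fitted yet")
        Y = np.asarray(X, dtype=float)
        n, p = Y.shape
        if p != self.n_features_in_:
            raise ValueError(f"fitted with p={self.n_features_in_}, got p={p}")
        batch = np.asarray(batch)
        tf = self.transforms_
        X_norm = tf.normalize_covariates(covariates, warn_out_of_range=True,
                                         n_rows=n)
        if X_norm.shape[1] != self.cvae_config_.covariate_dim:
            raise ValueError(
                f"fitted with q={self.cvae_config_.covariate_dim} covariates, "
                f"got q={X_norm.shape[1]}"
            )
        Y_norm = tf.normalize_features(Y)
        onehot = _onehot(batch, self.batch_levels_)

        mu, _ = self.cvae_.encode(Y_norm, X_norm, onehot)
        recon = self.cvae_.decode(mu, X_norm, onehot)
        resid = Y_norm - recon

        if target_batch == "self":
            mu_cb, resid_cb, dec_onehot = mu, resid, onehot
        else:
            combat_target = "pooled" if target_batch == "pooled" else target_batch
            mu_cb = mu.copy()
            if self.latent_combat_ is not None:
                mu_cb[:, self.latent_active_] = cb.apply_combat(
                    mu[:, self.latent_active_], X_norm, batch,
                    self.latent_combat_, target=combat_target,
                )
            resid_cb = cb.apply_combat(resid, X_norm, batch,
                                       self.residual_combat_, target=combat_target)
            dec_level = (self.reference_batch_ if target_batch == "pooled"
                         else target_batch)
            dec_onehot = _onehot(np.repeat(dec_level, n), self.batch_levels_)

        out_norm = self.cvae_.decode(mu_cb, X_norm, dec_onehot) + resid_cb
        return tf.denormalize_features(out_norm)

    def fit_transform(self, X, y=None, *, covariates=None, batch,
                      target_batch="pooled"):
        return self.fit(X, covariates=covariates, batch=batch).transform(
            X, covariates=covariates, batch=batch, target_batch=target_batch
        )


def deepcombat_fit(Y, covariates, batch, **kwargs) -> DeepComBat:
    """Functional wrapper: fit a :class:`DeepComBat` model."""
    return DeepComBat(**kwargs).fit(Y, covariates=covariates, batch=batch)


def deepcombat_apply(model: DeepComBat, Y, covariates, batch,
                     target_batch="pooled") -> np.ndarray:
    """Functional wrapper around :meth:`DeepComBat.transform`."""
    return model.transform(Y, covariates=covariates, batch=batch,
                           target_batch=target_batch)


def crossfit_harmonize(Y, covariates, batch, k: int = 10, seed: int = 0,
                       return_models: bool = False, **estimator_kwargs):
    """External harmonization by k-fold cross-fitting.

    Subjects are partitioned into ``k`` batch-stratified folds; each fold is
    harmonized by a model trained on the other folds (AdamW optimizer), so
    every subject is harmonized exactly once, out of sample.  Requires every
    batch to contain at least ``k`` subjects so each training fold sees every
    batch.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    batch = np.asarray(batch)
    covariates = None if covariates is None else np.asarray(covariates, dtype=float)
    levels, idx, counts = cb._batch_info(batch, n)
    if np.any(counts < k):
        bad = levels[counts < k]
        raise ValueError(
            f"every batch needs >= k={k} subjects for stratified cross-fit; "
            f"too small: {list(bad)}"
        )
    estimator_kwargs.setdefault("optimizer", "adamw")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    out = np.empty_like(Y)
    models = []
    for fold, (tr, te) in enumerate(skf.split(Y, idx)):
        model = DeepComBat(seed=seed + fold, **estimator_kwargs)
        cov_tr = None if covariates is None else covariates[tr]
        cov_te = None if covariates is None else covariates[te]
        model.fit(Y[tr], covariates=cov_tr, batch=batch[tr])
        out[te] = model.transform(Y[te], covariates=cov_te, batch=batch[te])
        models.append(model)
    if return_models:
        return out, models
    return out
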