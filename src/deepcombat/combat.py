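"""Empirical-Bayes location/scale batch-effect model (ComBat).

ComBat models each feature k of subject j in batch i as

    y_ijk = alpha_k + x_ij' beta_k + gamma_ik + delta_ik * e_ijk,
    e_ijk ~ N(0, sigma_k^2),

where gamma_ik is an additive (mean) batch effect conditional on the
biological covariates x_ij and delta_ik a multiplicative batch effect on the
residual scale.  Per-feature estimates of gamma and delta^2 are stabilized by
empirical-Bayes shrinkage toward cross-feature priors (normal for gamma,
inverse-gamma for delta^2) whose hyperparameters are estimated by the method
of moments across features; the shrunk estimates are the means of the
conditional posterior distributions, obtained by fixed-point iteration.

The same model is reused in this package on raw features, on CVAE latent
means, and on CVAE reconstruction residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ComBatModel",
    "ComBat",
    "fit_feature_models",
    "standardize_features",
    "estimate_priors",
    "eb_posterior",
    "fit_combat",
    "apply_combat",
]


class IdentifiabilityError(ValueError):
    """Design matrix is rank deficient; batch and covariates are confounded."""


@dataclass
class ComBatModel:
    """Fitted ComBat parameters.

    Location/scale estimates are stored in the original feature units for
    ``alpha``/``beta``/``gamma``; ``delta_sq`` terms are variance ratios of
    standardized residuals (unitless).  ``gamma_star``/``delta_sq_star`` are
    the EB posterior means; with ``eb_enabled=False`` they equal the raw
    estimates.
    """

    batch_levels: np.ndarray
    counts: np.ndarray                 # n_i per batch level
    alpha: np.ndarray                  # (p,) shared intercepts
    beta: np.ndarray                   # (q, p) covariate coefficients
    sigma_sq: np.ndarray               # (p,) pooled residual variances
    gamma_hat: np.ndarray              # (B, p) raw additive effects, original units
    gamma_star: np.ndarray             # (B, p) EB-shrunk additive effects
    delta_sq_hat: np.ndarray           # (B, p) raw residual-variance ratios
    delta_sq_star: np.ndarray          # (B, p) EB-shrunk variance ratios
    priors: dict = field(default_factory=dict)
    eb_enabled: bool = True
    n_features: int = 0
    n_covariates: int = 0

    def to_arrays(self, prefix: str = "") -> dict:
        """Flatten into a ``key -> array`` mapping for archiving."""
        out = {
            f"{prefix}batch_levels": np.asarray(self.batch_levels, dtype=str),
            f"{prefix}counts": self.counts,
            f"{prefix}alpha": self.alpha,
            f"{prefix}beta": self.beta,
            f"{prefix}sigma_sq": self.sigma_sq,
            f"{prefix}gamma_hat": self.gamma_hat,
            f"{prefix}gamma_star": self.gamma_star,
            f"{prefix}delta_sq_hat": self.delta_sq_hat,
            f"{prefix}delta_sq_star": self.delta_sq_star,
            f"{prefix}eb_enabled": np.array([int(self.eb_enabled)]),
        }
        for key in ("gamma_bar", "tau_bar_sq", "lambda_", "theta", "scale_eb"):
            if key in self.priors:
                out[f"{prefix}prior_{key}"] = np.asarray(self.priors[key], dtype=float)
        return out

    @classmethod
    def from_arrays(cls, arrays: dict, prefix: str = "") -> "ComBatModel":
        priors = {}
        for key in ("gamma_bar", "tau_bar_sq", "lambda_", "theta", "scale_eb"):
            pk = f"{prefix}prior_{key}"
            if pk in arrays:
                priors[key] = np.asarray(arrays[pk])
        return cls(
            batch_levels=np.asarray(arrays[f"{prefix}batch_levels"]),
            counts=np.asarray(arrays[f"{prefix}counts"]),
            alpha=np.asarray(arrays[f"{prefix}alpha"]),
            beta=np.asarray(arrays[f"{prefix}beta"]),
            sigma_sq=np.asarray(arrays[f"{prefix}sigma_sq"]),
            gamma_hat=np.asarray(arrays[f"{prefix}gamma_hat"]),
            gamma_star=np.asarray(arrays[f"{prefix}gamma_star"]),
            delta_sq_hat=np.asarray(arrays[f"{prefix}delta_sq_hat"]),
            delta_sq_star=np.asarray(arrays[f"{prefix}delta_sq_star"]),
            priors=priors,
            eb_enabled=bool(arrays[f"{prefix}eb_enabled"][0]),
            n_features=int(np.asarray(arrays[f"{prefix}alpha"]).shape[0]),
            n_covariates=int(np.asarray(arrays[f"{prefix}beta"]).shape[0]),
        )


def _as_matrix(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError(f"expected a 2-D feature matrix, got shape {Y.shape}")
    if not np.all(np.isfinite(Y)):
        raise ValueError("feature matrix contains non-finite values")
    return Y


def _batch_info(batch, n: int):
    batch = np.asarray(batch)
    if batch.shape[0] != n:
        raise ValueError("batch labels not aligned with feature matrix rows")
    levels, idx = np.unique(batch, return_inverse=True)
    counts = np.bincount(idx, minlength=levels.size)
    return levels, idx, counts


def _covariate_matrix(X, n: int) -> np.ndarray:
    if X is None:
        return np.empty((n, 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError("covariate design not aligned with feature matrix rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("covariate design contains non-finite values")
    return X


def fit_feature_models(Y, X, batch):
    """Least-squares stage: per-feature alpha, beta, gamma_hat, sigma_sq.

    The joint design is ``[batch one-hot | X]`` (the intercept lives in the
    span of the batch indicators).  The shared intercept alpha_k is the
    sample-size-weighted mean of the per-batch intercepts, which enforces the
    identifiability constraint ``sum_i n_i gamma_hat_ik = 0``.
    """
    Y = _as_matrix(Y)
    n, p = Y.shape
    levels, idx, counts = _batch_info(batch, n)
    if np.any(counts < 2):
        bad = levels[counts < 2]
        raise ValueError(f"every batch needs at least 2 subjects; too small: {list(bad)}")
    X = _covariate_matrix(X, n)
    B, q = levels.size, X.shape[1]

    onehot = np.zeros((n, B))
    onehot[np.arange(n), idx] = 1.0
    design = np.hstack([onehot, X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name offending covariate columns (those not adding rank beyond batch)
        bad_cols = []
        base = onehot
        for j in range(q):
            cand = np.hstack([base, X[:, j : j + 1]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                bad_cols.append(j)
            else:
                base = cand
        raise IdentifiabilityError(
            "design matrix [batch | covariates] is rank deficient; "
            f"covariate column(s) {bad_cols} are collinear with batch/intercept"
        )

    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    batch_int = coef[:B]                      # (B, p) per-batch intercepts
    beta = coef[B:]                           # (q, p)
    alpha = (counts / n) @ batch_int          # weighted grand mean
    gamma_hat = batch_int - alpha             # sum_i n_i gamma_hat = 0
    resid = Y - design @ coef
    sigma_sq = np.mean(resid**2, axis=0)      # pooled, denominator n
    degenerate = sigma_sq <= 1e-24 * (np.mean(Y**2, axis=0) + np.finfo(float).tiny)
    if np.any(degenerate):
        sigma_sq = np.where(degenerate, 0.0, sigma_sq)
        warnings.warn(
            f"features with zero residual variance (degenerate fit): "
            f"{np.flatnonzero(degenerate).tolist()}",
            RuntimeWarning,
        )
    return ComBatModel(
        batch_levels=levels,
        counts=counts,
        alpha=alpha,
        beta=beta,
        sigma_sq=sigma_sq,
        gamma_hat=gamma_hat,
        gamma_star=gamma_hat.copy(),
        delta_sq_hat=np.ones((B, p)),
        delta_sq_star=np.ones((B, p)),
        eb_enabled=False,
        n_features=p,
        n_covariates=q,
    )


def standardize_features(Y, model: ComBatModel, X, batch) -> np.ndarray:
    """Standardized residual-plus-batch matrix Z = (Y - alpha - X beta) / sigma.

    The per-batch mean of Z equals gamma_hat / sigma; its pooled variance is
    approximately 1 by construction.
    """
    Y = _as_matrix(Y)
    n, p = Y.shape
    if p != model.n_features:
        raise ValueError(f"model fitted with p={model.n_features}, got p={p}")
    X = _covariate_matrix(X, n)
    if X.shape[1] != model.n_covariates:
        raise ValueError(
            f"model fitted with q={model.n_covariates} covariates, got q={X.shape[1]}"
        )
    if np.any(model.sigma_sq <= 0):
        bad = np.flatnonzero(model.sigma_sq <= 0).tolist()
        raise ValueError(f"cannot standardize constant features (sigma=0): {bad}")
    sigma = np.sqrt(model.sigma_sq)
    return (Y - model.alpha - X @ model.beta) / sigma


def estimate_priors(gamma_hat, delta_sq_hat) -> dict:
    """Method-of-moments hyperparameters of the EB priors.

    Normal prior on additive effects: per batch i, ``gamma_bar_i`` and
    ``tau_bar_sq_i`` are the mean and variance of gamma_hat across features.
    Inverse-gamma prior on variance ratios: (lambda_i, theta_i) solve the
    mean/variance moment equations ``mean = theta/(lambda-1)``,
    ``var = theta^2 / ((lambda-1)^2 (lambda-2))``.

    gamma_hat here is on the standardized scale (gamma_hat / sigma).
    """
    gamma_hat = np.asarray(gamma_hat, dtype=float)
    delta_sq_hat = np.asarray(delta_sq_hat, dtype=float)
    B, p = gamma_hat.shape
    if p < 2:
        raise ValueError("prior estimation needs at least 2 features (moments across features)")
    gamma_bar = gamma_hat.mean(axis=1)
    tau_bar_sq = gamma_hat.var(axis=1, ddof=1)
    m = delta_sq_hat.mean(axis=1)
    s2 = delta_sq_hat.var(axis=1, ddof=1)
    lambda_ = np.full(B, np.nan)
    theta = np.full(B, np.nan)
    scale_eb = np.ones(B, dtype=bool)
    for i in range(B):
        if s2[i] == 0:
            warnings.warn(
                f"batch {i}: zero variance of delta_sq across features; "
                "inverse-gamma moments undefined, disabling scale shrinkage",
                RuntimeWarning,
            )
            scale_eb[i] = False
            continue
        lam = (2 * s2[i] + m[i] ** 2) / s2[i]           # = 2 + m^2/s2
        th = (m[i] * s2[i] + m[i] ** 3) / s2[i]         # = m (lam - 1)
        if lam <= 2:
            warnings.warn(
                f"batch {i}: degenerate inverse-gamma prior (lambda <= 2); "
                "disabling scale shrinkage",
                RuntimeWarning,
            )
            scale_eb[i] = False
            continue
        lambda_[i], theta[i] = lam, th
    return {
        "gamma_bar": gamma_bar,
        "tau_bar_sq": tau_bar_sq,
        "lambda_": lambda_,
        "theta": theta,
        "scale_eb": scale_eb.astype(float),
    }


def eb_posterior(Z, gamma_hat, delta_sq_hat, priors, batch_idx, counts,
                 tol: float = 1e-4, max_iter: int = 500):
    """Iterated conditional posterior means for (gamma*, delta^2*).

    Alternates the closed-form conditional updates

        gamma*_ik  = (n_i tau^2_i gamma_hat_ik + delta^2*_ik gamma_bar_i)
                     / (n_i tau^2_i + delta^2*_ik)
        delta^2*_ik = (theta_i + 0.5 sum_j (Z_ijk - gamma*_ik)^2)
                     / (n_i / 2 + lambda_i - 1)

    until the largest absolute parameter change drops below ``tol``.
    All quantities are on the standardized (sigma-unit) scale.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    Z = np.asarray(Z, dtype=float)
    gamma_hat = np.asarray(gamma_hat, dtype=float)
    delta_sq_hat = np.asarray(delta_sq_hat, dtype=float)
    B, p = gamma_hat.shape
    gamma_star = gamma_hat.copy()
    delta_sq_star = delta_sq_hat.copy()
    gamma_bar = priors["gamma_bar"]
    tau_bar_sq = priors["tau_bar_sq"]
    lambda_ = priors["lambda_"]
    theta = priors["theta"]
    scale_eb = priors.get("scale_eb", np.ones(B)).astype(bool)

    for i in range(B):
        rows = Z[batch_idx == i]
        n_i = counts[i]
        g_new = gamma_hat[i].copy()
        d_new = delta_sq_hat[i].copy()
        converged = False
        for _ in range(max_iter):
            g_old, d_old = g_new, d_new
            denom = n_i * tau_bar_sq[i] + d_old
            if tau_bar_sq[i] == 0:
                g_new = np.full(p, gamma_bar[i])
            else:
                g_new = (n_i * tau_bar_sq[i] * gamma_hat[i] + d_old * gamma_bar[i]) / denom
            if scale_eb[i]:
                sum2 = np.sum((rows - g_new) ** 2, axis=0)
                d_new = (theta[i] + 0.5 * sum2) / (n_i / 2 + lambda_[i] - 1)
            else:
                d_new = delta_sq_hat[i]
            change = max(np.max(np.abs(g_new - g_old)), np.max(np.abs(d_new - d_old)))
            if change < tol:
                converged = True
                break
        if not converged:
            raise RuntimeError(
                f"EB posterior iteration did not converge for batch {i} "
                f"after {max_iter} iterations (last change {change:.3g})"
            )
        gamma_star[i] = g_new
        delta_sq_star[i] = d_new
    if np.any(delta_sq_star <= 0) or not np.all(np.isfinite(gamma_star)):
        raise RuntimeError("EB posterior produced non-finite or non-positive estimates")
    return gamma_star, delta_sq_star


def fit_combat(Y, X, batch, eb_enabled: bool = True,
               tol: float = 1e-4, max_iter: int = 500) -> ComBatModel:
    """Full ComBat fit: least squares, standardization, per-batch moments,
    prior estimation, and EB posterior means (skipped if ``eb_enabled`` is
    False)."""
    Y = _as_matrix(Y)
    n, p = Y.shape
    levels, idx, counts = _batch_info(batch, n)
    if levels.size < 2:
        raise ValueError("ComBat requires at least 2 batches")
    model = fit_feature_models(Y, X, batch)
    Z = standardize_features(Y, model, X, batch)
    sigma = np.sqrt(model.sigma_sq)
    B = levels.size
    gamma_hat_std = model.gamma_hat / sigma
    delta_sq_hat = np.empty((B, p))
    for i in range(B):
        delta_sq_hat[i] = Z[idx == i].var(axis=0)      # within-batch, ddof=0
    model.delta_sq_hat = delta_sq_hat
    model.delta_sq_star = delta_sq_hat.copy()
    if eb_enabled:
        priors = estimate_priors(gamma_hat_std, delta_sq_hat)
        gamma_star_std, delta_sq_star = eb_posterior(
            Z, gamma_hat_std, delta_sq_hat, priors, idx, counts,
            tol=tol, max_iter=max_iter,
        )
        model.priors = priors
        model.gamma_star = gamma_star_std * sigma
        model.delta_sq_star = delta_sq_star
        model.eb_enabled = True
    else:
        model.gamma_star = model.gamma_hat.copy()
        model.delta_sq_star = delta_sq_hat.copy()
        model.eb_enabled = False
    return model


def apply_combat(Y, X, batch, model: ComBatModel, target="pooled") -> np.ndarray:
    """Remove estimated batch effects.

    ``target="pooled"`` maps every subject to the batch-free distribution:
    y_adj = alpha + X beta + sigma * (Z - gamma*_i/sigma) / delta*_i.
    ``target=<level>`` additionally re-adds that batch's shrunk effects so
    the output lives in the target batch's distribution; ``target="self"``
    uses each subject's own batch (an identity map).
    """
    Y = _as_matrix(Y)
    n, p = Y.shape
    batch = np.asarray(batch)
    levels = model.batch_levels
    level_pos = {lv: i for i, lv in enumerate(levels)}
    try:
        idx = np.array([level_pos[b] for b in batch])
    except KeyError as exc:
        raise ValueError(f"unseen batch level at apply time: {exc.args[0]!r}") from None
    X = _covariate_matrix(X, n)
    Z = standardize_features(Y, model, X, batch)
    sigma = np.sqrt(model.sigma_sq)
    gamma_star_std = model.gamma_star / sigma
    delta_star = np.sqrt(model.delta_sq_star)
    adj = (Z - gamma_star_std[idx]) / delta_star[idx]
    if target == "pooled":
        pass
    elif target == "self":
        adj = gamma_star_std[idx] + delta_star[idx] * adj
    else:
        if target not in level_pos:
            raise ValueError(f"unknown target batch level: {target!r}")
        t = level_pos[target]
        adj = gamma_star_std[t] + delta_star[t] * adj
    return model.alpha + X @ model.beta + sigma * adj


class ComBat(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper around the ComBat location/scale model.

    Parameters
    ----------
    eb : bool
        Use empirical-Bayes shrinkage of per-feature batch effects (default).
    tol, max_iter : float, int
        Convergence control for the EB posterior-mean iteration.
    target : str
        Default harmonization target for :meth:`transform`: ``"pooled"``,
        ``"self"``, or a batch level.

    Examples
    --------
    >>> cb = ComBat().fit(Y, batch=site, covariates=X)
    >>> Y_harm = cb.transform(Y, batch=site, covariates=X)
    """

    def __init__(self, eb: bool = True, tol: float = 1e-4, max_iter: int = 500,
                 target="pooled"):
        self.eb = eb
        self.tol = tol
        self.max_iter = max_iter
        self.target = target

    def fit(self, X, y=None, *, batch, covariates=None):
        self.model_ = fit_combat(X, covariates, batch, eb_enabled=self.eb,
                                 tol=self.tol, max_iter=self.max_iter)
        self.n_features_in_ = self.model_.n_features
        return self

    def transform(self, X, *, batch, covariates=None, target=None):
        if not hasattr(self, "model_"):
            raise RuntimeError("ComBat instance is not fitted yet")
        target = self.target if target is None else target
        return apply_combat(X, covariates, batch, self.model_, target=target)

    def fit_transform(self, X, y=None, *, batch, covariates=None, target=None):
        return self.fit(X, batch=batch, covariates=covariates).transform(
            X, batch=batch, covariates=covariates, target=target
        )
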