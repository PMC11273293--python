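"""Statistical audit battery for harmonization quality.

Four complementary views of residual batch signal:

* feature-wise two-sample Anderson-Darling tests between batch pairs
  (marginal distributional differences);
* feature-wise Gaussian linear models with a likelihood-ratio test for batch
  (conditional mean differences, adjusting for biology) plus per-covariate
  t-tests (biological signal preservation);
* MANOVA with Pillai's trace (multivariate conditional mean differences);
* kBET, a k-nearest-neighbor mixing test: well-harmonized data have local
  batch compositions matching the global one, so the chi-squared rejection
  rate stays near its null level;

plus a lightweight cross-validated k-nearest-neighbor batch-prediction score
(a deliberately small stand-in for a full ML model battery): accuracy near
the majority-class baseline means classifiers cannot recover batch.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "ad_two_sample",
    "featurewise_batch_lrt",
    "manova_pillai",
    "kbet",
    "batch_prediction_score",
    "evaluate_harmonization",
    "KBETResult",
    "EvaluationReport",
]


# --------------------------------------------------------------------- AD --
def ad_two_sample(a, b):
    """Scholz-Stephens two-sample Anderson-Darling test.

    Returns (statistic, p).  The asymptotic p-value comes from the published
    interpolation table and is therefore clipped to [0.001, 0.25].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("each sample needs at least 5 observations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns when p hits the clip
        res = stats.anderson_ksamp([a, b], method=None)
    return float(res.statistic), float(res.significance_level)


# -------------------------------------------------------------------- LRT --
def _design_with_batch(X, batch, n):
    batch = np.asarray(batch)
    levels, idx = np.unique(batch, return_inverse=True)
    B = levels.size
    dummies = np.zeros((n, B - 1))
    for i in range(1, B):
        dummies[idx == i, i - 1] = 1.0
    if X is None:
        X = np.empty((n, 0))
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    intercept = np.ones((n, 1))
    full = np.hstack([intercept, X, dummies])
    reduced = np.hstack([intercept, X])
    return full, reduced, X.shape[1], B


def featurewise_batch_lrt(Y, X, batch, covariate_names=None) -> dict:
    """Per-feature linear model y ~ 1 + covariates + batch.

    Batch significance by likelihood-ratio test, LRT = n ln(RSS0/RSS1) with
    B-1 degrees of freedom (Gaussian profile likelihood); covariate
    significance by per-coefficient t-tests in the full model.  Returns the
    per-feature p-values plus the across-feature mean and SD of -log10 p.
    """
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    full, reduced, q, B = _design_with_batch(X, batch, n)
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("rank-deficient design (batch collinear with covariates)")
    coef1, *_ = np.linalg.lstsq(full, Y, rcond=None)
    rss1 = np.sum((Y - full @ coef1) ** 2, axis=0)
    coef0, *_ = np.linalg.lstsq(reduced, Y, rcond=None)
    rss0 = np.sum((Y - reduced @ coef0) ** 2, axis=0)
    lrt = n * np.log(np.maximum(rss0, 1e-300) / np.maximum(rss1, 1e-300))
    batch_p = stats.chi2.sf(lrt, df=B - 1)

    # covariate t-tests in the full model
    dof = n - full.shape[1]
    xtx_inv = np.linalg.inv(full.T @ full)
    se = np.sqrt(np.outer(np.diag(xtx_inv), rss1 / dof))
    tvals = coef1 / se
    cov_p = 2 * stats.t.sf(np.abs(tvals[1 : 1 + q]), df=dof)  # (q, p)

    tiny = np.finfo(float).tiny
    neglog = -np.log10(np.maximum(batch_p, tiny))
    if covariate_names is None:
        covariate_names = [f"cov{j}" for j in range(q)]
    cov_neglog = -np.log10(np.maximum(cov_p, tiny))
    return {
        "batch_p": batch_p,
        "batch_neglog10_p": neglog,
        "batch_mean_neglog10_p": float(neglog.mean()),
        "batch_sd_neglog10_p": float(neglog.std(ddof=1)) if p > 1 else 0.0,
        "covariate_p": {name: cov_p[j] for j, name in enumerate(covariate_names)},
        "covariate_mean_neglog10_p": {
            name: float(cov_neglog[j].mean()) for j, name in enumerate(covariate_names)
        },
        "coefficients": coef1,
        "df_batch": B - 1,
    }


# ----------------------------------------------------------------- MANOVA --
def _pillai_term(Bhat, D, E, cols, n):
    """Pillai trace + approximate F for the hypothesis that the given design
    columns are jointly zero in a multivariate linear model."""
    p = E.shape[0]
    m_cols = np.asarray(cols)
    L = np.zeros((m_cols.size, Bhat.shape[0]))
    L[np.arange(m_cols.size), m_cols] = 1.0
    xtx_inv = np.linalg.pinv(D.T @ D)
    LB = L @ Bhat
    H = LB.T @ np.linalg.solve(L @ xtx_inv @ L.T, LB)
    V = float(np.trace(np.linalg.solve((H + E).T, H.T).T))
    df_h = m_cols.size
    df_e = n - Bhat.shape[0]
    s = min(df_h, p)
    m = (abs(df_h - p) - 1) / 2.0
    n2 = (df_e - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n2 + s + 1)
    denom = s - V
    if denom <= 0:
        return V, np.inf, df1, df2, 0.0
    F = (df2 / df1) * (V / denom)
    pval = float(stats.f.sf(F, df1, df2))
    return V, float(F), df1, df2, pval


def manova_pillai(Y, X, batch, covariate_names=None) -> dict:
    """Multivariate linear model Y ~ 1 + covariates + batch; per-term Pillai
    trace with the standard F approximation.  Returns a dict keyed by term
    ("batch" plus one per covariate column)."""
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    full, _, q, B = _design_with_batch(X, batch, n)
    m = full.shape[1]
    if n <= p + m:
        raise ValueError(f"MANOVA needs n > p + model df ({n} <= {p + m})")
    Bhat, *_ = np.linalg.lstsq(full, Y, rcond=None)
    resid = Y - full @ Bhat
    E = resid.T @ resid
    if np.linalg.matrix_rank(E) < p:
        raise ValueError("singular residual SSCP matrix (E)")
    if covariate_names is None:
        covariate_names = [f"cov{j}" for j in range(q)]
    terms = {"batch": list(range(1 + q, m))}
    for j, name in enumerate(covariate_names):
        terms[name] = [1 + j]
    tiny = np.finfo(float).tiny
    out = {}
    for name, cols in terms.items():
        V, F, df1, df2, pval = _pillai_term(Bhat, full, E, cols, n)
        out[name] = {
            "pillai": V,
            "F": F,
            "df1": df1,
            "df2": df2,
            "p": pval,
            "neglog10_p": float(-np.log10(max(pval, tiny)) + 0.0),  # +0.0 avoids -0
        }
    return out


# ------------------------------------------------------------------- kBET --
@dataclass
class KBETResult:
    rejection_rate: float     # observed mean chi2 rejection rate over repeats
    expected_rate: float      # mean rate under label-permutation null
    p_value: float            # one-sided permutation p for the observed rate
    k0: int
    alpha: float
    n_repeats: int
    n_permutations: int


def _neighbor_counts(Y_std, batch_idx, B, k0):
    nn = NearestNeighbors(n_neighbors=k0 + 1).fit(Y_std)
    _, ind = nn.kneighbors(Y_std)
    ind = ind[:, 1:]                      # drop self
    onehot = np.zeros((batch_idx.size, B))
    onehot[np.arange(batch_idx.size), batch_idx] = 1.0
    return onehot[ind].sum(axis=1), ind   # (n, B) neighborhood batch counts


def _chi2_stats(counts, expected_props, k0):
    expected = expected_props * k0
    return np.sum((counts - expected) ** 2 / expected, axis=1)


def _chi2_pvals(counts, expected_props, k0, B):
    return stats.chi2.sf(_chi2_stats(counts, expected_props, k0), df=B - 1)


def kbet(Y, batch, n_repeats: int = 500, k0: int | None = None,
         subset_frac: float = 0.1, alpha: float = 0.05,
         n_permutations: int = 100, rng=None) -> KBETResult:
    """k-nearest-neighbor batch-effect test.

    Each repeat samples ``ceil(subset_frac * n)`` observations and, for each,
    compares the batch composition of its ``k0`` nearest neighbors
    (Euclidean, on standardized features, excluding the point itself) to the
    global batch proportions with a Pearson chi-squared test (df B-1).  The
    observed statistic is the mean rejection rate at level ``alpha`` across
    repeats; the expected rate and the one-sided overall p-value come from a
    batch-label permutation null.  Defaults: k0 = max(10, floor(0.1 n)),
    subset fraction 0.1.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    batch = np.asarray(batch)
    levels, idx = np.unique(batch, return_inverse=True)
    B = levels.size
    if B < 2:
        raise ValueError("kBET requires at least 2 batches")
    if k0 is None:
        k0 = max(10, int(0.1 * n))
    if k0 >= n:
        raise ValueError("k0 must be smaller than the number of observations")
    rng = np.random.default_rng(rng)

    sd = Y.std(axis=0)
    sd[sd == 0] = 1.0
    Y_std = (Y - Y.mean(axis=0)) / sd
    props = np.bincount(idx, minlength=B) / n

    counts, ind = _neighbor_counts(Y_std, idx, B, k0)
    pvals = _chi2_pvals(counts, props, k0, B)
    reject = pvals < alpha
    m = int(np.ceil(subset_frac * n))
    subsets = np.stack([rng.choice(n, size=m, replace=False)
                        for _ in range(n_repeats)])
    observed = float(np.mean(reject[subsets]))

    # permutation null: full-data rejection rates under shuffled labels,
    # compared with the full-data observed rate so both carry the same noise.
    # Rejection counts are discrete; ties are broken by the continuous mean
    # chi-squared statistic so the permutation p is exactly uniform under
    # the null.
    observed_full = float(reject.mean())
    observed_stat = float(_chi2_stats(counts, props, k0).mean())
    null_rates = np.empty(n_permutations)
    null_stats = np.empty(n_permutations)
    onehot = np.eye(B)
    for t in range(n_permutations):
        perm = rng.permutation(idx)
        c = onehot[perm][ind].sum(axis=1)
        s = _chi2_stats(c, props, k0)
        null_rates[t] = np.mean(stats.chi2.sf(s, df=B - 1) < alpha)
        null_stats[t] = s.mean()
    expected = float(null_rates.mean())
    greater = (null_rates > observed_full) | (
        (null_rates == observed_full) & (null_stats > observed_stat)
    )
    p_value = float((1 + np.sum(greater)) / (n_permutations + 1))
    return KBETResult(
        rejection_rate=observed, expected_rate=expected, p_value=p_value,
        k0=k0, alpha=alpha, n_repeats=n_repeats, n_permutations=n_permutations,
    )


# ------------------------------------------------- batch-prediction score --
def batch_prediction_score(Y, batch, folds: int = 10, repeats: int = 10,
                           k: int = 5, seed: int = 0):
    """Cross-validated k-nearest-neighbor batch-classification accuracy.

    Returns (accuracy, majority_baseline).  Accuracy near the baseline means
    batch is not recoverable from the features.
    """
    Y = np.asarray(Y, dtype=float)
    batch = np.asarray(batch)
    levels, idx = np.unique(batch, return_inverse=True)
    counts = np.bincount(idx)
    if counts.min() < folds:
        raise ValueError("smallest batch has fewer subjects than CV folds")
    clf = make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=k))
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                 random_state=seed)
    scores = cross_val_score(clf, Y, idx, cv=cv, scoring="accuracy")
    return float(scores.mean()), float(counts.max() / counts.sum())


# ------------------------------------------------------------ full report --
@dataclass
class EvaluationReport:
    ad_mean_p: float
    ad_sd_p: float
    lrt_batch_mean_neglog10_p: float
    lrt_batch_sd_neglog10_p: float
    lrt_covariate_mean_neglog10_p: dict
    manova: dict
    kbet_rejection_rate: float
    kbet_expected_rate: float
    kbet_p: float
    batch_knn_accuracy: float
    batch_majority_baseline: float

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), indent=2, **kwargs)

    def to_markdown(self) -> str:
        lines = [
            "| metric | value |",
            "| --- | --- |",
            f"| Anderson-Darling mean p (pairwise batches) | {self.ad_mean_p:.3f} ({self.ad_sd_p:.3f}) |",
            f"| batch LRT mean -log10 p | {self.lrt_batch_mean_neglog10_p:.3f} ({self.lrt_batch_sd_neglog10_p:.3f}) |",
        ]
        for name, v in self.lrt_covariate_mean_neglog10_p.items():
            lines.append(f"| {name} mean -log10 p | {v:.3f} |")
        for term, d in self.manova.items():
            lines.append(
                f"| MANOVA Pillai ({term}) -log10 p | {d['neglog10_p']:.3f} |"
            )
        lines += [
            f"| kBET rejection rate (expected) | {self.kbet_rejection_rate:.3f} "
            f"({self.kbet_expected_rate:.3f}) |",
            f"| kBET p | {self.kbet_p:.3f} |",
            f"| kNN batch accuracy (majority baseline) | {self.batch_knn_accuracy:.3f} "
            f"({self.batch_majority_baseline:.3f}) |",
        ]
        return "\n".join(lines)


def evaluate_harmonization(Y, X, batch, covariate_names=None, seed: int = 0,
                           kbet_kwargs=None, knn_kwargs=None) -> EvaluationReport:
    """Run the full battery on one feature matrix."""
    Y = np.asarray(Y, dtype=float)
    batch = np.asarray(batch)
    levels = np.unique(batch)
    if isinstance(X, pd.DataFrame):
        covariate_names = covariate_names or list(X.columns)
        X = X.to_numpy(dtype=float)

    ad_ps = []
    for a, b in combinations(levels, 2):
        for k in range(Y.shape[1]):
            ad_ps.append(ad_two_sample(Y[batch == a, k], Y[batch == b, k])[1])
    ad_ps = np.asarray(ad_ps)

    lrt = featurewise_batch_lrt(Y, X, batch, covariate_names=covariate_names)
    manova = manova_pillai(Y, X, batch, covariate_names=covariate_names)
    kb = kbet(Y, batch, rng=seed, **(kbet_kwargs or {}))
    acc, baseline = batch_prediction_score(Y, batch, seed=seed, **(knn_kwargs or {}))
    return EvaluationReport(
        ad_mean_p=float(ad_ps.mean()),
        ad_sd_p=float(ad_ps.std(ddof=1)),
        lrt_batch_mean_neglog10_p=lrt["batch_mean_neglog10_p"],
        lrt_batch_sd_neglog10_p=lrt["batch_sd_neglog10_p"],
        lrt_covariate_mean_neglog10_p=lrt["covariate_mean_neglog10_p"],
        manova=manova,
        kbet_rejection_rate=kb.rejection_rate,
        kbet_expected_rate=kb.expected_rate,
        kbet_p=kb.p_value,
        batch_knn_accuracy=acc,
        batch_majority_baseline=baseline,
    )
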