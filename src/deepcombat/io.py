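"""CSV dataset handling and model persistence.

Datasets are a pair of delimited text files sharing an ID column: a feature
table (subjects x features, numeric) and a covariate table containing the
batch column plus biological covariates.  Categorical covariates are
dummy-coded with a recorded level order (reference level dropped, regression
identifiability); continuous covariates pass through.

Fitted DeepComBat models are archived as a flat key -> array ``.npz`` with a
JSON metadata entry carrying the schema version, the CVAE architecture, and
the recorded covariate schema; loading refuses mismatched versions.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .combat import ComBatModel
from .cvae import CVAE, CVAEConfig
from .harmonize import DeepComBat, NormalizationTransforms

__all__ = ["read_dataset", "write_features", "save_model", "load_model",
           "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"


def _read_table(path, sep=","):
    df = pd.read_csv(path, sep=sep)
    if df.columns.size == 0:
        raise ValueError(f"{path}: no header row found")
    return df


def read_dataset(features_path, covariates_path, batch_col: str,
                 id_col: str = "subject_id", sep: str = ",",
                 categorical=None):
    """Load and align a features file and a covariates file by ID.

    Returns ``(features_df, design_df, batch, ids)`` where ``features_df``
    is indexed by ID with numeric columns, ``design_df`` is the dummy-coded
    covariate design aligned to it (empty if the covariates file holds only
    the batch column), and ``batch`` the per-subject labels.
    """
    feats = _read_table(features_path, sep=sep)
    covs = _read_table(covariates_path, sep=sep)
    for name, df in (("features", feats), ("covariates", covs)):
        if id_col not in df.columns:
            raise ValueError(f"{name} file lacks ID column {id_col!r}")
        if df[id_col].duplicated().any():
            dup = df.loc[df[id_col].duplicated(), id_col].iloc[0]
            raise ValueError(f"{name} file has duplicate ID {dup!r}")
    if batch_col not in covs.columns:
        raise ValueError(f"covariates file lacks batch column {batch_col!r}")
    if set(feats[id_col]) != set(covs[id_col]):
        missing = set(feats[id_col]) ^ set(covs[id_col])
        raise ValueError(f"IDs do not match 1:1 across files; mismatched: "
                         f"{sorted(map(str, missing))[:5]}")
    feats = feats.set_index(id_col)
    covs = covs.set_index(id_col).loc[feats.index]  # realign by ID

    na = feats.isna()
    if na.any().any():
        r, c = np.argwhere(na.to_numpy())[0]
        raise ValueError(
            f"missing value in features at row {feats.index[r]!r}, "
            f"column {feats.columns[c]!r}"
        )
    try:
        feats = feats.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric feature value: {exc}") from None
    if covs.drop(columns=[batch_col]).isna().any().any():
        bad = covs.drop(columns=[batch_col]).isna().any()
        raise ValueError(
            f"missing covariate values in column(s) {list(bad[bad].index)}"
        )

    batch = covs[batch_col].astype(str).to_numpy()
    cov_df = covs.drop(columns=[batch_col])
    if categorical is None:
        categorical = [c for c in cov_df.columns
                       if not pd.api.types.is_numeric_dtype(cov_df[c])]
    design_parts = []
    for col in cov_df.columns:
        if col in categorical:
            levels = sorted(cov_df[col].astype(str).unique())
            for lv in levels[1:]:  # drop reference level
                design_parts.append(
                    (cov_df[col].astype(str) == lv).astype(float).rename(f"{col}_{lv}")
                )
        else:
            design_parts.append(cov_df[col].astype(float))
    design = pd.concat(design_parts, axis=1) if design_parts \
        else pd.DataFrame(index=feats.index)
    return feats, design, batch, feats.index.to_numpy()


def write_features(path, Y, feature_names, ids, id_col: str = "subject_id",
                   sep: str = ","):
    """Write a harmonized feature matrix with deterministic column order."""
    df = pd.DataFrame(np.asarray(Y), columns=list(feature_names))
    df.insert(0, id_col, ids)
    df.to_csv(path, sep=sep, index=False)


def save_model(model: DeepComBat, path) -> None:
    """Archive a fitted DeepComBat model (flat key -> array npz + JSON meta)."""
    if not hasattr(model, "cvae_"):
        raise ValueError("model is not fitted")
    arrays: dict[str, np.ndarray] = {}
    arrays.update(model.cvae_.to_arrays("cvae/"))
    arrays.update(model.transforms_.to_arrays("norm/"))
    if model.latent_combat_ is not None:
        arrays.update(model.latent_combat_.to_arrays("latent_combat/"))
    arrays.update(model.residual_combat_.to_arrays("residual_combat/"))
    arrays["batch_levels"] = np.asarray(model.batch_levels_, dtype=str)
    arrays["latent_active"] = model.latent_active_.astype(int)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "cvae_config": model.cvae_config_.to_dict(),
        "params": model.get_params(),
        "reference_batch": str(model.reference_batch_),
        "has_latent_combat": model.latent_combat_ is not None,
        "n_features": int(model.n_features_in_),
    }
    arrays["meta"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_model(path) -> DeepComBat:
    """Restore a DeepComBat model saved by :func:`save_model`."""
    with np.load(path, allow_pickle=False) as archive:
        arrays = {k: archive[k] for k in archive.files}
    meta = json.loads(str(arrays["meta"]))
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"model archive schema version {meta.get('schema_version')!r} "
            f"does not match supported version {SCHEMA_VERSION!r}"
        )
    params = meta["params"]
    if isinstance(params.get("hidden_sizes"), list):
        params["hidden_sizes"] = tuple(params["hidden_sizes"])
    model = DeepComBat(**params)
    config = CVAEConfig.from_dict(meta["cvae_config"])
    model.cvae_config_ = config
    model.cvae_ = CVAE.from_arrays(arrays, config, "cvae/")
    model.transforms_ = NormalizationTransforms.from_arrays(arrays, "norm/")
    model.latent_combat_ = (
        ComBatModel.from_arrays(arrays, "latent_combat/")
        if meta["has_latent_combat"] else None
    )
    model.residual_combat_ = ComBatModel.from_arrays(arrays, "residual_combat/")
    model.batch_levels_ = arrays["batch_levels"]
    model.latent_active_ = arrays["latent_active"].astype(bool)
    model.reference_batch_ = meta["reference_batch"]
    model.n_features_in_ = meta["n_features"]
    model.loss_trace_ = []
    return model
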