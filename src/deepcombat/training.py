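"""CVAE optimization under the cyclic KL-annealing schedule.

The KL weight lambda starts at 0 for a 5-epoch pretrain, then ramps linearly
from 0 to ``lambda_final`` within each 5-epoch cycle over 30 epochs of cyclic
annealing, and finishes with 5 epochs at ``lambda_final``.  Cycling the weight
lets the optimizer escape the posterior-collapse local minimum in which the
latent code carries no information.  Internal harmonization uses Adam,
external (cross-fit) harmonization AdamW; both with learning rate 0.01 and
minibatches of 64 subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .cvae import CVAE, CVAEConfig
from .nn import Adam

__all__ = ["TrainingConfig", "lambda_schedule", "train_cvae"]


@dataclass
class TrainingConfig:
    lambda_final: float = 0.1
    pretrain_epochs: int = 5
    cyclic_epochs: int = 30
    cycle_length: int = 5
    final_epochs: int = 5
    schedule: str = "cyclic"          # "cyclic" | "constant"
    optimizer: str = "adam"           # "adam" | "adamw"
    learning_rate: float = 0.01
    weight_decay: float = 0.01        # AdamW decoupled decay (logged in trace)
    minibatch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.schedule not in ("cyclic", "constant"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.optimizer not in ("adam", "adamw"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        for name in ("pretrain_epochs", "cyclic_epochs", "cycle_length",
                     "final_epochs", "minibatch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cyclic_epochs % self.cycle_length != 0:
            raise ValueError("cyclic_epochs must be divisible by cycle_length")
        if self.lambda_final < 0:
            raise ValueError("lambda_final must be nonnegative")

    @property
    def total_epochs(self) -> int:
        return self.pretrain_epochs + self.cyclic_epochs + self.final_epochs

    def to_dict(self) -> dict:
        return asdict(self)


def lambda_schedule(epoch: int, config: TrainingConfig) -> float:
    """KL weight for a 0-based epoch index.

    Cyclic: 0 during pretrain; within each annealing cycle the weight ramps
    linearly, reaching ``lambda_final`` on the cycle's last epoch
    (lambda_final * ((e mod L) + 1) / L); constant ``lambda_final`` during the
    final epochs.  Constant schedule: ``lambda_final`` throughout.
    """
    if not 0 <= epoch < config.total_epochs:
        raise ValueError(
            f"epoch {epoch} outside [0, {config.total_epochs})"
        )
    if config.schedule == "constant":
        return config.lambda_final
    if epoch < config.pretrain_epochs:
        return 0.0
    e = epoch - config.pretrain_epochs
    if e < config.cyclic_epochs:
        L = config.cycle_length
        return config.lambda_final * ((e % L) + 1) / L
    return config.lambda_final


def train_cvae(Y_norm, X_norm, batch_onehot, cvae_config: CVAEConfig,
               training_config: TrainingConfig | None = None):
    """Train a CVAE on normalized data; returns (model, per-epoch trace).

    Deterministic given ``training_config.seed``: minibatch shuffling and the
    reparameterization draws are reseeded per epoch from the master seed.
    The trace is a list of dicts (epoch, lambda, reconstruction, prior,
    total), with the summed losses accumulated over the epoch's minibatches.
    """
    cfg = training_config or TrainingConfig()
    Y_norm = np.asarray(Y_norm, dtype=float)
    n = Y_norm.shape[0]
    X_norm = np.empty((n, 0)) if X_norm is None else np.asarray(X_norm, dtype=float)
    batch_onehot = np.asarray(batch_onehot, dtype=float)

    model = CVAE(cvae_config, seed=cfg.seed)
    opt = Adam(
        model.parameters(),
        lr=cfg.learning_rate,
        weight_decay=cfg.weight_decay if cfg.optimizer == "adamw" else 0.0,
        decoupled_weight_decay=(cfg.optimizer == "adamw"),
    )
    ss = np.random.SeedSequence(cfg.seed)
    epoch_seeds = ss.spawn(cfg.total_epochs)
    trace = []
    for epoch in range(cfg.total_epochs):
        lam = lambda_schedule(epoch, cfg)
        rng = np.random.default_rng(epoch_seeds[epoch])
        order = rng.permutation(n)
        recon = prior = total = 0.0
        for start in range(0, n, cfg.minibatch_size):
            rows = order[start : start + cfg.minibatch_size]
            eps = rng.standard_normal((rows.size, cvae_config.latent_dim))
            loss, grads = model.loss_and_grads(
                Y_norm[rows], X_norm[rows], batch_onehot[rows], eps, lam
            )
            if not np.isfinite(loss["total"]):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (lambda={lam:.4g}); "
                    "learning rate may be too high or the input degenerate"
                )
            opt.step(grads)
            recon += loss["reconstruction"]
            prior += loss["prior"]
            total += loss["total"]
        trace.append({
            "epoch": epoch,
            "lambda": lam,
            "reconstruction": recon,
            "prior": prior,
            "total": total,
        })
    return model, trace
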