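"""Conditional variational autoencoder for feature-matrix harmonization.

The encoder maps the concatenation [y, x, b] of a normalized feature vector,
biological covariates, and a batch one-hot through four TanH hidden layers
into a Gaussian latent code N(mu, diag(sigma^2)); the decoder maps [z, x, b]
back to feature space through the mirrored ladder.  The latent width defaults
to p/4 rounded to the nearest power of 2, and hidden widths interpolate
linearly between the feature count and the latent width, so each hidden layer
sits roughly halfway between its neighbors.

Training loss per subject:

    L = sum_k (y_k - yhat_k)^2  +  lambda * KL( N(mu, diag sigma^2) || N(0, I) )

summed (not averaged) over subjects and features; averaging would silently
rescale the effective lambda.

All forward maps are deterministic; stochasticity enters only through the
reparameterized draw z = mu + sigma * eps with caller-supplied eps.
Gradients are computed by hand-written backprop (validated against finite
differences in the test suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import init_linear

__all__ = ["CVAEConfig", "CVAE", "plan_architecture", "kl_divergence", "cvae_loss"]

_LOGVAR_CLIP = 15.0  # |log-variance| bound to keep exp() finite


@dataclass
class CVAEConfig:
    input_dim: int                   # p, number of features
    covariate_dim: int               # q
    batch_dim: int                   # number of batch indicator columns
    latent_dim: int
    hidden_sizes: tuple              # encoder-side, strictly decreasing
    activation: str = "tanh"
    shared_trunk: bool = True

    def to_dict(self) -> dict:
        return {
            "input_dim": self.input_dim,
            "covariate_dim": self.covariate_dim,
            "batch_dim": self.batch_dim,
            "latent_dim": self.latent_dim,
            "hidden_sizes": list(self.hidden_sizes),
            "activation": self.activation,
            "shared_trunk": self.shared_trunk,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CVAEConfig":
        d = dict(d)
        d["hidden_sizes"] = tuple(d["hidden_sizes"])
        return cls(**d)


def plan_architecture(p: int, q: int, batch_dim: int, *, latent_dim: int | None = None,
                      hidden_sizes=None, n_hidden: int = 4) -> CVAEConfig:
    """Size the network from the feature count.

    latent_dim = 2**round(log2(p/4)); hidden widths are the rounded linear
    interpolation between p and latent_dim over ``n_hidden`` interior steps,
    which places each hidden layer approximately halfway between the layers
    before and after it.  For p = 62 this gives latent 16 and ladder
    (53, 44, 34, 25).
    """
    if p < 2:
        raise ValueError("need at least 2 features")
    if latent_dim is None:
        if p / 4 < 1:
            warnings.warn("p/4 < 1; using minimum latent dimension 2", RuntimeWarning)
            latent_dim = 2
        else:
            latent_dim = int(2 ** round(np.log2(p / 4)))
            latent_dim = max(latent_dim, 2)
    if hidden_sizes is None:
        ladder = np.round(np.linspace(p, latent_dim, n_hidden + 2))[1:-1]
        hidden_sizes = tuple(int(h) for h in ladder)
    else:
        hidden_sizes = tuple(int(h) for h in hidden_sizes)
    return CVAEConfig(
        input_dim=p,
        covariate_dim=q,
        batch_dim=batch_dim,
        latent_dim=latent_dim,
        hidden_sizes=hidden_sizes,
    )


def kl_divergence(mu, sigma) -> float:
    """KL( N(mu, diag sigma^2) || N(0, I) ) in closed form.

    0.5 * sum_d (mu_d^2 + sigma_d^2 - 1 - ln sigma_d^2); nonnegative, zero
    iff mu = 0 and sigma = 1.  Accepts a single vector or a batch of rows
    (returns per-row values in that case).
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    terms = mu**2 + sigma**2 - 1.0 - 2.0 * np.log(sigma)
    return 0.5 * terms.sum(axis=-1)


def cvae_loss(y, y_hat, mu, sigma, lam: float) -> dict:
    """Per-subject loss breakdown, summed over subjects for batched input."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    recon = float(np.sum((y - y_hat) ** 2))
    prior = float(np.sum(kl_divergence(mu, sigma)))
    return {"reconstruction": recon, "prior": prior, "total": recon + lam * prior}


class CVAE:
    """Fully connected CVAE with a shared encoder trunk and two linear heads
    (mu and log-variance), mirrored TanH decoder, linear output layer."""

    def __init__(self, config: CVAEConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        enc_widths = [c.input_dim + c.covariate_dim + c.batch_dim, *c.hidden_sizes]
        dec_widths = [c.latent_dim + c.covariate_dim + c.batch_dim,
                      *reversed(c.hidden_sizes)]
        self.params: dict[str, np.ndarray] = {}
        for i in range(len(enc_widths) - 1):
            W, b = init_linear(rng, enc_widths[i], enc_widths[i + 1])
            self.params[f"enc_W{i}"], self.params[f"enc_b{i}"] = W, b
        for head in ("mu", "lv"):
            W, b = init_linear(rng, enc_widths[-1], c.latent_dim)
            self.params[f"{head}_W"], self.params[f"{head}_b"] = W, b
        for i in range(len(dec_widths) - 1):
            W, b = init_linear(rng, dec_widths[i], dec_widths[i + 1])
            self.params[f"dec_W{i}"], self.params[f"dec_b{i}"] = W, b
        W, b = init_linear(rng, dec_widths[-1], c.input_dim)
        self.params["out_W"], self.params["out_b"] = W, b
        self._n_hidden = len(c.hidden_sizes)

    # ---- parameter bookkeeping -------------------------------------------
    def param_names(self) -> list:
        names = []
        for i in range(self._n_hidden):
            names += [f"enc_W{i}", f"enc_b{i}"]
        names += ["mu_W", "mu_b", "lv_W", "lv_b"]
        for i in range(self._n_hidden):
            names += [f"dec_W{i}", f"dec_b{i}"]
        names += ["out_W", "out_b"]
        return names

    def parameters(self) -> list:
        return [self.params[k] for k in self.param_names()]

    # ---- forward maps -----------------------------------------------------
    @staticmethod
    def _check2d(a, dim, what):
        a = np.atleast_2d(np.asarray(a, dtype=float))
        if a.shape[1] != dim:
            raise ValueError(f"{what} has width {a.shape[1]}, expected {dim}")
        return a

    def _concat_inputs(self, y_or_z, x, b):
        n = y_or_z.shape[0]
        x = self._check2d(x, self.config.covariate_dim, "covariate input") \
            if self.config.covariate_dim else np.empty((n, 0))
        b = self._check2d(b, self.config.batch_dim, "batch input")
        if x.shape[0] != n or b.shape[0] != n:
            raise ValueError("row mismatch between feature, covariate and batch inputs")
        return np.hstack([y_or_z, x, b])

    def encode(self, y, x, b):
        """Deterministic map to the latent Gaussian: returns (mu, sigma)."""
        y = self._check2d(y, self.config.input_dim, "feature input")
        a = self._concat_inputs(y, x, b)
        for i in range(self._n_hidden):
            a = np.tanh(a @ self.params[f"enc_W{i}"] + self.params[f"enc_b{i}"])
        mu = a @ self.params["mu_W"] + self.params["mu_b"]
        logvar = np.clip(a @ self.params["lv_W"] + self.params["lv_b"],
                         -_LOGVAR_CLIP, _LOGVAR_CLIP)
        return mu, np.exp(0.5 * logvar)

    def sample_latent(self, mu, sigma, rng: np.random.Generator):
        """Reparameterized draw z = mu + sigma * eps, eps ~ N(0, I)."""
        mu = np.asarray(mu, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        eps = rng.standard_normal(mu.shape)
        return mu + sigma * eps

    def decode(self, z, x, b):
        z = self._check2d(z, self.config.latent_dim, "latent input")
        a = self._concat_inputs(z, x, b)
        for i in range(self._n_hidden):
            a = np.tanh(a @ self.params[f"dec_W{i}"] + self.params[f"dec_b{i}"])
        return a @ self.params["out_W"] + self.params["out_b"]

    # ---- training step: forward with cache + analytic backprop ------------
    def loss_and_grads(self, y, x, b, eps, lam: float):
        """Total loss (summed over the rows of ``y``) and gradients.

        ``eps`` is the standard-normal draw for the reparameterization trick,
        shaped (n, latent_dim).
        """
        c = self.config
        y = self._check2d(y, c.input_dim, "feature input")
        n = y.shape[0]
        x = self._check2d(x, c.covariate_dim, "covariate input") \
            if c.covariate_dim else np.empty((n, 0))
        b = self._check2d(b, c.batch_dim, "batch input")

        # encoder forward
        enc_acts = [np.hstack([y, x, b])]
        a = enc_acts[0]
        for i in range(self._n_hidden):
            a = np.tanh(a @ self.params[f"enc_W{i}"] + self.params[f"enc_b{i}"])
            enc_acts.append(a)
        h = enc_acts[-1]
        mu = h @ self.params["mu_W"] + self.params["mu_b"]
        logvar_raw = h @ self.params["lv_W"] + self.params["lv_b"]
        logvar = np.clip(logvar_raw, -_LOGVAR_CLIP, _LOGVAR_CLIP)
        sigma = np.exp(0.5 * logvar)
        z = mu + sigma * eps

        # decoder forward
        dec_acts = [np.hstack([z, x, b])]
        a = dec_acts[0]
        for i in range(self._n_hidden):
            a = np.tanh(a @ self.params[f"dec_W{i}"] + self.params[f"dec_b{i}"])
            dec_acts.append(a)
        y_hat = dec_acts[-1] @ self.params["out_W"] + self.params["out_b"]

        recon = float(np.sum((y - y_hat) ** 2))
        kl = float(0.5 * np.sum(mu**2 + sigma**2 - 1.0 - logvar))
        loss = {"reconstruction": recon, "prior": kl, "total": recon + lam * kl}

        grads = {k: None for k in self.params}
        # output layer
        g = 2.0 * (y_hat - y)
        grads["out_W"] = dec_acts[-1].T @ g
        grads["out_b"] = g.sum(axis=0)
        g = g @ self.params["out_W"].T
        # decoder hiddens (reverse)
        for i in range(self._n_hidden - 1, -1, -1):
            g = g * (1.0 - dec_acts[i + 1] ** 2)
            grads[f"dec_W{i}"] = dec_acts[i].T @ g
            grads[f"dec_b{i}"] = g.sum(axis=0)
            g = g @ self.params[f"dec_W{i}"].T
        dz = g[:, : c.latent_dim]

        dmu = dz + lam * mu
        # d sigma/d logvar = 0.5 sigma; clip is inactive almost surely, its
        # saturation zeroes the gradient where it binds
        active = (np.abs(logvar_raw) < _LOGVAR_CLIP).astype(float)
        dlogvar = (0.5 * dz * eps * sigma + lam * 0.5 * (sigma**2 - 1.0)) * active

        grads["mu_W"] = h.T @ dmu
        grads["mu_b"] = dmu.sum(axis=0)
        grads["lv_W"] = h.T @ dlogvar
        grads["lv_b"] = dlogvar.sum(axis=0)
        g = dmu @ self.params["mu_W"].T + dlogvar @ self.params["lv_W"].T
        # encoder hiddens (reverse)
        for i in range(self._n_hidden - 1, -1, -1):
            g = g * (1.0 - enc_acts[i + 1] ** 2)
            grads[f"enc_W{i}"] = enc_acts[i].T @ g
            grads[f"enc_b{i}"] = g.sum(axis=0)
            g = g @ self.params[f"enc_W{i}"].T
        return loss, [grads[k] for k in self.param_names()]

    # ---- serialization ----------------------------------------------------
    def to_arrays(self, prefix: str = "cvae/") -> dict:
        out = {f"{prefix}{k}": v for k, v in self.params.items()}
        return out

    @classmethod
    def from_arrays(cls, arrays: dict, config: CVAEConfig, prefix: str = "cvae/") -> "CVAE":
        model = cls(config, seed=0)
        for k in model.params:
            model.params[k] = np.asarray(arrays[f"{prefix}{k}"])
        return model
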