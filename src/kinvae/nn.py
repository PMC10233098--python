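"""Numerical core of the supervised variational autoencoder.

The network is small enough (12 inputs, one or two tanh hidden layers, a
2-10 dimensional latent space) that it is implemented directly in numpy
with hand-written forward and backward passes and an Adam optimizer; a
finite-difference gradient check in the test suite pins the backward pass
to the loss definition.

Loss (unit weights on all three terms):

    total = L_recon + KL(q(z|x), N(0, I)) + L_pred

* ``L_recon`` — mean squared error between input and reconstruction.
* ``KL`` — closed form for a diagonal Gaussian posterior against the
  standard normal: 1/2 * sum_j (mu_j^2 + sigma_j^2 - 1 - log sigma_j^2).
* ``L_pred`` — binary cross-entropy of the predictor head (2-unit softmax
  by default; a single sigmoid unit is config-selectable), probabilities
  clamped to [1e-7, 1 - 1e-7].

The latent SD is parameterized through a log-variance head (sigma =
exp(logvar / 2)), guaranteeing positivity, and sampling uses the
reparameterization z = mu + sigma * eps so gradients flow through both
moments.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ShapeError

EPS_PROB = 1e-7


@dataclass
class EncoderOutput:
    """Latent posterior parameters for a batch (or single) input."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape:
            raise ShapeError("mu and sigma must share a shape")
        if not np.all(np.isfinite(self.mu)) or not np.all(np.isfinite(self.sigma)):
            raise ValueError("non-finite encoder output")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")


@dataclass
class LossBreakdown:
    """The three equally weighted loss components; total is their exact sum."""

    recon: float
    kl: float
    pred: float

    def __post_init__(self):
        for name in ("recon", "kl", "pred"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} loss must be nonnegative")

    @property
    def total(self) -> float:
        return self.recon + self.kl + self.pred


# ---------------------------------------------------------------- losses

def kl_loss(enc: EncoderOutput) -> float:
    """KL(q, N(0, I)) for a diagonal Gaussian; mean over the batch axis."""
    mu, sigma = np.atleast_2d(enc.mu), np.atleast_2d(enc.sigma)
    per_sample = 0.5 * np.sum(mu**2 + sigma**2 - 1.0 - 2.0 * np.log(sigma), axis=1)
    return float(per_sample.mean())


def reconstruction_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean squared error over features (and batch, if batched)."""
    x, x_hat = np.asarray(x, dtype=float), np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ShapeError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    return float(np.mean((x - x_hat) ** 2))


def predictor_loss(y, p) -> float:
    """Binary cross-entropy -[y log p + (1-y) log(1-p)], batch-averaged."""
    y = np.atleast_1d(np.asarray(y))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be binary (0/1)")
    p = np.clip(p, EPS_PROB, 1.0 - EPS_PROB)
    y = y.astype(float)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def total_loss(recon: float, kl: float, pred: float) -> LossBreakdown:
    return LossBreakdown(recon=recon, kl=kl, pred=pred)


def sample_latent(enc: EncoderOutput, rng: np.random.Generator | int | None = None,
                  eps: np.ndarray | None = None) -> np.ndarray:
    """Reparameterized draw z = mu + sigma * eps, eps ~ N(0, I)."""
    if eps is None:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        eps = rng.standard_normal(enc.mu.shape)
    return enc.mu + enc.sigma * eps


# ---------------------------------------------------------------- network

def _act(a: np.ndarray, kind: str) -> np.ndarray:
    return np.tanh(a) if kind == "tanh" else np.maximum(a, 0.0)


def _act_grad(h: np.ndarray, a: np.ndarray, kind: str) -> np.ndarray:
    return 1.0 - h**2 if kind == "tanh" else (a > 0).astype(float)


def init_params(n_features: int, config, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Glorot-normal weights, zero biases; layout mirrors the architecture."""
    d = config.latent_dim

    def glorot(n_in, n_out):
        return rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / (n_in + n_out))

    params: dict[str, np.ndarray] = {}
    sizes = [n_features, *config.encoder_hidden]
    for i in range(len(config.encoder_hidden)):
        params[f"enc_W{i}"] = glorot(sizes[i], sizes[i + 1])
        params[f"enc_b{i}"] = np.zeros(sizes[i + 1])
    params["W_mu"] = glorot(sizes[-1], d)
    params["b_mu"] = np.zeros(d)
    params["W_lv"] = glorot(sizes[-1], d)
    params["b_lv"] = np.zeros(d)
    dec_sizes = [d, *reversed(config.encoder_hidden)]
    for i in range(len(config.encoder_hidden)):
        params[f"dec_W{i}"] = glorot(dec_sizes[i], dec_sizes[i + 1])
        params[f"dec_b{i}"] = np.zeros(dec_sizes[i + 1])
    params["W_out"] = glorot(dec_sizes[-1], n_features)
    params["b_out"] = np.zeros(n_features)
    params["W_p1"] = glorot(d, config.predictor_hidden)
    params["b_p1"] = np.zeros(config.predictor_hidden)
    n_out = 2 if config.predictor_head == "softmax" else 1
    params["W_p2"] = glorot(config.predictor_hidden, n_out)
    params["b_p2"] = np.zeros(n_out)
    return params


def encode(params: dict, X: np.ndarray, config) -> EncoderOutput:
    """Deterministic encoder forward pass on standardized inputs."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    H = np.atleast_2d(X)
    if H.shape[1] != params["enc_W0"].shape[0]:
        raise ShapeError(
            f"expected {params['enc_W0'].shape[0]} features, got {H.shape[1]}"
        )
    for i in range(len(config.encoder_hidden)):
        H = _act(H @ params[f"enc_W{i}"] + params[f"enc_b{i}"], config.activation)
    mu = H @ params["W_mu"] + params["b_mu"]
    logvar = H @ params["W_lv"] + params["b_lv"]
    sigma = np.exp(0.5 * logvar)
    if single:
        mu, sigma = mu[0], sigma[0]
    return EncoderOutput(mu=mu, sigma=sigma)


def _forward(params: dict, X: np.ndarray, y: np.ndarray, eps: np.ndarray, config):
    """Full forward pass; returns the loss breakdown and a cache for backward."""
    n = X.shape[0]
    cache: dict = {"X": X, "y": y, "eps": eps}
    H = X
    enc_h, enc_a = [], []
    for i in range(len(config.encoder_hidden)):
        a = H @ params[f"enc_W{i}"] + params[f"enc_b{i}"]
        H = _act(a, config.activation)
        enc_a.append(a)
        enc_h.append(H)
    cache["enc_h"], cache["enc_a"] = enc_h, enc_a
    mu = H @ params["W_mu"] + params["b_mu"]
    logvar = H @ params["W_lv"] + params["b_lv"]
    sigma = np.exp(0.5 * logvar)
    z = mu + sigma * eps
    cache.update(mu=mu, logvar=logvar, sigma=sigma, z=z)

    Hd = z
    dec_h, dec_a = [], []
    for i in range(len(config.encoder_hidden)):
        a = Hd @ params[f"dec_W{i}"] + params[f"dec_b{i}"]
        Hd = _act(a, config.activation)
        dec_a.append(a)
        dec_h.append(Hd)
    cache["dec_h"], cache["dec_a"] = dec_h, dec_a
    x_hat = Hd @ params["W_out"] + params["b_out"]
    cache["x_hat"] = x_hat

    a_p = z @ params["W_p1"] + params["b_p1"]
    h_p = np.tanh(a_p)  # predictor hidden layer is tanh by construction
    logits = h_p @ params["W_p2"] + params["b_p2"]
    cache.update(a_p=a_p, h_p=h_p, logits=logits)

    if config.predictor_head == "softmax":
        shifted = logits - logits.max(axis=1, keepdims=True)
        expl = np.exp(shifted)
        P = expl / expl.sum(axis=1, keepdims=True)
        p1 = P[:, 1]
        cache["P"] = P
    else:
        p1 = 1.0 / (1.0 + np.exp(-logits[:, 0]))
        cache["p1"] = p1

    recon = float(np.mean((x_hat - X) ** 2))
    kl = float(np.mean(0.5 * np.sum(mu**2 + sigma**2 - 1.0 - logvar, axis=1)))
    pc = np.clip(p1, EPS_PROB, 1.0 - EPS_PROB)
    pred = float(np.mean(-(y * np.log(pc) + (1 - y) * np.log(1.0 - pc))))
    return LossBreakdown(recon=recon, kl=kl, pred=pred), cache


def _backward(params: dict, cache: dict, config) -> dict[str, np.ndarray]:
    """Exact gradients of the total loss w.r.t. every parameter."""
    X, y, eps = cache["X"], cache["y"], cache["eps"]
    n, F = X.shape
    grads: dict[str, np.ndarray] = {}

    # decoder / reconstruction
    dxhat = 2.0 * (cache["x_hat"] - X) / (n * F)
    grads["W_out"] = cache["dec_h"][-1].T @ dxhat
    grads["b_out"] = dxhat.sum(axis=0)
    dH = dxhat @ params["W_out"].T
    for i in reversed(range(len(config.encoder_hidden))):
        da = dH * _act_grad(cache["dec_h"][i], cache["dec_a"][i], config.activation)
        prev = cache["z"] if i == 0 else cache["dec_h"][i - 1]
        grads[f"dec_W{i}"] = prev.T @ da
        grads[f"dec_b{i}"] = da.sum(axis=0)
        dH = da @ params[f"dec_W{i}"].T
    dz = dH

    # predictor head
    if config.predictor_head == "softmax":
        onehot = np.zeros_like(cache["P"])
        onehot[np.arange(n), y.astype(int)] = 1.0
        dlogits = (cache["P"] - onehot) / n
    else:
        dlogits = ((cache["p1"] - y) / n)[:, None]
    grads["W_p2"] = cache["h_p"].T @ dlogits
    grads["b_p2"] = dlogits.sum(axis=0)
    dh_p = dlogits @ params["W_p2"].T
    da_p = dh_p * (1.0 - cache["h_p"] ** 2)
    grads["W_p1"] = cache["z"].T @ da_p
    grads["b_p1"] = da_p.sum(axis=0)
    dz = dz + da_p @ params["W_p1"].T

    # latent heads (KL + reparameterization)
    mu, sigma = cache["mu"], cache["sigma"]
    dmu = dz + mu / n
    dlogvar = dz * eps * 0.5 * sigma + 0.5 * (sigma**2 - 1.0) / n
    H_enc = cache["enc_h"][-1]
    grads["W_mu"] = H_enc.T @ dmu
    grads["b_mu"] = dmu.sum(axis=0)
    grads["W_lv"] = H_enc.T @ dlogvar
    grads["b_lv"] = dlogvar.sum(axis=0)
    dH = dmu @ params["W_mu"].T + dlogvar @ params["W_lv"].T

    for i in reversed(range(len(config.encoder_hidden))):
        da = dH * _act_grad(cache["enc_h"][i], cache["enc_a"][i], config.activation)
        prev = X if i == 0 else cache["enc_h"][i - 1]
        grads[f"enc_W{i}"] = prev.T @ da
        grads[f"enc_b{i}"] = da.sum(axis=0)
        dH = da @ params[f"enc_W{i}"].T
    return grads


def loss_and_grads(params: dict, X: np.ndarray, y: np.ndarray, eps: np.ndarray, config):
    loss, cache = _forward(params, X, y, eps, config)
    return loss, _backward(params, cache, config)


def predict_proba(params: dict, X: np.ndarray, config) -> np.ndarray:
    """Class probabilities from the latent mean (no sampling noise)."""
    enc = encode(params, np.atleast_2d(X), config)
    return predict_proba_from_latent(params, enc.mu, config)


def predict_proba_from_latent(params: dict, z: np.ndarray, config) -> np.ndarray:
    """Predictor-head class probabilities for given latent positions."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    h_p = np.tanh(z @ params["W_p1"] + params["b_p1"])
    logits = h_p @ params["W_p2"] + params["b_p2"]
    if config.predictor_head == "softmax":
        shifted = logits - logits.max(axis=1, keepdims=True)
        expl = np.exp(shifted)
        return expl / expl.sum(axis=1, keepdims=True)
    p1 = 1.0 / (1.0 + np.exp(-logits[:, 0]))
    return np.column_stack([1.0 - p1, p1])


def reconstruct(params: dict, X: np.ndarray, config) -> np.ndarray:
    """Decoder output from the latent mean."""
    enc = encode(params, np.atleast_2d(X), config)
    H = np.atleast_2d(enc.mu)
    for i in range(len(config.encoder_hidden)):
        H = _act(H @ params[f"dec_W{i}"] + params[f"dec_b{i}"], config.activation)
    return H @ params["W_out"] + params["b_out"]


# ---------------------------------------------------------------- optimizer

class Adam:
    """Standard Adam with bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


class SGD:
    def __init__(self, params: dict, lr: float):
        self.lr = lr

    def step(self, params: dict, grads: dict) -> None:
        for k, g in grads.items():
            params[k] -= self.lr * g
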