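"""The sparse supervised autoencoder network.

Architecture: a symmetric linear fully-connected autoencoder.  The encoder
maps the d-dimensional raw-count profile of a cell through one hidden layer
with ReLU activation into a latent layer of dimension k = 2 (one coordinate
per class); the decoder mirrors the encoder (independent weights, mirrored
shapes) back to d dimensions.  A softmax over the two latent coordinates
yields the per-cell class probabilities; class 1 ("gRNA-targeted") is the
perturbation score.

The training objective is joint: cross-entropy of the softmax scores against
the control/targeted labels plus lambda times a Huber (smooth-l1)
reconstruction loss, minimized subject to the first encoder layer lying in
an l1,1 ball (see :mod:`cropsae.projection`).

Everything here is plain numpy with explicit analytic gradients: the network
is small enough that this is both fast and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, f1_score

__all__ = [
    "SSAEWeights",
    "ForwardOutput",
    "init_weights",
    "forward",
    "softmax_scores",
    "huber_loss",
    "ssae_loss",
    "loss_and_grads",
    "class1_logit_input_gradient",
    "accuracy_f1",
    "Adam",
]

LATENT_DIM = 2

_LAYERS = ("W1", "b1", "W2", "b2", "W3", "b3", "W4", "b4")


@dataclass
class SSAEWeights:
    """Weights of the symmetric autoencoder.

    ``W1`` (d, h) / ``b1`` (h,) : gene -> hidden (the sparsity-constrained
    layer; row i is the fan-out of gene i and defines its selection status).
    ``W2`` (h, 2) / ``b2`` (2,) : hidden -> latent.
    ``W3`` (2, h) / ``b3`` (h,) : latent -> decoder hidden (ReLU).
    ``W4`` (h, d) / ``b4`` (d,) : decoder hidden -> reconstruction.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray
    W4: np.ndarray
    b4: np.ndarray

    @property
    def n_genes(self) -> int:
        return self.W1.shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.W1.shape[1]

    def copy(self) -> "SSAEWeights":
        return SSAEWeights(**{k: getattr(self, k).copy() for k in _LAYERS})

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in _LAYERS}

    def save(self, path) -> None:
        np.savez(path, **self.as_dict())

    @classmethod
    def load(cls, path) -> "SSAEWeights":
        with np.load(path) as data:
            return cls(**{k: data[k] for k in _LAYERS})


@dataclass
class ForwardOutput:
    """Activations of one forward pass (n cells)."""

    Z: np.ndarray       # (n, 2) latent coordinates (class logits)
    X_hat: np.ndarray   # (n, d) reconstruction
    scores: np.ndarray  # (n, 2) softmax class probabilities
    H1: np.ndarray = field(repr=False, default=None)  # encoder hidden (post-ReLU)
    H2: np.ndarray = field(repr=False, default=None)  # decoder hidden (post-ReLU)


def init_weights(n_genes: int, hidden_dim: int, rng: np.random.Generator) -> SSAEWeights:
    """Glorot-uniform initialization, biases at zero."""

    def glorot(fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    d, h, k = n_genes, hidden_dim, LATENT_DIM
    return SSAEWeights(
        W1=glorot(d, h), b1=np.zeros(h),
        W2=glorot(h, k), b2=np.zeros(k),
        W3=glorot(k, h), b3=np.zeros(h),
        W4=glorot(h, d), b4=np.zeros(d),
    )


def softmax_scores(Z: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max subtraction for overflow safety."""
    Z = np.asarray(Z, dtype=float)
    shifted = Z - Z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def forward(weights: SSAEWeights, X: np.ndarray) -> ForwardOutput:
    """Deterministic forward pass; raises on gene-dimension mismatch."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != weights.n_genes:
        raise ValueError(
            f"input has {X.shape[-1] if X.ndim == 2 else '?'} genes, "
            f"model expects {weights.n_genes}"
        )
    H1 = np.maximum(X @ weights.W1 + weights.b1, 0.0)
    Z = H1 @ weights.W2 + weights.b2
    H2 = np.maximum(Z @ weights.W3 + weights.b3, 0.0)
    X_hat = H2 @ weights.W4 + weights.b4
    return ForwardOutput(Z=Z, X_hat=X_hat, scores=softmax_scores(Z), H1=H1, H2=H2)


def huber_loss(residual: np.ndarray, delta: float = 1.0) -> float:
    """Smooth-l1 loss, mean-reduced over all entries.

    Quadratic ``0.5 r^2 / delta`` for |r| <= delta, linear
    ``|r| - 0.5 delta`` beyond; the two branches meet at |r| = delta.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    r = np.asarray(residual, dtype=float)
    a = np.abs(r)
    quad = 0.5 * r * r / delta
    lin = a - 0.5 * delta
    return float(np.mean(np.where(a <= delta, quad, lin)))


def _cross_entropy(scores: np.ndarray, Y: np.ndarray,
                   class_weights: np.ndarray | None) -> float:
    p = np.clip(scores[np.arange(len(Y)), Y], 1e-12, 1.0)
    if class_weights is None:
        return float(-np.mean(np.log(p)))
    w = class_weights[Y]
    return float(-(w * np.log(p)).sum() / w.sum())


def ssae_loss(out: ForwardOutput, X: np.ndarray, Y: np.ndarray,
              lam: float = 1.0, delta: float = 1.0,
              class_weights: np.ndarray | None = None) -> tuple[float, float, float]:
    """Joint loss: cross-entropy + lambda * Huber reconstruction.

    Returns ``(total, ce, reconstruction)``; the components are logged by
    the trainer.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    Y = np.asarray(Y, dtype=int)
    ce = _cross_entropy(out.scores, Y, class_weights)
    rec = huber_loss(out.X_hat - np.asarray(X, dtype=float), delta)
    return ce + lam * rec, ce, rec


def loss_and_grads(weights: SSAEWeights, X: np.ndarray, Y: np.ndarray,
                   lam: float = 1.0, delta: float = 1.0,
                   class_weights: np.ndarray | None = None):
    """Loss components plus analytic gradients for every layer.

    Returns ``(total, ce, rec, grads)`` with ``grads`` keyed like
    :attr:`SSAEWeights` fields.  Verified against central finite
    differences in the test suite.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=int)
    n, d = X.shape
    out = forward(weights, X)
    total, ce, rec = ssae_loss(out, X, Y, lam=lam, delta=delta,
                               class_weights=class_weights)

    # cross-entropy head
    T = np.zeros_like(out.scores)
    T[np.arange(n), Y] = 1.0
    if class_weights is None:
        dZ_ce = (out.scores - T) / n
    else:
        w = class_weights[Y]
        dZ_ce = (out.scores - T) * w[:, None] / w.sum()

    # Huber reconstruction
    r = out.X_hat - X
    dXhat = lam * np.clip(r / delta, -1.0, 1.0) / (n * d)

    # decoder backward
    gW4 = out.H2.T @ dXhat
    gb4 = dXhat.sum(axis=0)
    dH2 = dXhat @ weights.W4.T
    dH2 *= out.H2 > 0
    gW3 = out.Z.T @ dH2
    gb3 = dH2.sum(axis=0)
    dZ = dZ_ce + dH2 @ weights.W3.T

    # encoder backward
    gW2 = out.H1.T @ dZ
    gb2 = dZ.sum(axis=0)
    dH1 = dZ @ weights.W2.T
    dH1 *= out.H1 > 0
    gW1 = X.T @ dH1
    gb1 = dH1.sum(axis=0)

    grads = {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2,
             "W3": gW3, "b3": gb3, "W4": gW4, "b4": gb4}
    return total, ce, rec, grads


def class1_logit_input_gradient(weights: SSAEWeights, X: np.ndarray) -> np.ndarray:
    """Gradient of the class-1 latent coordinate with respect to each input.

    The logit depends on the encoder only; for a batch of cells the gradient
    of cell i's logit w.r.t. its own profile is
    ``((H1_i > 0) * W2[:, 1]) @ W1^T``.  Used by the attribution module.
    """
    X = np.asarray(X, dtype=float)
    H1pre = X @ weights.W1 + weights.b1
    mask = (H1pre > 0).astype(float)
    return (mask * weights.W2[:, 1]) @ weights.W1.T


def accuracy_f1(scores: np.ndarray, Y: np.ndarray) -> tuple[float, float]:
    """Accuracy and class-1 F1 of argmax predictions.

    F1 is 0 when positives exist but none are predicted.
    """
    pred = np.asarray(scores).argmax(axis=1)
    Y = np.asarray(Y, dtype=int)
    acc = float(accuracy_score(Y, pred))
    f1 = float(f1_score(Y, pred, pos_label=1, zero_division=0))
    return acc, f1


class Adam:
    """Plain Adam with bias correction, operating on an SSAEWeights in place."""

    def __init__(self, weights: SSAEWeights, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.weights = weights
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(getattr(weights, k)) for k in _LAYERS}
        self.v = {k: np.zeros_like(getattr(weights, k)) for k in _LAYERS}

    def step(self, grads: dict) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k in _LAYERS:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            getattr(self.weights, k)[...] -= self.lr * update
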