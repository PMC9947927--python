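"""Sparse stacked-autoencoder classifier with a softmax head (SAE-SM).

Architecture: input -> sigmoid encoder 1 -> sigmoid encoder 2 -> softmax
over C classes.  Training has two phases:

1. greedy layer-wise pretraining: each encoder is trained (with an
   untied sigmoid decoder, discarded afterwards) to minimize mean squared
   reconstruction error plus a KL-divergence sparsity penalty pulling the
   mean hidden activation of every unit toward a small target rho, plus
   an L2 weight penalty;
2. supervised fine-tuning: a randomly initialized softmax head is added
   and the whole network minimizes categorical cross-entropy (plus L2) by
   full-batch back-propagation.

Everything is plain numpy with analytic gradients; the gradient of every
loss is checked against central finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class SAEConfig:
    """Hyperparameters of one SAE-SM.

    ``hidden1``/``hidden2`` of ``None`` default to ceil(d/2) and
    ceil(d/4), floored at the class count.
    """

    hidden1: int | None = None
    hidden2: int | None = None
    sparsity_target: float = 0.05
    sparsity_weight: float = 3.0
    l2_weight: float = 1e-4
    pretrain_epochs: int = 100
    finetune_epochs: int = 200
    learning_rate: float = 0.05
    seed: int = 0

    def resolve_hidden(self, d: int, n_classes: int) -> tuple:
        h1 = self.hidden1 if self.hidden1 is not None else max(n_classes, -(-d // 2))
        h2 = self.hidden2 if self.hidden2 is not None else max(n_classes, -(-d // 4))
        return h1, h2


def _glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_out, fan_in))


# ---------------------------------------------------------------------------
# Autoencoder loss / gradient (exposed for gradient-correctness tests)

def ae_loss(params, X, rho, beta, lam):
    """Reconstruction + KL-sparsity + L2 loss of one sigmoid autoencoder.

    ``params = (W1, b1, W2, b2)`` with W1 the (h x d) encoder and W2 the
    (d x h) decoder.  Loss = mean_n 0.5*||x_hat - x||^2
    + beta * sum_u KL(rho || rho_hat_u) + lam/2 * (||W1||^2 + ||W2||^2).
    """
    W1, b1, W2, b2 = params
    N = X.shape[0]
    H = sigmoid(X @ W1.T + b1)
    Xhat = sigmoid(H @ W2.T + b2)
    recon = 0.5 * np.sum((Xhat - X) ** 2) / N
    rho_hat = np.clip(H.mean(axis=0), 1e-10, 1 - 1e-10)
    kl = np.sum(
        rho * np.log(rho / rho_hat) + (1 - rho) * np.log((1 - rho) / (1 - rho_hat))
    )
    l2 = 0.5 * lam * (np.sum(W1**2) + np.sum(W2**2))
    return recon + beta * kl + l2


def ae_grad(params, X, rho, beta, lam):
    """Analytic gradient of :func:`ae_loss` w.r.t. every parameter."""
    W1, b1, W2, b2 = params
    N = X.shape[0]
    H = sigmoid(X @ W1.T + b1)
    Xhat = sigmoid(H @ W2.T + b2)
    delta_out = (Xhat - X) / N * Xhat * (1 - Xhat)
    gW2 = delta_out.T @ H + lam * W2
    gb2 = delta_out.sum(axis=0)
    rho_hat = np.clip(H.mean(axis=0), 1e-10, 1 - 1e-10)
    kl_grad = -rho / rho_hat + (1 - rho) / (1 - rho_hat)
    delta_h = (delta_out @ W2 + beta * kl_grad / N) * H * (1 - H)
    gW1 = delta_h.T @ X + lam * W1
    gb1 = delta_h.sum(axis=0)
    return gW1, gb1, gW2, gb2


# ---------------------------------------------------------------------------
# Full-network cross-entropy loss / gradient

def net_loss(params, X, Y, lam):
    """Cross-entropy + L2 of the full encoder1/encoder2/softmax network.

    ``params = (W1, b1, W2, b2, Ws, bs)``; ``Y`` is one-hot N x C.
    """
    W1, b1, W2, b2, Ws, bs = params
    N = X.shape[0]
    H1 = sigmoid(X @ W1.T + b1)
    H2 = sigmoid(H1 @ W2.T + b2)
    P = softmax(H2 @ Ws.T + bs)
    ce = -np.sum(Y * np.log(np.clip(P, 1e-12, None))) / N
    l2 = 0.5 * lam * (np.sum(W1**2) + np.sum(W2**2) + np.sum(Ws**2))
    return ce + l2


def net_grad(params, X, Y, lam):
    W1, b1, W2, b2, Ws, bs = params
    N = X.shape[0]
    H1 = sigmoid(X @ W1.T + b1)
    H2 = sigmoid(H1 @ W2.T + b2)
    P = softmax(H2 @ Ws.T + bs)
    delta_s = (P - Y) / N
    gWs = delta_s.T @ H2 + lam * Ws
    gbs = delta_s.sum(axis=0)
    delta_2 = (delta_s @ Ws) * H2 * (1 - H2)
    gW2 = delta_2.T @ H1 + lam * W2
    gb2 = delta_2.sum(axis=0)
    delta_1 = (delta_2 @ W2) * H1 * (1 - H1)
    gW1 = delta_1.T @ X + lam * W1
    gb1 = delta_1.sum(axis=0)
    return gW1, gb1, gW2, gb2, gWs, gbs


def _descend(params, grad_fn, epochs, lr):
    """Full-batch Adam descent on the given loss gradient."""
    b1, b2, eps = 0.9, 0.999, 1e-8
    params = [p.copy() for p in params]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    for epoch in range(1, epochs + 1):
        grads = grad_fn(params)
        for p, mi, vi, g in zip(params, m, v, grads):
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient at epoch {epoch}")
            mi *= b1
            mi += (1 - b1) * g
            vi *= b2
            vi += (1 - b2) * g * g
            mhat = mi / (1 - b1**epoch)
            vhat = vi / (1 - b2**epoch)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
    return params


def train_autoencoder(
    X: np.ndarray, in_dim: int, out_dim: int, cfg: SAEConfig, rng: np.random.Generator
):
    """Train one sparse autoencoder; return (encoder W, encoder b).

    The decoder is untied and discarded.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != in_dim:
        raise ValueError(f"expected N x {in_dim} input, got {X.shape}")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    W1 = _glorot(rng, out_dim, in_dim)
    b1 = np.zeros(out_dim)
    W2 = _glorot(rng, in_dim, out_dim)
    b2 = np.zeros(in_dim)
    rho, beta, lam = cfg.sparsity_target, cfg.sparsity_weight, cfg.l2_weight
    params = _descend(
        [W1, b1, W2, b2],
        lambda p: ae_grad(tuple(p), X, rho, beta, lam),
        cfg.pretrain_epochs,
        cfg.learning_rate,
    )
    return params[0], params[1]


def pretrain_stack(X: np.ndarray, cfg: SAEConfig, n_classes: int):
    """Greedy layer-wise pretraining of the two encoders."""
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    h1, h2 = cfg.resolve_hidden(d, n_classes)
    rng = np.random.default_rng(cfg.seed)
    enc1 = train_autoencoder(X, d, h1, cfg, rng)
    H1 = sigmoid(X @ enc1[0].T + enc1[1])
    enc2 = train_autoencoder(H1, h1, h2, cfg, rng)
    return enc1, enc2


@dataclass
class SAEModel:
    """A fitted SAE-SM: two sigmoid encoders under a softmax head."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    Ws: np.ndarray
    bs: np.ndarray
    classes_: np.ndarray
    scale_min: np.ndarray
    scale_range: np.ndarray
    config: SAEConfig = field(default_factory=SAEConfig)
    fitted: bool = True

    @property
    def input_dim(self) -> int:
        return self.W1.shape[1]

    @property
    def n_classes(self) -> int:
        return self.classes_.size

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.scale_min) / self.scale_range

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class-probability rows (softmax output, rows sum to 1)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError(f"expected N x {self.input_dim} input, got {X.shape}")
        Z = self._scale(X)
        H1 = sigmoid(Z @ self.W1.T + self.b1)
        H2 = sigmoid(H1 @ self.W2.T + self.b2)
        return softmax(H2 @ self.Ws.T + self.bs)

    def predict(self, X: np.ndarray) -> np.ndarray:
        P = self.predict_proba(X)
        return self.classes_[np.argmax(P, axis=1)]  # ties -> lowest class

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema": "subloc2l.sae-sm/1",
            "config": asdict(self.config),
            "classes": self.classes_.tolist(),
            "scale_min": self.scale_min.tolist(),
            "scale_range": self.scale_range.tolist(),
            "weights": {
                k: getattr(self, k).tolist()
                for k in ("W1", "b1", "W2", "b2", "Ws", "bs")
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SAEModel":
        w = {k: np.asarray(v, dtype=float) for k, v in d["weights"].items()}
        return cls(
            **w,
            classes_=np.asarray(d["classes"], dtype=int),
            scale_min=np.asarray(d["scale_min"], dtype=float),
            scale_range=np.asarray(d["scale_range"], dtype=float),
            config=SAEConfig(**d["config"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "SAEModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fine_tune(enc1, enc2, X, y, cfg: SAEConfig, n_classes: int | None = None,
              scale_min=None, scale_range=None) -> SAEModel:
    """Add a softmax head and fine-tune the whole network by backprop.

    ``X`` must already be scaled to [0, 1] (the scaling used during
    pretraining); the scaler is stored in the returned model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if n_classes is not None:
        expected = np.arange(1, n_classes + 1)
        if not np.array_equal(classes, expected):
            missing = sorted(set(expected) - set(classes))
            raise ValueError(f"classes absent from training labels: {missing}")
        classes = expected
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    C = classes.size
    Y = (y[:, None] == classes[None, :]).astype(float)

    rng = np.random.default_rng(cfg.seed + 1)
    W1, b1 = enc1[0].copy(), enc1[1].copy()
    W2, b2 = enc2[0].copy(), enc2[1].copy()
    Ws = _glorot(rng, C, W2.shape[0])
    bs = np.zeros(C)
    params = _descend(
        [W1, b1, W2, b2, Ws, bs],
        lambda p: net_grad(tuple(p), X, Y, cfg.l2_weight),
        cfg.finetune_epochs,
        cfg.learning_rate,
    )
    d = X.shape[1]
    if scale_min is None:
        scale_min = np.zeros(d)
    if scale_range is None:
        scale_range = np.ones(d)
    return SAEModel(
        W1=params[0], b1=params[1], W2=params[2], b2=params[3],
        Ws=params[4], bs=params[5],
        classes_=classes,
        scale_min=np.asarray(scale_min, dtype=float),
        scale_range=np.asarray(scale_range, dtype=float),
        config=cfg,
    )


def fit_sae(X: np.ndarray, y: np.ndarray, cfg: SAEConfig | None = None,
            n_classes: int | None = None) -> SAEModel:
    """Full SAE-SM training: scale, pretrain layer-wise, fine-tune.

    Inputs are min-max scaled to [0, 1] per feature on the training rows
    (sigmoid reconstruction targets must live in [0, 1]); the scaler is
    stored in the model and applied to any rows passed to predict.
    """
    if cfg is None:
        cfg = SAEConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.size:
        raise ValueError("row count must equal label count")
    lo = X.min(axis=0)
    rng_ = X.max(axis=0) - lo
    rng_[rng_ == 0] = 1.0
    Z = (X - lo) / rng_
    C = n_classes if n_classes is not None else np.unique(y).size
    enc1, enc2 = pretrain_stack(Z, cfg, C)
    model = fine_tune(enc1, enc2, Z, y, cfg, n_classes=n_classes,
                      scale_min=lo, scale_range=rng_)
    return model
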