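"""Shallow autoencoder with saturating-linear encoder, trained by SCG.

The model is a single-hidden-layer autoencoder mapping an n-sample EEG
epoch x to an m-dimensional code (m < n) and back:

    y    = satlin(W_E^T x + b_E)        encoder, satlin = clip to [-1, 1]
    xhat = W_D^T y + b_D                decoder, identity (purelin) output

Training minimizes mean squared reconstruction error over a batch of
epochs plus an L2 penalty on the weight matrices (biases excluded),
using scaled conjugate gradient. At deployment the decoder is discarded
and the encoder output serves as the feature vector for a conventional
classifier; the compression ratio is n/m.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._core import LabeledEpochSet
from .scg import SCGResult, minimize_scg


def satlin(v):
    """Symmetric saturating linear transfer function.

    Identity on [-1, 1], clipped to -1 below and +1 above. Scalar in,
    scalar out; array in, elementwise array out.
    """
    return np.clip(v, -1.0, 1.0)


@dataclass
class AEModel:
    """Trained (or raw) autoencoder parameters.

    ``W_E`` is (n, m), ``b_E`` is (m,); ``W_D`` is (m, n), ``b_D`` is (n,).
    ``decode_calls`` counts decoder evaluations, letting a pipeline assert
    that the deployed classification path is encoder-only.
    """

    W_E: np.ndarray
    b_E: np.ndarray
    W_D: np.ndarray
    b_D: np.ndarray
    use_decoder_bias: bool = True
    encoder_activation: str = "satlin"
    decoder_activation: str = "purelin"
    decode_calls: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.W_E = np.asarray(self.W_E, dtype=float)
        self.b_E = np.asarray(self.b_E, dtype=float)
        self.W_D = np.asarray(self.W_D, dtype=float)
        self.b_D = np.asarray(self.b_D, dtype=float)
        n, m = self.W_E.shape
        if m >= n:
            raise ValueError(f"hidden size m={m} must be smaller than input n={n}")
        if self.b_E.shape != (m,) or self.W_D.shape != (m, n) or self.b_D.shape != (n,):
            raise ValueError("inconsistent parameter shapes")
        for arr in (self.W_E, self.b_E, self.W_D, self.b_D):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite model parameters")

    @property
    def n(self) -> int:
        return self.W_E.shape[0]

    @property
    def m(self) -> int:
        return self.W_E.shape[1]

    # -- portable serialization: JSON header + base64 float64 blocks ------

    def save(self, path) -> None:
        def b64(a: np.ndarray) -> str:
            return base64.b64encode(np.ascontiguousarray(a, dtype="<f8").tobytes()).decode()

        doc = {
            "format": "seizae-ae-model",
            "n": self.n, "m": self.m,
            "encoder_activation": self.encoder_activation,
            "decoder_activation": self.decoder_activation,
            "use_decoder_bias": self.use_decoder_bias,
            "W_E": b64(self.W_E), "b_E": b64(self.b_E),
            "W_D": b64(self.W_D), "b_D": b64(self.b_D),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path) -> "AEModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "seizae-ae-model":
            raise ValueError(f"{path}: not an autoencoder model file")
        n, m = int(doc["n"]), int(doc["m"])

        def arr(key: str, shape) -> np.ndarray:
            a = np.frombuffer(base64.b64decode(doc[key]), dtype="<f8")
            return a.reshape(shape).copy()

        return cls(arr("W_E", (n, m)), arr("b_E", (m,)),
                   arr("W_D", (m, n)), arr("b_D", (n,)),
                   use_decoder_bias=bool(doc["use_decoder_bias"]),
                   encoder_activation=doc["encoder_activation"],
                   decoder_activation=doc["decoder_activation"])


@dataclass
class TrainConfig:
    """Autoencoder training hyperparameters.

    ``l2_coeff`` weights the L2 penalty on W_E and W_D (biases excluded).
    ``sigma0``/``lambda0`` are the SCG second-order step constant and
    initial damping. Training stops when the relative loss change stays
    below ``tol`` for 5 consecutive accepted iterations, or at
    ``max_iter``.
    """

    l2_coeff: float = 1e-4
    max_iter: int = 1000
    tol: float = 1e-8
    seed: int = 0
    sigma0: float = 1e-4
    lambda0: float = 1e-6
    use_decoder_bias: bool = True

    def __post_init__(self) -> None:
        if self.l2_coeff < 0:
            raise ValueError("l2_coeff must be non-negative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class TrainTrace:
    """Loss per accepted SCG iteration (non-increasing), plus termination info."""

    losses: list[float]
    n_iter: int
    reason: str


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, LabeledEpochSet):
        return data.X
    return np.atleast_2d(np.asarray(data, dtype=float))


def encode(model: AEModel, x) -> np.ndarray:
    """Encoder forward pass: satlin(W_E^T x + b_E), components in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.n:
        raise ValueError(f"input length {X.shape[1]} != model n {model.n}")
    Y = satlin(X @ model.W_E + model.b_E)
    return Y[0] if single else Y


def decode(model: AEModel, y) -> np.ndarray:
    """Decoder forward pass: W_D^T y (+ b_D), identity output activation."""
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = np.atleast_2d(y)
    if Y.shape[1] != model.m:
        raise ValueError(f"code length {Y.shape[1]} != model m {model.m}")
    model.decode_calls += 1
    Xhat = Y @ model.W_D
    if model.use_decoder_bias:
        Xhat = Xhat + model.b_D
    return Xhat[0] if single else Xhat


def loss(model: AEModel, data, l2_coeff: float = 0.0) -> float:
    """Mean squared reconstruction error plus L2 weight penalty.

    The mean runs over both batch and sample axes; the penalty is
    ``l2_coeff * (||W_E||_F^2 + ||W_D||_F^2)``, biases excluded.
    """
    X = _as_matrix(data)
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    Xhat = decode(model, encode(model, X))
    mse = float(np.mean((X - Xhat) ** 2))
    pen = l2_coeff * float(np.sum(model.W_E**2) + np.sum(model.W_D**2))
    return mse + pen


def _pack(W_E, b_E, W_D, b_D) -> np.ndarray:
    return np.concatenate([W_E.ravel(), b_E, W_D.ravel(), b_D])


def _unpack(w: np.ndarray, n: int, m: int):
    i = 0
    W_E = w[i:i + n * m].reshape(n, m); i += n * m
    b_E = w[i:i + m]; i += m
    W_D = w[i:i + m * n].reshape(m, n); i += m * n
    b_D = w[i:i + n]
    return W_E, b_E, W_D, b_D


def _loss_grad(w: np.ndarray, X: np.ndarray, n: int, m: int,
               l2: float, use_bias: bool) -> tuple[float, np.ndarray]:
    """Objective and analytic gradient for the packed parameter vector."""
    W_E, b_E, W_D, b_D = _unpack(w, n, m)
    N = X.shape[0]
    Z = X @ W_E + b_E
    Y = np.clip(Z, -1.0, 1.0)
    Xhat = Y @ W_D
    if use_bias:
        Xhat = Xhat + b_D
    R = Xhat - X
    f = float(np.mean(R**2)) + l2 * float(np.sum(W_E**2) + np.sum(W_D**2))
    dXhat = (2.0 / (N * n)) * R
    gW_D = Y.T @ dXhat + 2.0 * l2 * W_D
    gb_D = dXhat.sum(axis=0) if use_bias else np.zeros(n)
    dY = dXhat @ W_D.T
    dZ = dY * (np.abs(Z) <= 1.0)  # satlin subgradient: 1 on the linear segment
    gW_E = X.T @ dZ + 2.0 * l2 * W_E
    gb_E = dZ.sum(axis=0)
    return f, _pack(gW_E, gb_E, gW_D, gb_D)


def init_model(n: int, m: int, seed: int = 0,
               use_decoder_bias: bool = True) -> AEModel:
    """Seeded uniform init in +-sqrt(6/(n+m)) for weights; zero biases."""
    rng = np.random.default_rng(seed)
    bound = np.sqrt(6.0 / (n + m))
    return AEModel(
        W_E=rng.uniform(-bound, bound, size=(n, m)),
        b_E=np.zeros(m),
        W_D=rng.uniform(-bound, bound, size=(m, n)),
        b_D=np.zeros(n),
        use_decoder_bias=use_decoder_bias,
    )


def train_scg(data, hidden_size: int,
              cfg: TrainConfig | None = None) -> tuple[AEModel, TrainTrace]:
    """Train the autoencoder on a batch of epochs (labels, if any, ignored)."""
    cfg = cfg or TrainConfig()
    X = _as_matrix(data)
    n = X.shape[1]
    m = int(hidden_size)
    if m >= n:
        raise ValueError(f"hidden size m={m} must be smaller than epoch length n={n}")
    if m < 1:
        raise ValueError("hidden size must be at least 1")
    model0 = init_model(n, m, seed=cfg.seed, use_decoder_bias=cfg.use_decoder_bias)
    w0 = _pack(model0.W_E, model0.b_E, model0.W_D, model0.b_D)
    res: SCGResult = minimize_scg(
        lambda w: _loss_grad(w, X, n, m, cfg.l2_coeff, cfg.use_decoder_bias),
        w0, max_iter=cfg.max_iter, tol=cfg.tol,
        sigma0=cfg.sigma0, lambda0=cfg.lambda0)
    W_E, b_E, W_D, b_D = _unpack(res.w, n, m)
    model = AEModel(W_E, b_E, W_D, b_D, use_decoder_bias=cfg.use_decoder_bias)
    return model, TrainTrace(losses=res.losses, n_iter=res.n_iter, reason=res.reason)


def fit_feature_extractor(train_set, hidden_size: int,
                          cfg: TrainConfig | None = None,
                          folds: int = 5) -> tuple[AEModel, np.ndarray]:
    """K-fold reconstruction-error estimate, then a final refit on all epochs.

    Each fold trains on the complement and reports held-out reconstruction
    MSE (no L2 term); the returned model is retrained on the full set. The
    decoder exists only inside this routine's error estimates — deployment
    uses :func:`encode` alone.
    """
    cfg = cfg or TrainConfig()
    X = _as_matrix(train_set)
    N = X.shape[0]
    if folds < 2:
        raise ValueError("folds must be at least 2")
    if N < folds:
        raise ValueError(f"need at least {folds} epochs for {folds}-fold CV, got {N}")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(N)
    bounds = np.linspace(0, N, folds + 1).astype(int)
    fold_mse = np.empty(folds)
    for i in range(folds):
        held = order[bounds[i]:bounds[i + 1]]
        rest = np.setdiff1d(order, held)
        model_i, _ = train_scg(X[rest], hidden_size, cfg)
        Xhat = decode(model_i, encode(model_i, X[held]))
        fold_mse[i] = np.mean((X[held] - Xhat) ** 2)
    final_model, _ = train_scg(X, hidden_size, cfg)
    return final_model, fold_mse


def reconstruction_mae(model: AEModel, data) -> tuple[np.ndarray, float]:
    """Per-epoch mean absolute reconstruction error and its batch mean."""
    X = _as_matrix(data)
    Xhat = decode(model, encode(model, X))
    per_epoch = np.mean(np.abs(X - Xhat), axis=1)
    return per_epoch, float(np.mean(per_epoch))
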