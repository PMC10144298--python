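"""Ictal/interictal classification of encoded feature vectors.

Six classifier families operate on the autoencoder's latent codes:

* weighted kNN — 10 Euclidean nearest neighbors, squared-inverse-distance
  vote (native implementation; an exact-match query takes the matched
  point's label, and vote ties fall to the interictal class),
* Gaussian-kernel SVM — kernel scale 2, additive kernel offset 0.1 on
  every kernel evaluation; fitting delegates to a dual solver on the
  precomputed Gram matrix, the decision path is native,
* softmax — binary logistic map trained on binary cross-entropy with the
  same scaled-conjugate-gradient optimizer as the autoencoder,
* QDA — per-class maximum-likelihood Gaussians with a small ridge,
* kernel naive Bayes — per-feature Gaussian kernel densities with
  normal-reference bandwidth,
* decision tree — Gini impurity ('gdi') splits, capped at 159 nodes.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit, logsumexp
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ._core import ICTAL, INTERICTAL
from . import complexity
from .complexity import CountingConvention, DEFAULT_CONVENTION, OpCountReport
from .scg import minimize_scg

FAMILIES = ("knn", "svm", "qda", "nb", "dt", "softmax")

_ZERO_DIST = 1e-24  # squared distance below this is an exact match


@dataclass
class KNNConfig:
    k: int = 10
    metric: str = "euclidean"
    weighting: str = "squared_inverse"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")


@dataclass
class SVMConfig:
    kernel: str = "gaussian"
    kernel_scale: float = 2.0
    kernel_offset: float = 0.1
    box_constraint: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel_scale <= 0:
            raise ValueError("kernel_scale must be positive")
        if self.box_constraint <= 0:
            raise ValueError("box_constraint must be positive")


@dataclass
class SoftmaxConfig:
    max_iter: int = 500
    tol: float = 1e-10
    seed: int = 0


@dataclass
class TrainedClassifier:
    """A fitted decision function over encoded features.

    ``parameters`` holds family-specific state; ``predict`` /
    ``decision_scores`` below dispatch on ``family``.
    """

    family: str
    parameters: dict = field(default_factory=dict)
    classes: tuple[str, ...] = (ICTAL, INTERICTAL)
    n_features: int = 0

    def save(self, path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        obj = pickle.loads(Path(path).read_bytes())
        if not isinstance(obj, cls):
            raise ValueError(f"{path}: not a classifier file")
        return obj


def _check_features(F: np.ndarray) -> np.ndarray:
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite feature values")
    return F


def _gaussian_gram(A: np.ndarray, B: np.ndarray, cfg: SVMConfig) -> np.ndarray:
    """K(u, v) = exp(-||u-v||^2 / scale^2) + offset, for all pairs."""
    d2 = (np.sum(A**2, axis=1)[:, None] + np.sum(B**2, axis=1)[None, :]
          - 2.0 * A @ B.T)
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-d2 / cfg.kernel_scale**2) + cfg.kernel_offset


def fit(family: str, features, labels, config=None) -> TrainedClassifier:
    """Fit one classifier family on encoded features.

    ``labels`` are ``'ictal'`` / ``'interictal'`` strings. Single-class
    input is allowed only for kNN (which then predicts the sole class)
    and the tree/NB/QDA error out or degenerate per family semantics.
    """
    F = _check_features(features)
    y = np.asarray(labels, dtype=object)
    if y.shape[0] != F.shape[0]:
        raise ValueError("feature/label count mismatch")
    present = set(y.tolist())
    clf = TrainedClassifier(family=family, n_features=F.shape[1])

    if family == "knn":
        cfg = config or KNNConfig()
        clf.parameters = {"X": F.copy(), "y": y.copy(), "k": cfg.k}
        return clf

    if len(present) < 2:
        raise ValueError(f"{family} requires both classes in training data")

    if family == "svm":
        cfg = config or SVMConfig()
        t = np.where(y == ICTAL, 1.0, -1.0)
        G = _gaussian_gram(F, F, cfg)
        svc = SVC(C=cfg.box_constraint, kernel="precomputed")
        svc.fit(G, t)
        sv_idx = svc.support_
        clf.parameters = {
            "sv": F[sv_idx].copy(),
            # dual_coef_ = alpha_i * t_i over support vectors
            "dual_coef": svc.dual_coef_.ravel().copy(),
            "bias": float(svc.intercept_[0]),
            "cfg": cfg,
        }
        return clf

    if family == "softmax":
        cfg = config or SoftmaxConfig()
        t = np.where(y == ICTAL, 1.0, 0.0)
        m = F.shape[1]
        rng = np.random.default_rng(cfg.seed)
        w0 = np.concatenate([rng.uniform(-0.01, 0.01, size=m), [0.0]])

        def bce_grad(w):
            z = F @ w[:m] + w[m]
            p = expit(z)
            # numerically stable BCE via log(1+exp(-|z|))
            f = float(np.mean(np.logaddexp(0.0, z) - t * z))
            dz = (p - t) / F.shape[0]
            return f, np.concatenate([F.T @ dz, [dz.sum()]])

        res = minimize_scg(bce_grad, w0, max_iter=cfg.max_iter, tol=cfg.tol)
        clf.parameters = {"w": res.w[:m].copy(), "b": float(res.w[m]),
                          "losses": res.losses}
        return clf

    if family == "qda":
        params = {}
        for lab in (ICTAL, INTERICTAL):
            Fi = F[y == lab]
            mu = Fi.mean(axis=0)
            C = np.cov(Fi.T, bias=True).reshape(F.shape[1], F.shape[1])
            C = C + (1e-6 * np.trace(C) / F.shape[1] + 1e-12) * np.eye(F.shape[1])
            sign, logdet = np.linalg.slogdet(C)
            params[lab] = {"mu": mu, "prec": np.linalg.inv(C),
                           "logdet": logdet,
                           "logprior": np.log(Fi.shape[0] / F.shape[0])}
        clf.parameters = params
        return clf

    if family == "nb":
        params = {}
        for lab in (ICTAL, INTERICTAL):
            Fi = F[y == lab]
            sd = Fi.std(axis=0, ddof=1) if Fi.shape[0] > 1 else np.zeros(F.shape[1])
            # normal-reference (Silverman) bandwidth per feature
            h = 1.06 * sd * Fi.shape[0] ** (-1 / 5)
            h = np.where(h > 0, h, 1e-3)
            params[lab] = {"train": Fi.copy(), "h": h,
                           "logprior": np.log(Fi.shape[0] / F.shape[0])}
        clf.parameters = params
        return clf

    if family == "dt":
        # total node count of a binary tree = 2*leaves - 1 <= 159 -> 80 leaves
        tree = DecisionTreeClassifier(criterion="gini", max_leaf_nodes=80,
                                      random_state=0)
        tree.fit(F, y.astype(str))
        clf.parameters = {"tree": tree}
        return clf

    raise ValueError(f"unknown classifier family {family!r}")


def _knn_predict(p: dict, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Xtr, ytr, k = p["X"], p["y"], min(p["k"], p["X"].shape[0])
    out = np.empty(F.shape[0], dtype=object)
    scores = np.empty(F.shape[0])
    d2 = (np.sum(F**2, axis=1)[:, None] + np.sum(Xtr**2, axis=1)[None, :]
          - 2.0 * F @ Xtr.T)
    np.maximum(d2, 0.0, out=d2)
    for i in range(F.shape[0]):
        di = d2[i]
        zero = np.flatnonzero(di < _ZERO_DIST)
        if zero.size:  # exact match: squared-inverse weight diverges
            out[i] = ytr[zero[0]]
            scores[i] = np.inf if out[i] == ICTAL else -np.inf
            continue
        nn = np.argsort(di, kind="stable")[:k]
        w = 1.0 / di[nn]  # di is already the squared distance
        w_ict = float(w[ytr[nn] == ICTAL].sum())
        w_int = float(w[ytr[nn] == INTERICTAL].sum())
        # tie -> interictal (favors specificity)
        out[i] = ICTAL if w_ict > w_int else INTERICTAL
        scores[i] = w_ict - w_int
    return out, scores


def decision_scores(model: TrainedClassifier, features) -> np.ndarray:
    """Real-valued decision score per row; positive favors ictal."""
    F = _check_features(features)
    if F.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {F.shape[1]} != training dimension {model.n_features}")
    p = model.parameters
    fam = model.family
    if fam == "knn":
        return _knn_predict(p, F)[1]
    if fam == "svm":
        K = _gaussian_gram(F, p["sv"], p["cfg"])
        return K @ p["dual_coef"] + p["bias"]
    if fam == "softmax":
        return F @ p["w"] + p["b"]
    if fam == "qda":
        sc = {}
        for lab in (ICTAL, INTERICTAL):
            q = p[lab]
            D = F - q["mu"]
            sc[lab] = (-0.5 * np.einsum("ij,jk,ik->i", D, q["prec"], D)
                       - 0.5 * q["logdet"] + q["logprior"])
        return sc[ICTAL] - sc[INTERICTAL]
    if fam == "nb":
        sc = {}
        for lab in (ICTAL, INTERICTAL):
            q = p[lab]
            # log mean_j N(x_f; train_jf, h_f), summed over features f
            Z = (F[:, None, :] - q["train"][None, :, :]) / q["h"]
            logpdf = -0.5 * Z**2 - np.log(q["h"] * np.sqrt(2 * np.pi))
            sc[lab] = (logsumexp(logpdf, axis=1)
                       - np.log(q["train"].shape[0])).sum(axis=1) + q["logprior"]
        return sc[ICTAL] - sc[INTERICTAL]
    if fam == "dt":
        tree = p["tree"]
        proba = tree.predict_proba(F)
        i_ict = list(tree.classes_).index(ICTAL) if ICTAL in tree.classes_ else None
        return proba[:, i_ict] - 0.5 if i_ict is not None else np.full(F.shape[0], -1.0)
    raise ValueError(f"unknown classifier family {fam!r}")


def predict(model: TrainedClassifier, features) -> np.ndarray:
    """Predicted label per row ('ictal' / 'interictal')."""
    F = _check_features(features)
    if F.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {F.shape[1]} != training dimension {model.n_features}")
    if model.family == "knn":
        return _knn_predict(model.parameters, F)[0]
    if model.family == "dt":
        return model.parameters["tree"].predict(F).astype(object)
    s = decision_scores(model, F)
    return np.where(s > 0, ICTAL, INTERICTAL).astype(object)


def decision_ops(model: TrainedClassifier,
                 conv: CountingConvention = DEFAULT_CONVENTION) -> OpCountReport:
    """Multiplication/addition cost of one predict call for this model."""
    m = model.n_features
    if model.family == "svm":
        return complexity.svm_op_count(m, conv)
    if model.family == "knn":
        return complexity.knn_op_count(m, model.parameters["X"].shape[0], conv)
    if model.family == "softmax":
        return complexity.softmax_op_count(m, conv)
    raise ValueError(
        f"op counting is defined for knn/svm/softmax, not {model.family!r}")
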