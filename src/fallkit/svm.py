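"""Soft-margin RBF-kernel SVM detector.

Training is backed by scikit-learn's C-SVC (libsvm) with linear slacks;
the trained model is reduced to its portable parts — support vectors,
multipliers, bias, kernel width — and the decision function

    score(x) = sum_j D_j * alpha_j * exp(-gamma * ||X_j - x||^2) + b

is evaluated directly from those parts, so a saved model is a plain
text file with no pickle dependency.  ``sign(0)`` maps to -1 (no alarm).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from fallkit.features import FeatureSeries
from fallkit.training import LabeledFrameSet

__all__ = [
    "SvmModel",
    "rbf_kernel",
    "train",
    "decision",
    "decision_scores",
    "classify_series",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = "1"

DEFAULT_GAMMA = 5.3
DEFAULT_COST = 4.7


@dataclass
class SvmModel:
    """Support vectors, multipliers and bias of a trained RBF SVM."""

    support_vectors: np.ndarray  # (k, n)
    alphas: np.ndarray  # (k,), 0 < alpha_j <= C
    sv_labels: np.ndarray  # (k,), +/-1
    bias: float
    gamma: float
    cost: float
    param_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.support_vectors = np.asarray(self.support_vectors, dtype=float)
        self.alphas = np.asarray(self.alphas, dtype=float)
        self.sv_labels = np.asarray(self.sv_labels, dtype=int)
        k = self.support_vectors.shape[0]
        if not (len(self.alphas) == len(self.sv_labels) == k):
            raise ValueError("support vector / alpha / label counts differ")
        if np.any(self.alphas <= 0) or np.any(self.alphas > self.cost + 1e-9):
            raise ValueError("alphas must satisfy 0 < alpha <= C")

    @property
    def n_support(self) -> int:
        return self.support_vectors.shape[0]

    @property
    def n_features(self) -> int:
        return self.support_vectors.shape[1]

    @property
    def dual_coef(self) -> np.ndarray:
        """D_j * alpha_j for each stored vector."""
        return self.sv_labels * self.alphas


def rbf_kernel(x: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """Gaussian radial basis kernel ``exp(-gamma * ||x - y||^2)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    d2 = float(np.sum((x - y) ** 2))
    return float(np.exp(-gamma * d2))


def train(
    data: LabeledFrameSet,
    gamma: float = DEFAULT_GAMMA,
    cost: float = DEFAULT_COST,
    tol: float = 1e-6,
) -> SvmModel:
    """Fit the soft-margin dual and keep only the support vectors."""
    classes = np.unique(data.D)
    if len(classes) < 2:
        raise ValueError(f"training data contains a single class: {classes.tolist()}")
    clf = SVC(C=cost, kernel="rbf", gamma=gamma, tol=tol, cache_size=500)
    clf.fit(data.X, data.D)
    if clf.fit_status_ != 0:
        raise RuntimeError(
            f"SVM solver did not converge (fit_status={clf.fit_status_}, "
            f"m={len(data)}, gamma={gamma}, C={cost})"
        )
    dual = clf.dual_coef_.ravel()  # D_j * alpha_j, libsvm ordering
    sv_labels = np.sign(dual).astype(int)
    alphas = np.abs(dual)
    # libsvm orients the decision function by its internal class order;
    # clf.classes_ is sorted ([-1, 1]) so decision_function is already
    # positive on the +1 side and intercept_ is b.
    model = SvmModel(
        support_vectors=clf.support_vectors_.copy(),
        alphas=alphas,
        sv_labels=sv_labels,
        bias=float(clf.intercept_[0]),
        gamma=gamma,
        cost=cost,
        param_names=tuple(data.param_names),
    )
    return model


def decision_scores(model: SvmModel, X: np.ndarray, chunk: int = 8192) -> np.ndarray:
    """Vectorized decision scores for an (m, n) block of patterns."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"pattern dimension {X.shape[1]} != model dimension {model.n_features}"
        )
    sv = model.support_vectors
    sv_sq = np.einsum("ij,ij->i", sv, sv)
    coef = model.dual_coef
    out = np.empty(X.shape[0])
    for start in range(0, X.shape[0], chunk):
        blk = X[start : start + chunk]
        d2 = (
            np.einsum("ij,ij->i", blk, blk)[:, None]
            - 2.0 * blk @ sv.T
            + sv_sq[None, :]
        )
        np.maximum(d2, 0.0, out=d2)
        out[start : start + chunk] = np.exp(-model.gamma * d2) @ coef + model.bias
    return out


def decision(model: SvmModel, x: np.ndarray) -> tuple[float, int]:
    """Decision score and label for one pattern; sign(0) -> -1."""
    score = float(decision_scores(model, np.asarray(x, dtype=float)[None, :])[0])
    return score, (1 if score > 0 else -1)


def classify_series(
    model: SvmModel, feats: FeatureSeries, params: tuple[str, ...] | None = None
) -> np.ndarray:
    """Per-sample +/-1 labels for a feature series."""
    params = tuple(params) if params is not None else model.param_names
    if params != model.param_names:
        raise ValueError(
            f"parameter combination {params} does not match model {model.param_names}"
        )
    if len(feats) == 0:
        return np.empty(0, dtype=int)
    scores = decision_scores(model, feats.matrix(params))
    return np.where(scores > 0, 1, -1)


def save_model(model: SvmModel, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        f"fallkit-svm-model v{MODEL_FORMAT_VERSION}",
        "params " + ",".join(model.param_names),
        f"gamma {float(model.gamma)!r}",
        f"cost {float(model.cost)!r}",
        f"bias {float(model.bias)!r}",
        f"nsv {model.n_support}",
    ]
    for lbl, a, vec in zip(model.sv_labels, model.alphas, model.support_vectors):
        lines.append(
            f"{lbl:+d} {float(a)!r} " + " ".join(repr(float(v)) for v in vec)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def load_model(path: str | Path) -> SvmModel:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("fallkit-svm-model"):
        raise ValueError(f"{path}: not a fallkit SVM model file")
    version = lines[0].rsplit("v", 1)[-1].strip()
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {version!r} unsupported "
            f"(expected {MODEL_FORMAT_VERSION!r})"
        )
    try:
        header = dict(line.split(None, 1) for line in lines[1:6])
        params = tuple(header["params"].split(","))
        gamma = float(header["gamma"])
        cost = float(header["cost"])
        bias = float(header["bias"])
        nsv = int(header["nsv"])
        body = lines[6 : 6 + nsv]
        if len(body) != nsv:
            raise ValueError("truncated support vector block")
        labels, alphas, vecs = [], [], []
        for line in body:
            parts = line.split()
            labels.append(int(parts[0]))
            alphas.append(float(parts[1]))
            vecs.append([float(v) for v in parts[2:]])
    except (KeyError, IndexError, ValueError) as exc:
        raise ValueError(f"{path}: malformed model file ({exc})") from None
    return SvmModel(
        support_vectors=np.array(vecs),
        alphas=np.array(alphas),
        sv_labels=np.array(labels),
        bias=bias,
        gamma=gamma,
        cost=cost,
        param_names=params,
    )
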