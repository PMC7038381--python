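"""Extreme learning machines: the random-hidden-layer ELM and its kernel
variant (KELM), as statsmodels-style model objects.

Both are single-hidden-layer networks whose output weights have a
regularized least-squares closed form. With one-hot targets
T in R^{N x C} and regularization mu > 0:

ELM
    H_{nl} = g(w_l . x_n + b_l)  with random W, b,
    beta = (H'H + I_L / mu)^{-1} H'T        (N >= L, primal)
    beta = H'(HH' + I_N / mu)^{-1} T        (N <  L, dual)
    f(x) = g(xW' + b) beta.

KELM replaces the random feature map by a kernel, K_ij = k(x_i, x_j):
    f(x) = [k(x, x_1) ... k(x, x_N)] (K + I_N / mu)^{-1} T,
so the hidden width never needs choosing. The dual system is solved by a
Cholesky factorization (K + I/mu is symmetric positive definite for the RBF
kernel), never by explicit inversion. Predicted class = argmax of the score
row, ties broken toward the lowest class index.

Usage::

    model = KELM(X, y, mu=1000, theta=10)
    res = model.fit()
    res.predict(Xq)
    print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.spatial.distance import cdist

from .exceptions import (
    DatasetError,
    DimensionError,
    NumericalError,
    ParameterError,
)

__all__ = [
    "LabelEncoding",
    "one_hot_encode",
    "KELMConfig",
    "ELMConfig",
    "KELM",
    "KELMResults",
    "ELM",
    "ELMResults",
    "kelm_train",
    "kelm_predict",
    "elm_train",
]

_SCHEMA_VERSION = 1


# ------------------------------------------------------------- label coding
@dataclass
class LabelEncoding:
    """One-hot multi-class coding with a deterministic class order."""

    classes: list
    T: np.ndarray  # (N, C) one-hot targets
    labels: list

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def decode(self, scores: np.ndarray) -> np.ndarray:
        """Class of the maximal score per row (lowest index wins ties)."""
        idx = np.argmax(np.asarray(scores), axis=1)
        return np.asarray([self.classes[i] for i in idx], dtype=object)


def one_hot_encode(labels) -> LabelEncoding:
    """Encode labels as one-hot rows; classes sorted lexicographically."""
    labels = list(labels)
    if not labels:
        raise DatasetError("cannot encode an empty label list")
    classes = sorted(set(labels))
    pos = {c: k for k, c in enumerate(classes)}
    T = np.zeros((len(labels), len(classes)))
    for n, lab in enumerate(labels):
        T[n, pos[lab]] = 1.0
    return LabelEncoding(classes=classes, T=T, labels=labels)


# ------------------------------------------------------------------ configs
@dataclass
class KELMConfig:
    """mu: regularization coefficient (the sweep literature's gamma);
    theta: RBF kernel width. Defaults mu=1000, theta=10 — the empirically
    favorable settings for e-tongue features."""

    mu: float = 1000.0
    theta: float = 10.0
    kernel_name: str = "rbf"

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ParameterError(f"mu must be > 0, got {self.mu}")
        if not self.theta > 0:
            raise ParameterError(f"theta must be > 0, got {self.theta}")
        if self.kernel_name not in ("rbf", "linear"):
            raise ParameterError(f"unknown KELM kernel {self.kernel_name!r}")


@dataclass
class ELMConfig:
    """L: hidden-neuron count; W, b are drawn uniform on [-1, 1] from `seed`."""

    L: int = 100
    activation: str = "sigmoid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ParameterError(f"L must be >= 1, got {self.L}")
        if self.activation != "sigmoid":
            raise ParameterError(f"unknown activation {self.activation!r}")


def _gram(A: np.ndarray, B: np.ndarray, config: KELMConfig) -> np.ndarray:
    if config.kernel_name == "linear":
        return A @ B.T
    return np.exp(-cdist(A, B, metric="sqeuclidean") / (2.0 * config.theta**2))


def _as_matrix(X) -> np.ndarray:
    X = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise DatasetError("non-finite entries in feature matrix")
    return X


# --------------------------------------------------------------------- KELM
class KELM:
    """Kernel extreme learning machine built from a feature matrix + labels."""

    def __init__(self, X, y, mu: float = 1000.0, theta: float = 10.0,
                 kernel: str = "rbf", config: KELMConfig | None = None):
        self.config = config or KELMConfig(mu=mu, theta=theta, kernel_name=kernel)
        self.X = _as_matrix(X)
        self.encoding = one_hot_encode(y)
        if self.X.shape[0] != len(self.encoding.labels):
            raise DimensionError(
                f"{self.X.shape[0]} feature rows for {len(self.encoding.labels)} labels"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label", **kw) -> "KELM":
        y = df[label_col]
        X = df.drop(columns=[label_col])
        return cls(X, list(y), **kw)

    def fit(self) -> "KELMResults":
        K = _gram(self.X, self.X, self.config)
        N = K.shape[0]
        A_sys = K + np.eye(N) / self.config.mu
        try:
            cho = scipy.linalg.cho_factor(A_sys, lower=True)
            dual = scipy.linalg.cho_solve(cho, self.encoding.T)
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise NumericalError(
                f"(K + I/mu) factorization failed (N={N}, mu={self.config.mu}, "
                f"theta={self.config.theta}): {exc}"
            ) from exc
        return KELMResults(model=self, dual_coefficients=dual)


@dataclass
class KELMResults:
    """Fitted KELM: training features + dual coefficients (K + I/mu)^{-1} T."""

    model: KELM
    dual_coefficients: np.ndarray

    @property
    def encoding(self) -> LabelEncoding:
        return self.model.encoding

    @property
    def training_features(self) -> np.ndarray:
        return self.model.X

    def decision_function(self, Xq) -> np.ndarray:
        Xq = _as_matrix(Xq)
        if Xq.shape[1] != self.model.X.shape[1]:
            raise DimensionError(
                f"query width {Xq.shape[1]} != training width {self.model.X.shape[1]}"
            )
        Kq = _gram(Xq, self.model.X, self.model.config)
        return Kq @ self.dual_coefficients

    def predict(self, Xq) -> np.ndarray:
        return self.encoding.decode(self.decision_function(Xq))

    def score(self, Xq, y_true) -> float:
        """Fraction of correct predictions."""
        pred = self.predict(Xq)
        return float(np.mean(pred == np.asarray(list(y_true), dtype=object)))

    @property
    def training_residual(self) -> float:
        """Frobenius norm of the training score error, ||f(X) - T||_F."""
        scores = self.decision_function(self.model.X)
        return float(np.linalg.norm(scores - self.encoding.T))

    def summary(self) -> str:
        c = self.model.config
        lines = [
            "Kernel Extreme Learning Machine",
            "=" * 45,
            f"kernel:            {c.kernel_name} (theta={c.theta:g})",
            f"regularization mu: {c.mu:g}",
            f"training samples:  {self.model.X.shape[0]}",
            f"feature width:     {self.model.X.shape[1]}",
            f"classes ({self.encoding.n_classes}): {self.encoding.classes}",
            f"training accuracy: {100 * self.score(self.model.X, self.encoding.labels):.2f}%",
            f"training residual: {self.training_residual:.3e}",
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------ persistence
    def save(self, path: str | Path) -> None:
        """Portable bundle: .npz arrays + JSON sidecar (versioned schema)."""
        path = Path(path)
        np.savez_compressed(
            path,
            training_features=self.model.X,
            dual_coefficients=self.dual_coefficients,
        )
        meta = {
            "schema_version": _SCHEMA_VERSION,
            "model": "kelm",
            "classes": [str(c) for c in self.encoding.classes],
            "labels": [str(l) for l in self.encoding.labels],
            "mu": self.model.config.mu,
            "theta": self.model.config.theta,
            "kernel_name": self.model.config.kernel_name,
        }
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "KELMResults":
        path = Path(path)
        arrays = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        with open(path.with_suffix(".json")) as fh:
            meta = json.load(fh)
        model = KELM(
            arrays["training_features"],
            meta["labels"],
            config=KELMConfig(mu=meta["mu"], theta=meta["theta"],
                              kernel_name=meta["kernel_name"]),
        )
        return cls(model=model, dual_coefficients=arrays["dual_coefficients"])


# ---------------------------------------------------------------------- ELM
def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class ELM:
    """Random-hidden-layer ELM. `branch` forces the primal/dual closed form
    ("auto" picks primal when N >= L); the two are algebraically identical."""

    def __init__(self, X, y, L: int = 100, mu: float = 1000.0, seed: int = 0,
                 branch: str = "auto", config: ELMConfig | None = None):
        self.config = config or ELMConfig(L=L, seed=seed)
        if not mu > 0:
            raise ParameterError(f"mu must be > 0, got {mu}")
        if branch not in ("auto", "primal", "dual"):
            raise ParameterError(f"unknown branch {branch!r}")
        self.mu = mu
        self.branch = branch
        self.X = _as_matrix(X)
        self.encoding = one_hot_encode(y)
        if self.X.shape[0] != len(self.encoding.labels):
            raise DimensionError("feature rows / labels mismatch")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label", **kw) -> "ELM":
        y = df[label_col]
        return cls(df.drop(columns=[label_col]), list(y), **kw)

    def _hidden(self, X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
        return _sigmoid(X @ W.T + b)

    def fit(self) -> "ELMResults":
        N, p = self.X.shape
        L = self.config.L
        rng = np.random.default_rng(self.config.seed)
        W = rng.uniform(-1.0, 1.0, size=(L, p))
        b = rng.uniform(-1.0, 1.0, size=L)
        H = self._hidden(self.X, W, b)
        T = self.encoding.T
        branch = self.branch
        if branch == "auto":
            branch = "primal" if N >= L else "dual"
        try:
            if branch == "primal":
                beta = scipy.linalg.solve(
                    H.T @ H + np.eye(L) / self.mu, H.T @ T, assume_a="pos"
                )
            else:
                beta = H.T @ scipy.linalg.solve(
                    H @ H.T + np.eye(N) / self.mu, T, assume_a="pos"
                )
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise NumericalError(f"ELM solve failed ({branch}): {exc}") from exc
        return ELMResults(model=self, W=W, b=b, beta=beta, branch_used=branch)


@dataclass
class ELMResults:
    model: ELM
    W: np.ndarray
    b: np.ndarray
    beta: np.ndarray
    branch_used: str = "primal"

    @property
    def encoding(self) -> LabelEncoding:
        return self.model.encoding

    def decision_function(self, Xq) -> np.ndarray:
        Xq = _as_matrix(Xq)
        if Xq.shape[1] != self.W.shape[1]:
            raise DimensionError(
                f"query width {Xq.shape[1]} != training width {self.W.shape[1]}"
            )
        return self.model._hidden(Xq, self.W, self.b) @ self.beta

    def predict(self, Xq) -> np.ndarray:
        return self.encoding.decode(self.decision_function(Xq))

    def score(self, Xq, y_true) -> float:
        pred = self.predict(Xq)
        return float(np.mean(pred == np.asarray(list(y_true), dtype=object)))

    def summary(self) -> str:
        lines = [
            "Extreme Learning Machine",
            "=" * 45,
            f"hidden neurons L:  {self.model.config.L} ({self.branch_used} solve)",
            f"regularization mu: {self.model.mu:g}",
            f"seed:              {self.model.config.seed}",
            f"training samples:  {self.model.X.shape[0]}",
            f"classes ({self.encoding.n_classes}): {self.encoding.classes}",
            f"training accuracy: {100 * self.score(self.model.X, self.encoding.labels):.2f}%",
        ]
        return "\n".join(lines)


# --------------------------------------------- functional operation surface
def kelm_train(Xf, labels, config: KELMConfig | None = None) -> KELMResults:
    """Train a KELM (functional wrapper over KELM(...).fit())."""
    return KELM(Xf, labels, config=config or KELMConfig()).fit()


def kelm_predict(model: KELMResults, Xq) -> tuple[np.ndarray, np.ndarray]:
    """Scores (Q x C) and predicted labels for query features."""
    scores = model.decision_function(Xq)
    return scores, model.encoding.decode(scores)


def elm_train(Xf, labels, config: ELMConfig | None = None,
              mu: float = 1000.0, branch: str = "auto") -> ELMResults:
    """Train an ELM (functional wrapper over ELM(...).fit())."""
    config = config or ELMConfig()
    return ELM(Xf, labels, mu=mu, branch=branch, config=config).fit()
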