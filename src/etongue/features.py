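"""Feature specificity enhancement (FSE) and the kernel baseline method (KBM).

Two working electrodes driven by the same pulse excitation share a large
common-mode component; the class-informative signal is their half-difference.
Writing a pair of responses as

    x_i = x_c + x_s,    x_j = x_c - x_s,
    x_c = (x_i + x_j) / 2,    x_s = (x_i - x_j) / 2,

FSE maps every ordered electrode pair (i, j), i != j, to a single scalar

    Z_ij = k(x_i, x_j) = exp(-||x_i - x_j||^2 / (2 sigma^2))   (RBF kernel),

which depends on the difference only: the common-mode term cancels exactly.
A sample of m electrodes therefore yields m(m-1) features regardless of the
response length d. The contrast method KBM applies the same kernel to each
raw response norm, Z_i = exp(-||x_i||^2 / (2 sigma^2)), and retains the
common mode — it exists to quantify what common-mode cancellation buys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .dataset import LabeledDataset, SensorResponseMatrix
from .exceptions import DatasetError, DimensionError, ParameterError

__all__ = [
    "FSEConfig",
    "PairDecomposition",
    "FeatureVector",
    "rbf_kernel",
    "decompose_pair",
    "fse_transform",
    "kbm_transform",
    "transform_dataset",
    "save_feature_table",
    "load_feature_table",
]

_KNOWN_KERNELS = ("rbf", "polynomial", "sigmoid")


@dataclass
class FSEConfig:
    """Feature-extraction settings.

    sigma : float
        RBF kernel width, in the same units as the raw responses. Default 10,
        the geometric centre of the width range over which recognition is
        insensitive to sigma (see docs/methods.md).
    kernel_name : str
        Only ``"rbf"`` is implemented; ``"polynomial"``/``"sigmoid"`` are
        recognized names that raise ``NotImplementedError`` when used.
    unique_pairs : bool
        If True emit only the m(m-1)/2 unordered pairs (the RBF is symmetric,
        so ordered pairs duplicate values); default False keeps all m(m-1)
        ordered pairs, matching the method as published.
    zscore : bool
        Optional per-electrode standardization (mean 0, sd 1 over time)
        before the kernel; default off — raw units interact with sigma.
    """

    sigma: float = 10.0
    kernel_name: str = "rbf"
    unique_pairs: bool = False
    zscore: bool = False

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.kernel_name not in _KNOWN_KERNELS:
            raise ParameterError(
                f"unknown kernel {self.kernel_name!r}; known: {_KNOWN_KERNELS}"
            )

    def _require_rbf(self) -> None:
        if self.kernel_name != "rbf":
            raise NotImplementedError(
                f"kernel {self.kernel_name!r} is declared but not implemented; "
                "use 'rbf'"
            )


@dataclass
class PairDecomposition:
    """Common-mode / specificity split of one electrode pair."""

    common_mode: np.ndarray
    specificity: np.ndarray
    i: int
    j: int


@dataclass
class FeatureVector:
    """Extracted features of one sample.

    ``pair_index`` holds the 0-based (i, j) electrode pairs for FSE, or the
    electrode indices for KBM; ``names`` renders them 1-based ("Z_2_1", "Z_3")
    for table headers.
    """

    values: np.ndarray
    method: str
    pair_index: list[tuple] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        if self.method == "fse":
            return [f"Z_{i + 1}_{j + 1}" for i, j in self.pair_index]
        return [f"Z_{i + 1}" for (i,) in self.pair_index]

    def __len__(self) -> int:
        return len(self.values)


def rbf_kernel(u: np.ndarray, v: np.ndarray, sigma: float) -> float:
    """Gaussian kernel exp(-||u - v||^2 / (2 sigma^2)); 1 iff u == v."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise DimensionError(f"length mismatch: {u.shape} vs {v.shape}")
    if not sigma > 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    diff = u - v
    return float(np.exp(-(diff @ diff) / (2.0 * sigma**2)))


def decompose_pair(X: SensorResponseMatrix, i: int, j: int) -> PairDecomposition:
    """Split responses i and j into common-mode and specificity halves.

    The identity ``common + spec == x_i`` and ``common - spec == x_j`` holds
    exactly (it is plain affine arithmetic).
    """
    if i == j:
        raise ParameterError(f"pair requires i != j, got i = j = {i}")
    xi, xj = X.values[i], X.values[j]
    return PairDecomposition(
        common_mode=(xi + xj) / 2.0, specificity=(xi - xj) / 2.0, i=i, j=j
    )


def _prepare(X: SensorResponseMatrix, config: FSEConfig) -> np.ndarray:
    V = X.values
    if config.zscore:
        sd = V.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        V = (V - V.mean(axis=1, keepdims=True)) / sd
    return V


def fse_transform(X: SensorResponseMatrix, config: FSEConfig | None = None) -> FeatureVector:
    """All pairwise kernel features Z_ij = k(x_i, x_j), i != j.

    Ordered pairs are flattened row-major: (1,2), (1,3), ..., (m, m-1) —
    length m(m-1). With ``unique_pairs`` only i < j is kept (length
    m(m-1)/2). Every RBF feature lies in (0, 1]; adding the same vector to
    every electrode row leaves the output unchanged.
    """
    config = config or FSEConfig()
    config._require_rbf()
    V = _prepare(X, config)
    m = V.shape[0]
    if m < 2:
        raise DatasetError(f"FSE needs at least 2 electrodes, got {m}")
    # condensed pairwise squared distances, expanded to a symmetric matrix
    D = squareform(pdist(V, metric="sqeuclidean"))
    Z = np.exp(-D / (2.0 * config.sigma**2))
    if config.unique_pairs:
        pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    else:
        pairs = [(i, j) for i in range(m) for j in range(m) if j != i]
    values = np.array([Z[i, j] for i, j in pairs])
    return FeatureVector(values=values, method="fse", pair_index=pairs)


def kbm_transform(X: SensorResponseMatrix, config: FSEConfig | None = None) -> FeatureVector:
    """Per-electrode kernel of the raw norm: Z_i = exp(-||x_i||^2 / (2 sigma^2)).

    Unlike FSE this keeps the common-mode component: adding a shared vector
    to every row changes the output in general.
    """
    config = config or FSEConfig()
    config._require_rbf()
    V = _prepare(X, config)
    sq_norms = np.einsum("ij,ij->i", V, V)
    values = np.exp(-sq_norms / (2.0 * config.sigma**2))
    return FeatureVector(
        values=values, method="kbm", pair_index=[(i,) for i in range(V.shape[0])]
    )


_TRANSFORMS = {"fse": fse_transform, "kbm": kbm_transform}


def transform_dataset(
    data: LabeledDataset, method: str = "fse", config: FSEConfig | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Apply a per-sample transform to a whole dataset.

    Returns a feature table (rows = samples, columns named after electrode
    pairs) and the label series in the same order. The transform is
    unsupervised — labels are carried through, never read.
    """
    if method not in _TRANSFORMS:
        raise ParameterError(f"unknown method {method!r}; known: {list(_TRANSFORMS)}")
    fn = _TRANSFORMS[method]
    if len(data) == 0:
        return pd.DataFrame(), pd.Series([], dtype=object, name="label")
    first = fn(data[0], config)
    rows = np.empty((len(data), len(first)))
    rows[0] = first.values
    for n in range(1, len(data)):
        fv = fn(data[n], config)
        if len(fv) != len(first):
            raise DatasetError("samples produced inconsistent feature lengths")
        rows[n] = fv.values
    index = [s.sample_id or str(n) for n, s in enumerate(data)]
    X = pd.DataFrame(rows, columns=first.names, index=index)
    y = pd.Series(list(data.labels), index=index, name="label")
    return X, y


def save_feature_table(X: pd.DataFrame, y: pd.Series, path) -> None:
    """Write features + labels as one CSV (label first, pair-named columns)."""
    out = X.copy()
    out.insert(0, "label", y.values)
    out.to_csv(path, index_label="sample_id", float_format="%.17e")


def load_feature_table(path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, index_col="sample_id", float_precision="round_trip")
    y = df.pop("label")
    return df, y
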