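"""Cross-validation protocols, accuracy/STD reporting, and parameter sweeps.

Two protocols mirror standard e-tongue practice:

* ``loo_replicate`` — with R samples per class (balanced design), round r
  holds out the r-th sample of *every* class: R splits; 56 train / 7 test
  on the 63-sample beverage design.
* ``fourfold`` — a seeded stratified four-way grouping in which every class
  appears in every group and group sizes are as even as possible
  (28/29/28/29 on the 114-sample benchmark design).

``evaluate_model`` composes a feature extractor (fitted on training samples
only — extraction is unsupervised and, for FSE/KBM, stateless) with a
classifier, and aggregates per-split accuracies into a mean and standard
deviation in percent. Native classifiers are KELM and ELM; SVM, RF, LDA and
NB adapters (scikit-learn, fixed published settings) and PCA/DWT feature
adapters are optional conveniences for baseline grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import LabeledDataset
from .exceptions import CapabilityError, ParameterError, ProtocolError
from .features import FSEConfig, fse_transform, kbm_transform
from .kelm import ELMConfig, KELMConfig, ELM, KELM

__all__ = [
    "SplitPlan",
    "EvalResult",
    "SweepPoint",
    "make_loo_replicate_splits",
    "make_fourfold_splits",
    "evaluate_model",
    "sensitivity_sweep",
    "results_table",
]


@dataclass
class SplitPlan:
    """Train/test index pairs for one protocol."""

    splits: list[tuple[np.ndarray, np.ndarray]]
    protocol: str

    def __post_init__(self) -> None:
        for tr, te in self.splits:
            if np.intersect1d(tr, te).size:
                raise ProtocolError("train and test indices overlap")

    def __len__(self) -> int:
        return len(self.splits)

    def __iter__(self):
        return iter(self.splits)


def make_loo_replicate_splits(data: LabeledDataset) -> SplitPlan:
    """Hold out one sample per class per round.

    Requires the same number of samples R in every class; yields R splits
    whose test sets partition the dataset, each containing exactly one
    sample of each class (in stable within-class order).
    """
    labels = data.labels
    by_class: dict = {}
    for idx, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(idx)
    counts = {c: len(v) for c, v in by_class.items()}
    if len(set(counts.values())) != 1:
        raise ProtocolError(f"classes are unbalanced: {counts}")
    R = next(iter(counts.values()))
    n = len(data)
    splits = []
    for r in range(R):
        test = np.array(sorted(v[r] for v in by_class.values()))
        train = np.setdiff1d(np.arange(n), test)
        splits.append((train, test))
    return SplitPlan(splits=splits, protocol="loo_replicate")


def make_fourfold_splits(data: LabeledDataset, seed: int = 0,
                         n_folds: int = 4) -> SplitPlan:
    """Seeded stratified grouping into ``n_folds`` disjoint test groups.

    Within each class the samples are shuffled and dealt out so that every
    class reaches every group; per-class remainders rotate through the
    groups, keeping overall group sizes maximally even (|size difference|
    <= 1 across groups).
    """
    labels = data.labels
    by_class: dict = {}
    for idx, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(idx)
    for c, v in by_class.items():
        if len(v) < n_folds:
            raise ProtocolError(
                f"class {c!r} has {len(v)} samples < {n_folds} folds"
            )
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    rotation = 0
    for c in sorted(by_class, key=str):
        idxs = np.array(by_class[c])
        rng.shuffle(idxs)
        base, extra = divmod(len(idxs), n_folds)
        cursor = 0
        for k in range(n_folds):
            take = base + (1 if (k - rotation) % n_folds < extra else 0)
            folds[k].extend(idxs[cursor:cursor + take].tolist())
            cursor += take
        rotation = (rotation + extra) % n_folds
    n = len(data)
    splits = []
    for k in range(n_folds):
        test = np.array(sorted(folds[k]))
        train = np.setdiff1d(np.arange(n), test)
        splits.append((train, test))
    return SplitPlan(splits=splits, protocol="fourfold")


# ------------------------------------------------------- feature extractors
class _StatelessExtractor:
    """Per-sample transform with no training state (FSE, KBM, raw)."""

    def __init__(self, fn, config):
        self.fn, self.config = fn, config

    def fit(self, samples):
        return self

    def transform(self, samples) -> np.ndarray:
        return np.array([self.fn(s, self.config).values for s in samples])


class _RawExtractor:
    def __init__(self, config=None):
        pass

    def fit(self, samples):
        return self

    def transform(self, samples) -> np.ndarray:
        return np.array([s.values.ravel() for s in samples])


class _PCAExtractor:
    """PCA over flattened responses, fitted on the training split only."""

    def __init__(self, config=None, n_components: int = 20):
        self.n_components = n_components
        self._pca = None

    def fit(self, samples):
        from sklearn.decomposition import PCA

        flat = np.array([s.values.ravel() for s in samples])
        self._pca = PCA(
            n_components=min(self.n_components, *flat.shape), random_state=0
        ).fit(flat)
        return self

    def transform(self, samples) -> np.ndarray:
        flat = np.array([s.values.ravel() for s in samples])
        return self._pca.transform(flat)


class _DWTExtractor:
    """Per-electrode wavelet approximation coefficients, concatenated."""

    def __init__(self, config=None, wavelet: str = "db4", level: int | None = None):
        self.wavelet, self.level = wavelet, level

    def fit(self, samples):
        return self

    def transform(self, samples) -> np.ndarray:
        try:
            import pywt
        except ImportError as exc:  # pragma: no cover
            raise CapabilityError("DWT adapter requires PyWavelets") from exc
        rows = []
        for s in samples:
            d = s.values.shape[1]
            level = self.level or max(
                pywt.dwt_max_level(d, pywt.Wavelet(self.wavelet).dec_len) - 2, 1
            )
            rows.append(
                np.concatenate(
                    [pywt.wavedec(ch, self.wavelet, level=level)[0]
                     for ch in s.values]
                )
            )
        return np.array(rows)


_EXTRACTORS = {
    "fse": lambda cfg: _StatelessExtractor(fse_transform, cfg),
    "kbm": lambda cfg: _StatelessExtractor(kbm_transform, cfg),
    "rd": _RawExtractor,
    "pca": _PCAExtractor,
    "dwt": _DWTExtractor,
}


# ------------------------------------------------------------- classifiers
def _make_classifier(name: str, config):
    if name == "kelm":
        cfg = config or KELMConfig()

        class _K:
            def fit(self, X, y):
                self._res = KELM(X, y, config=cfg).fit()
                return self

            def predict(self, X):
                return self._res.predict(X)

        return _K()
    if name == "elm":
        cfg = config or ELMConfig()
        mu = getattr(cfg, "mu", 1000.0)

        class _E:
            def fit(self, X, y):
                self._res = ELM(X, y, mu=mu, config=cfg
                                if isinstance(cfg, ELMConfig) else None).fit()
                return self

            def predict(self, X):
                return self._res.predict(X)

        return _E()
    try:
        if name == "svm":
            from sklearn.svm import SVC

            return SVC(C=1000.0, gamma=0.001, kernel="rbf")
        if name == "rf":
            from sklearn.ensemble import RandomForestClassifier

            return RandomForestClassifier(n_estimators=50, random_state=0)
        if name == "lda":
            from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

            return LinearDiscriminantAnalysis()
        if name == "nb":
            from sklearn.naive_bayes import GaussianNB

            return GaussianNB()
    except ImportError as exc:
        raise CapabilityError(f"classifier adapter {name!r} unavailable") from exc
    raise ParameterError(f"unknown classifier {name!r}")


# ------------------------------------------------------------------ results
@dataclass
class EvalResult:
    """Per-split accuracies plus their mean and STD in percent."""

    per_split_accuracy: list[float]  # fractions in [0, 1]
    model_spec: dict = field(default_factory=dict)
    per_split_predictions: list = field(default_factory=list)
    per_split_truth: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        """Mean accuracy in percent."""
        return 100.0 * float(np.mean(self.per_split_accuracy))

    @property
    def std_accuracy(self) -> float:
        """Sample standard deviation (ddof=1) of split accuracies, percent."""
        accs = self.per_split_accuracy
        if len(accs) < 2:
            return 0.0
        return 100.0 * float(np.std(accs, ddof=1))

    def summary(self) -> str:
        spec = ", ".join(f"{k}={v}" for k, v in self.model_spec.items())
        return (
            f"{spec}\n"
            f"splits: {len(self.per_split_accuracy)}  "
            f"accuracy: {self.mean_accuracy:.2f}% +/- {self.std_accuracy:.2f}%"
        )


@dataclass
class SweepPoint:
    """One grid point of a sensitivity sweep; ``error`` is set (and
    ``result`` None) when the model could not be evaluated there, e.g.
    degenerate all-zero features crashing a classifier."""

    value: float
    result: EvalResult | None = None
    error: str | None = None


def evaluate_model(
    feature_method: str,
    feature_config: FSEConfig | None,
    classifier: str,
    classifier_config,
    data: LabeledDataset,
    plan: SplitPlan,
) -> EvalResult:
    """Run one (feature method, classifier) model through a split plan.

    For every split the extractor is fitted on the training samples only,
    both partitions are transformed, the classifier is fitted on the
    training features, and test accuracy is recorded.
    """
    if feature_method not in _EXTRACTORS:
        raise ParameterError(
            f"unknown feature method {feature_method!r}; known: {list(_EXTRACTORS)}"
        )
    labels = data.labels
    accs, preds, truths = [], [], []
    for train_idx, test_idx in plan:
        train = [data[i] for i in train_idx]
        test = [data[i] for i in test_idx]
        extractor = _EXTRACTORS[feature_method](feature_config).fit(train)
        F_tr = extractor.transform(train)
        F_te = extractor.transform(test)
        clf = _make_classifier(classifier, classifier_config)
        clf.fit(F_tr, list(labels[train_idx]))
        pred = np.asarray(clf.predict(F_te), dtype=object)
        truth = labels[test_idx]
        accs.append(float(np.mean(pred == truth)))
        preds.append(pred)
        truths.append(truth)
    return EvalResult(
        per_split_accuracy=accs,
        model_spec={
            "feature": feature_method,
            "classifier": classifier,
            "protocol": plan.protocol,
            **_config_fields(feature_config, classifier_config),
        },
        per_split_predictions=preds,
        per_split_truth=truths,
    )


def _config_fields(feature_config, classifier_config) -> dict:
    out = {}
    if feature_config is not None:
        out["sigma"] = feature_config.sigma
    if isinstance(classifier_config, KELMConfig):
        out["mu"] = classifier_config.mu
        out["theta"] = classifier_config.theta
    return out


def sensitivity_sweep(
    parameter: str,
    grid,
    data: LabeledDataset,
    plan: SplitPlan,
    feature_method: str = "fse",
    feature_config: FSEConfig | None = None,
    classifier: str = "kelm",
    classifier_config: KELMConfig | None = None,
) -> list[SweepPoint]:
    """Evaluate the model along a one-parameter grid, all else fixed.

    ``parameter``: ``sigma`` (feature kernel width), ``gamma``
    (regularization, a.k.a. mu) or ``theta`` (classifier kernel width).
    Grid points where evaluation fails are recorded with a diagnostic
    instead of aborting the sweep.
    """
    grid = list(grid)
    if not grid:
        raise ParameterError("sweep grid must be nonempty")
    if parameter not in ("sigma", "gamma", "theta"):
        raise ParameterError(f"unknown sweep parameter {parameter!r}")
    feature_config = feature_config or FSEConfig()
    classifier_config = classifier_config or (
        KELMConfig() if classifier == "kelm" else None
    )
    points = []
    for value in grid:
        fc, cc = feature_config, classifier_config
        if parameter == "sigma":
            fc = replace(feature_config, sigma=float(value))
        elif parameter == "gamma":
            cc = replace(classifier_config, mu=float(value))
        else:
            cc = replace(classifier_config, theta=float(value))
        try:
            res = evaluate_model(feature_method, fc, classifier, cc, data, plan)
            points.append(SweepPoint(value=float(value), result=res))
        except Exception as exc:  # record, don't abort: mirrors NB-on-zeros
            points.append(SweepPoint(value=float(value), error=str(exc)))
    return points


def results_table(results: list[EvalResult]) -> pd.DataFrame:
    """Tidy table of evaluation results (one row per model)."""
    rows = []
    for r in results:
        rows.append(
            {**r.model_spec, "mean_accuracy": round(r.mean_accuracy, 2),
             "std_accuracy": round(r.std_accuracy, 2),
             "n_splits": len(r.per_split_accuracy)}
        )
    return pd.DataFrame(rows)
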