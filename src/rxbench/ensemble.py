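"""Stacked heterogeneous ensembles of base classifications.

Training meta-features are produced by leave-one-out cross-validation so
row i's base prediction never comes from a model that saw row i; test
meta-features come from base models refit on the full training set. Base
columns can be passed through raw, z-scored, or min-max scaled (test
columns always transformed with training-set parameters), and a
meta-classifier from a small registry is trained on top. The reference
meta-classifier is a Naive Bayes with Gaussian-kernel density estimates
per feature and class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "loo_base_predictions",
    "normalize_predictions",
    "NaiveBayesKde",
    "stack",
    "META_CLASSIFIERS",
]


def loo_base_predictions(
    fit_fns: dict[str, callable], features: np.ndarray, labels: np.ndarray
) -> pd.DataFrame:
    """Leave-one-out base-model predictions on the training rows.

    ``fit_fns[name](X, y)`` must return a callable mapping rows to scores.
    Cell (i, name) is the prediction of model ``name`` trained on all rows
    except i, applied to row i.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = len(y)
    out = {}
    for name, fit in fit_fns.items():
        col = np.empty(n)
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            try:
                model = fit(X[keep], y[keep])
                col[i] = float(np.asarray(model(X[i : i + 1]))[0])
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(f"base model {name!r} failed on fold {i}") from exc
        out[name] = col
    df = pd.DataFrame(out)
    df["label"] = y
    return df


@dataclass
class _ColumnStats:
    mean: np.ndarray
    sd: np.ndarray
    lo: np.ndarray
    hi: np.ndarray


def _fit_stats(matrix: np.ndarray) -> _ColumnStats:
    return _ColumnStats(
        mean=matrix.mean(axis=0),
        sd=matrix.std(axis=0, ddof=0),
        lo=matrix.min(axis=0),
        hi=matrix.max(axis=0),
    )


def normalize_predictions(
    train_matrix: np.ndarray,
    method: str = "zscore",
    test_matrix: np.ndarray | None = None,
):
    """Per-column normalization: raw, zscore (mean 0, sd 1) or scale01
    (min 0, max 1). Test columns use training-set parameters; constant
    columns map to zeros with a warning.

    Returns the transformed training matrix, or a (train, test) pair.
    """
    if method not in ("raw", "zscore", "scale01"):
        raise ValueError("method must be raw, zscore or scale01")
    train = np.asarray(train_matrix, dtype=float)
    test = None if test_matrix is None else np.asarray(test_matrix, dtype=float)
    if method == "raw":
        return train if test is None else (train, test)
    st = _fit_stats(train)
    if method == "zscore":
        scale = st.sd.copy()
        center = st.mean
    else:
        scale = st.hi - st.lo
        center = st.lo
    const = scale == 0
    if const.any():
        warnings.warn("constant base column(s) mapped to zeros", stacklevel=2)
        scale = np.where(const, 1.0, scale)

    def tf(M):
        out = (M - center) / scale
        out[:, const] = 0.0
        return out

    return tf(train) if test is None else (tf(train), tf(test))


class NaiveBayesKde:
    """Naive Bayes with per-feature, per-class Gaussian kernel densities.

    The class-conditional density of feature j is the average of Gaussian
    kernels centered at the training values, with Silverman's rule-of-thumb
    bandwidth per feature and class (``bandwidth`` overrides it globally).
    The posterior is prior times the product of feature densities.
    """

    def __init__(self, bandwidth: float | None = None):
        self.bandwidth = bandwidth

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NaiveBayesKde":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training labels contain a single class")
        self._train = {}
        self._h = {}
        self._prior = {}
        for c in self.classes_:
            Xc = X[y == c]
            self._train[c] = Xc
            self._prior[c] = len(Xc) / len(y)
            if self.bandwidth is not None:
                h = np.full(X.shape[1], float(self.bandwidth))
            else:
                n = len(Xc)
                sd = Xc.std(axis=0, ddof=1) if n > 1 else np.ones(X.shape[1])
                iqr = (
                    np.subtract(*np.percentile(Xc, [75, 25], axis=0))
                    if n > 1
                    else np.ones(X.shape[1])
                )
                spread = np.where(iqr > 0, np.minimum(sd, iqr / 1.34), sd)
                h = 0.9 * spread * max(n, 2) ** (-0.2)
                h = np.where(h > 0, h, 1e-3)
            self._h[c] = h
        return self

    def _log_density(self, c, X: np.ndarray) -> np.ndarray:
        Xc = self._train[c]
        h = self._h[c]
        # (query, train, feature) kernel matrix, summed over train points
        z = (X[:, None, :] - Xc[None, :, :]) / h
        k = np.exp(-0.5 * z * z) / (np.sqrt(2 * np.pi) * h)
        dens = k.mean(axis=1)
        return np.log(np.maximum(dens, 1e-300)).sum(axis=1)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        logp = np.column_stack(
            [np.log(self._prior[c]) + self._log_density(c, X) for c in self.classes_]
        )
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict_positive(self, X: np.ndarray) -> np.ndarray:
        """Posterior probability of the positive (largest-label) class."""
        return self.predict_proba(X)[:, -1]


def _meta_logistic():
    m = LogisticRegression(max_iter=1000)
    return m


META_CLASSIFIERS: dict[str, callable] = {
    "nb_kde": lambda: NaiveBayesKde(),
    "logistic": _meta_logistic,
    "gaussian_nb": GaussianNB,
    "decision_tree": lambda: DecisionTreeClassifier(random_state=0),
}


def register_meta_classifier(name: str, factory) -> None:
    """Plug in an additional meta-classifier factory."""
    META_CLASSIFIERS[name] = factory


def stack(
    base_train: np.ndarray,
    labels: np.ndarray,
    base_test: np.ndarray,
    normalization: str = "zscore",
    meta: str = "nb_kde",
    bandwidth: float | None = None,
) -> np.ndarray:
    """Train a meta-classifier on normalized base predictions; score test rows.

    ``base_train`` should be leave-one-out predictions (see
    :func:`loo_base_predictions`); ``base_test`` the full-refit predictions
    on test subjects. Returns positive-class ensemble scores for the test
    rows, suitable for tie-aware scoring.
    """
    if meta not in META_CLASSIFIERS:
        raise ValueError(f"unknown meta-classifier {meta!r}")
    y = np.asarray(labels).astype(int)
    tr, te = normalize_predictions(base_train, normalization, base_test)
    if meta == "nb_kde":
        model = NaiveBayesKde(bandwidth=bandwidth)
        model.fit(tr, y)
        return model.predict_positive(te)
    model = META_CLASSIFIERS[meta]()
    model.fit(tr, y)
    return model.predict_proba(te)[:, -1]
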