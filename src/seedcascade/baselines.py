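"""Chemometric benchmark classifiers and evaluation protocols.

PLS-DA (partial least squares on one-hot targets, argmax decoding) and a
one-vs-rest RBF-kernel SVM, together with the two protocols used to score
them: a seeded stratified 7:3 split and stratified 10-fold cross-validation.
The fits themselves are delegated to scikit-learn; this module owns the
one-hot encoding/decoding, the protocol bookkeeping, and determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .errors import InvalidArgumentError
from .spectra import SpectrumSet


@dataclass
class SplitPlan:
    """Deterministic train/test partition (or CV fold assignment)."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    ratio: float
    stratified: bool
    rng_seed: int


def split_dataset(
    sset_or_labels,
    ratio: float = 0.7,
    stratified: bool = True,
    rng_seed: int = 0,
) -> SplitPlan:
    """Seeded (stratified) split: ``ratio`` of samples go to training.

    Accepts either a SpectrumSet with a label column chosen by the caller
    downstream, or a bare label array; stratification uses the joint
    variety/GM label when available.
    """
    if isinstance(sset_or_labels, SpectrumSet):
        labels = (
            sset_or_labels.joint_labels()
            if sset_or_labels.gm_labels is not None
            else sset_or_labels.variety_labels
        )
    else:
        labels = np.asarray(sset_or_labels, dtype=object)
    n = len(labels)
    if not 0 < ratio < 1:
        raise InvalidArgumentError("ratio must be in (0, 1)")
    if stratified:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < 2:
            raise InvalidArgumentError("stratified split needs >= 2 samples per class")
    idx = np.arange(n)
    tr, te = train_test_split(
        idx,
        train_size=ratio,
        stratify=labels if stratified else None,
        random_state=rng_seed,
        shuffle=True,
    )
    return SplitPlan(np.sort(tr), np.sort(te), ratio, stratified, rng_seed)


class PLSDAModel:
    """PLS2 regression of one-hot targets on centered spectra, argmax decode."""

    def __init__(self, n_latent: int = 5):
        self.n_latent = n_latent
        self.classes_: np.ndarray | None = None
        self._pls: PLSRegression | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PLSDAModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        self.classes_ = np.unique(y)
        if self.n_latent > min(X.shape[0] - 1, X.shape[1]):
            raise InvalidArgumentError(
                f"n_latent={self.n_latent} exceeds min(n_samples-1, n_bands)"
            )
        onehot = (y[:, None] == self.classes_[None, :]).astype(float)
        self._pls = PLSRegression(n_components=self.n_latent, scale=False)
        self._pls.fit(X, onehot)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self._pls.predict(np.asarray(X, dtype=float)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[scores.argmax(axis=1)]  # ties -> lowest index


def plsda_fit(train: SpectrumSet, labels: np.ndarray, n_latent: int = 5) -> PLSDAModel:
    return PLSDAModel(n_latent).fit(train.spectra, labels)


def plsda_predict(model: PLSDAModel, spectra: np.ndarray | SpectrumSet) -> np.ndarray:
    X = spectra.spectra if isinstance(spectra, SpectrumSet) else spectra
    return model.predict(X)


class SVMModel:
    """One-vs-rest RBF SVM; width defaults to 1 / (n_bands * Var(X))."""

    def __init__(self, C: float = 100.0, gamma: str | float = "scale"):
        self.C, self.gamma = C, gamma
        self._ovr: OneVsRestClassifier | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVMModel":
        y = np.asarray(y, dtype=object).astype(str)
        if np.unique(y).size < 2:
            raise InvalidArgumentError("SVM needs at least 2 classes")
        self._ovr = OneVsRestClassifier(SVC(C=self.C, kernel="rbf", gamma=self.gamma))
        self._ovr.fit(np.asarray(X, dtype=float), y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._ovr.predict(np.asarray(X, dtype=float)).astype(object)


def svm_fit(train: SpectrumSet, labels: np.ndarray, C: float = 100.0,
            gamma: str | float = "scale") -> SVMModel:
    return SVMModel(C, gamma).fit(train.spectra, labels)


def svm_predict(model: SVMModel, spectra: np.ndarray | SpectrumSet) -> np.ndarray:
    X = spectra.spectra if isinstance(spectra, SpectrumSet) else spectra
    return model.predict(X)


def crossval(
    model_builder,
    X: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    rng_seed: int = 0,
) -> dict:
    """Stratified k-fold CV; pooled accuracy over out-of-fold predictions.

    ``model_builder()`` must return a fresh object with fit/predict.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=object)
    if k > len(y):
        raise InvalidArgumentError(f"k={k} exceeds n_samples={len(y)}")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise InvalidArgumentError("stratified CV needs >= k samples per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
    fold_acc = []
    pooled_pred = np.empty(len(y), dtype=object)
    for tr, te in skf.split(X, y.astype(str)):
        model = model_builder()
        model.fit(X[tr], y[tr])
        pred = np.asarray(model.predict(X[te]), dtype=object)
        pooled_pred[te] = pred
        fold_acc.append(float((pred == y[te]).mean()))
    return {
        "fold_accuracy": fold_acc,
        "pooled_accuracy": float((pooled_pred == y).mean()),
    }
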