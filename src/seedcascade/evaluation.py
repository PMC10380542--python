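"""Confusion matrices, classification metrics, PCA scores and transfer matrices.

Metrics follow the usual multiclass conventions: per-class precision
``TP/(TP+FP)`` and recall ``TP/(TP+FN)``, macro F1 as the unweighted mean of
per-class F1 over all named classes, and micro F1 from pooled counts — which
for single-label classification is algebraically identical to accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .spectra import SpectrumSet


@dataclass
class ConfusionMatrix:
    """Integer tabulation, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_names)
        if self.counts.shape != (k, k) or np.any(self.counts < 0):
            raise InvalidArgumentError("counts must be a nonnegative k x k matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp

    @property
    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp

    def row_normalized(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.counts / self.counts.sum(axis=1, keepdims=True)
        return np.nan_to_num(out)


@dataclass
class EvalReport:
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_f1: float
    micro_f1: float
    confusion: ConfusionMatrix
    degenerate_classes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "micro_f1": self.micro_f1,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "class_names": self.confusion.class_names,
            "confusion_counts": self.confusion.counts.tolist(),
            "degenerate_classes": self.degenerate_classes,
        }


def confusion_matrix(true_labels, predicted_labels, class_names=None) -> ConfusionMatrix:
    """Exact integer tabulation of (true, predicted) pairs."""
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    if t.shape != p.shape:
        raise InvalidArgumentError("label arrays differ in length")
    if class_names is None:
        class_names = sorted({str(x) for x in np.concatenate([t, p])})
    class_names = [str(c) for c in class_names]
    index = {c: i for i, c in enumerate(class_names)}
    counts = np.zeros((len(class_names), len(class_names)), dtype=int)
    for ti, pi in zip(t, p):
        if str(ti) not in index:
            raise InvalidArgumentError(f"unknown true label {ti!r}")
        if str(pi) not in index:
            raise InvalidArgumentError(f"unknown predicted label {pi!r}")
        counts[index[str(ti)], index[str(pi)]] += 1
    return ConfusionMatrix(counts, class_names)


def classification_metrics(cm: ConfusionMatrix) -> EvalReport:
    """Accuracy, per-class precision/recall/F1, macro and micro F1.

    Classes with an empty precision or recall denominator score 0 for that
    metric (and are flagged) — the ratio is undefined there.
    """
    if cm.total == 0:
        raise InvalidArgumentError("empty confusion matrix")
    tp, fp, fn = cm.tp.astype(float), cm.fp.astype(float), cm.fn.astype(float)
    degenerate = []
    precision, recall, f1 = {}, {}, {}
    for i, name in enumerate(cm.class_names):
        pden, rden = tp[i] + fp[i], tp[i] + fn[i]
        if pden == 0 or rden == 0:
            degenerate.append(name)
        prec = tp[i] / pden if pden > 0 else 0.0
        rec = tp[i] / rden if rden > 0 else 0.0
        precision[name] = prec
        recall[name] = rec
        f1[name] = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    if degenerate:
        warnings.warn(
            f"precision/recall undefined (set to 0) for classes: {degenerate}",
            RuntimeWarning,
            stacklevel=2,
        )
    macro_f1 = float(np.mean(list(f1.values())))
    micro_p = tp.sum() / (tp.sum() + fp.sum()) if tp.sum() + fp.sum() > 0 else 0.0
    micro_r = tp.sum() / (tp.sum() + fn.sum()) if tp.sum() + fn.sum() > 0 else 0.0
    micro_f1 = 2 * micro_p * micro_r / (micro_p + micro_r) if micro_p + micro_r > 0 else 0.0
    accuracy = float(tp.sum() / cm.total)
    return EvalReport(
        accuracy, precision, recall, f1, macro_f1, float(micro_f1), cm, degenerate
    )


def evaluate_predictions(true_labels, predicted_labels, class_names=None) -> EvalReport:
    return classification_metrics(confusion_matrix(true_labels, predicted_labels, class_names))


def pca_scores(sset: SpectrumSet | np.ndarray, n_components: int = 2):
    """Mean-centered PCA scores and explained-variance fractions.

    Sign convention: within each component the loading with the largest
    magnitude is made positive, so score plots are deterministic.
    """
    X = sset.spectra if isinstance(sset, SpectrumSet) else np.asarray(sset, dtype=float)
    n, b = X.shape
    if n_components > min(n - 1, b):
        raise InvalidArgumentError("n_components exceeds min(n_samples - 1, n_bands)")
    Xc = X - X.mean(axis=0)
    total_var = float((Xc**2).sum())
    if total_var == 0:
        raise InvalidArgumentError("degenerate input: data have zero variance")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    scores = (U * S)[:, :n_components]
    explained = (S**2 / (S**2).sum())[:n_components]
    return scores, explained


def cross_variety_matrix(
    gm_registry: dict, per_variety_test_sets: dict[str, SpectrumSet]
) -> tuple[np.ndarray, list[str]]:
    """Accuracy of variety-i's GM model evaluated on variety-j's test set.

    Rows index the model's home variety, columns the evaluated variety.
    Off-diagonal entries quantify how poorly a GM detector transfers across
    genetic backgrounds.
    """
    varieties = sorted(gm_registry)
    for v, s in per_variety_test_sets.items():
        if s.gm_labels is None:
            raise InvalidArgumentError(f"test set for {v!r} lacks GM labels")
    axes = [s.band_axis for s in per_variety_test_sets.values()]
    if any(a != axes[0] for a in axes[1:]):
        raise InvalidArgumentError("test sets use different band axes")
    mat = np.zeros((len(varieties), len(varieties)))
    for i, vi in enumerate(varieties):
        model = gm_registry[vi]
        for j, vj in enumerate(varieties):
            test = per_variety_test_sets.get(vj)
            if test is None:
                raise InvalidArgumentError(f"no test set for variety {vj!r}")
            pred = model.predict(test.spectra)
            mat[i, j] = float((pred == test.gm_labels).mean())
    return mat, varieties
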