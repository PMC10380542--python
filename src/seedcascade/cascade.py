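"""Multireceptive-field 1-D CNN and the two-phase cascade classifier.

Architecture
------------
The network consumes a single spectrum as a 1-channel signal of length
``n_bands`` and stacks:

1. *Module 1* — four parallel stride-1 convolutions with kernel sizes
   1/3/5/7 (``module1_filters`` each, 'same' padding), summed elementwise
   and passed through a rectifier.  The raw spectrum is then concatenated
   back along the channel axis, so a 128-filter module feeds 129 channels
   forward: the model can reuse the unprocessed signal while going deeper.
2. *Module 2* — the same four-kernel pattern with ``module2_filters``
   filters, summed and rectified (no second concatenation).
3. Two common stride-1 convolutions (kernel 3, padding 1) with
   ``common_filters`` filters, each followed by max pooling
   (kernel 3 / stride 2 / padding 1) which roughly halves the length.
4. A single affine head from the flattened features to the class scores.

Softmax is applied only at inference time to turn scores into confidences.

Two-phase inference: a 3-class variety model picks the variety; the same
spectrum is then routed to that variety's dedicated binary GM-status model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .errors import (
    DivergenceError,
    InvalidArgumentError,
    InvalidTrainingSetError,
    MissingModelError,
)
from .spectra import BandAxis, SpectrumSet

softmax = nn.softmax


@dataclass(frozen=True)
class ModelSpec:
    """Structural hyperparameters of the spectral CNN.

    The defaults (128/64 module filters, 64+32 common filters) are the
    full-scale architecture; the ``scaled`` constructor builds
    proportionally slimmer models for quick experiments.
    """

    n_bands: int
    n_classes: int
    module1_filters: int = 128
    module2_filters: int = 64
    common_filters: tuple[int, int] = (64, 32)
    kernel_sizes: tuple[int, ...] = (1, 3, 5, 7)
    dtype: str = "float32"

    def __post_init__(self):
        if self.n_classes < 2:
            raise InvalidArgumentError("need at least 2 classes")
        if self.n_bands < 8:
            raise InvalidArgumentError("need n_bands >= 8 for two pooling stages")

    @classmethod
    def scaled(cls, n_bands: int, n_classes: int, scale: int = 8, **kw) -> "ModelSpec":
        """Slim variant: all widths divided by ``scale`` (min 4 filters)."""
        return cls(
            n_bands,
            n_classes,
            module1_filters=max(4, 128 // scale),
            module2_filters=max(4, 64 // scale),
            common_filters=(max(4, 64 // scale), max(4, 32 // scale)),
            **kw,
        )

    @property
    def pooled_length(self) -> int:
        L = nn.MaxPool1d.out_length(self.n_bands)
        return nn.MaxPool1d.out_length(L)

    @property
    def flat_features(self) -> int:
        return self.common_filters[1] * self.pooled_length

    @property
    def module2_in_channels(self) -> int:
        return self.module1_filters + 1


class CascadeNet:
    """The network itself; see the module docstring for the layout."""

    def __init__(self, spec: ModelSpec, rng_seed: int = 0):
        self.spec = spec
        dtype = np.dtype(spec.dtype)
        rng = np.random.default_rng(rng_seed)
        self.module1 = [nn.Conv1d(1, spec.module1_filters, k, rng, dtype) for k in spec.kernel_sizes]
        c2_in = spec.module1_filters + 1
        self.module2 = [nn.Conv1d(c2_in, spec.module2_filters, k, rng, dtype) for k in spec.kernel_sizes]
        self.relu1, self.relu2 = nn.ReLU(), nn.ReLU()
        self.conv_a = nn.Conv1d(spec.module2_filters, spec.common_filters[0], 3, rng, dtype)
        self.relu_a = nn.ReLU()
        self.pool_a = nn.MaxPool1d()
        self.conv_b = nn.Conv1d(spec.common_filters[0], spec.common_filters[1], 3, rng, dtype)
        self.relu_b = nn.ReLU()
        self.pool_b = nn.MaxPool1d()
        self.head = nn.Linear(spec.flat_features, spec.n_classes, rng, dtype)
        self._flat_shape: tuple | None = None

    # -- parameter plumbing -------------------------------------------
    @property
    def layers_with_params(self):
        return [*self.module1, *self.module2, self.conv_a, self.conv_b, self.head]

    @property
    def params(self):
        return [pg for layer in self.layers_with_params for pg in layer.params]

    def state_dict(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for (p, _), s in zip(self.params, state):
            p[...] = s

    # -- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Spectra ``(B, n_bands)`` -> raw class scores ``(B, n_classes)``."""
        x = np.asarray(x, dtype=self.spec.dtype)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.spec.n_bands:
            raise InvalidArgumentError(
                f"model expects {self.spec.n_bands} bands, got {x.shape[1]}"
            )
        x3 = x[:, None, :]
        m1 = self.relu1.forward(sum(c.forward(x3) for c in self.module1))
        h = np.concatenate([m1, x3], axis=1)
        m2 = self.relu2.forward(sum(c.forward(h) for c in self.module2))
        a = self.pool_a.forward(self.relu_a.forward(self.conv_a.forward(m2)))
        b = self.pool_b.forward(self.relu_b.forward(self.conv_b.forward(a)))
        self._flat_shape = b.shape
        return self.head.forward(b.reshape(b.shape[0], -1))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backprop score gradients; returns the gradient w.r.t. the input."""
        g = self.head.backward(dlogits.astype(self.spec.dtype)).reshape(self._flat_shape)
        g = self.conv_b.backward(self.relu_b.backward(self.pool_b.backward(g)))
        g = self.conv_a.backward(self.relu_a.backward(self.pool_a.backward(g)))
        g = self.relu2.backward(g)
        g = sum(c.backward(g) for c in self.module2)
        gm1 = self.relu1.backward(g[:, :-1, :])
        gx3 = g[:, -1:, :].copy()
        gx3 += sum(c.backward(gm1) for c in self.module1)
        return gx3[:, 0, :]


def build_cascadenet(spec: ModelSpec, rng_seed: int = 0) -> CascadeNet:
    """Construct and Kaiming-initialize the network for ``spec``."""
    return CascadeNet(spec, rng_seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimization protocol.

    The full-scale protocol trains for 10,000 epochs at learning rate 5e-4
    with batch size 256, carving a stratified 10% validation split out of
    the training set and keeping the parameters with the best validation
    accuracy.  Experiments in this package override ``epochs`` downward.
    """

    epochs: int = 10_000
    learning_rate: float = 5e-4
    batch_size: int = 256
    val_fraction: float = 0.10
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.val_fraction < 1:
            raise InvalidArgumentError("val_fraction must be in (0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise InvalidArgumentError("batch_size and epochs must be >= 1")


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = -1.0


class SpectrumClassifier:
    """A trained CascadeNet bound to class names and a band axis."""

    def __init__(self, net: CascadeNet, class_names: list[str], band_axis: BandAxis):
        self.net = net
        self.class_names = list(class_names)
        self.band_axis = band_axis

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def predict_logits(self, X: np.ndarray, batch: int = 512) -> np.ndarray:
        out = [self.net.forward(X[i:i + batch]) for i in range(0, len(X), batch)]
        return np.vstack(out).astype(float)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.predict_logits(X))

    def predict_indices(self, X: np.ndarray) -> np.ndarray:
        return self.predict_logits(X).argmax(axis=1)  # argmax ties -> lowest index

    def predict(self, X: np.ndarray) -> np.ndarray:
        names = np.asarray(self.class_names, dtype=object)
        return names[self.predict_indices(X)]


def _stratified_split(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Per-class held-out indices (at least 1 per class)."""
    hold, keep = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_hold = max(1, int(round(fraction * idx.size)))
        if n_hold >= idx.size:
            raise InvalidTrainingSetError(f"class {cls!r} too small for a validation split")
        hold.append(idx[:n_hold])
        keep.append(idx[n_hold:])
    return np.sort(np.concatenate(keep)), np.sort(np.concatenate(hold))


def train_model(
    train: SpectrumSet,
    labels: np.ndarray,
    cfg: TrainConfig,
    spec: ModelSpec | None = None,
    class_names: list[str] | None = None,
) -> tuple[SpectrumClassifier, TrainHistory]:
    """Train a CascadeNet on ``train`` with per-sample ``labels``.

    Minimizes mean cross-entropy with Adam; tracks validation accuracy each
    epoch on a stratified, seeded 10% carve-out and returns the parameter
    snapshot with the highest validation accuracy (earliest epoch on ties).
    """
    y_names = np.asarray(labels, dtype=object)
    if class_names is None:
        class_names = sorted({str(v) for v in y_names})
    if len(class_names) < 2:
        raise InvalidTrainingSetError("training set must contain at least 2 classes")
    name_to_idx = {n: i for i, n in enumerate(class_names)}
    try:
        y = np.array([name_to_idx[str(v)] for v in y_names], dtype=int)
    except KeyError as exc:
        raise InvalidArgumentError(f"label {exc.args[0]!r} not in class_names") from exc
    counts = np.bincount(y, minlength=len(class_names))
    if np.any(counts < 2):
        raise InvalidTrainingSetError("every class needs at least 2 samples")

    spec = spec or ModelSpec(train.n_bands, len(class_names))
    if spec.n_bands != train.n_bands or spec.n_classes != len(class_names):
        raise InvalidArgumentError("ModelSpec does not match the training data")
    rng = np.random.default_rng(cfg.rng_seed)
    net = CascadeNet(spec, rng_seed=int(rng.integers(2**31)))
    X = train.spectra.astype(spec.dtype)
    tr_idx, val_idx = _stratified_split(y, cfg.val_fraction, rng)
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    opt = nn.Adam(net.params, lr=cfg.learning_rate)
    hist = TrainHistory()
    best_state = net.state_dict()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(Xtr))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            logits = net.forward(Xtr[sel])
            loss, dlogits = nn.cross_entropy(logits, ytr[sel])
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}", step=epoch)
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(sel)
        hist.loss.append(epoch_loss / len(Xtr))
        val_pred = np.vstack(
            [net.forward(Xval[i:i + 512]) for i in range(0, len(Xval), 512)]
        ).argmax(axis=1)
        val_acc = float((val_pred == yval).mean())
        hist.val_accuracy.append(val_acc)
        if val_acc > hist.best_val_accuracy:
            hist.best_val_accuracy = val_acc
            hist.best_epoch = epoch
            best_state = net.state_dict()
    net.load_state(best_state)
    return SpectrumClassifier(net, class_names, train.band_axis), hist


# ---------------------------------------------------------------------------
# cascade container
# ---------------------------------------------------------------------------

@dataclass
class CascadeModel:
    """Phase-1 variety model plus per-variety binary GM models."""

    variety_model: SpectrumClassifier
    gm_registry: dict[str, SpectrumClassifier]


def cascade_predict(cascade: CascadeModel, sset: SpectrumSet) -> pd.DataFrame:
    """Two-phase prediction for every spectrum in ``sset``.

    Phase 1 picks the variety by softmax argmax; the identical spectrum is
    then handed to that variety's GM model.  Raises
    :class:`MissingModelError` if a predicted variety has no registry entry.
    """
    vm = cascade.variety_model
    if sset.n_bands != vm.net.spec.n_bands:
        raise InvalidArgumentError("band count does not match the variety model")
    proba1 = vm.predict_proba(sset.spectra)
    v_idx = proba1.argmax(axis=1)
    varieties = np.asarray(vm.class_names, dtype=object)[v_idx]
    v_conf = proba1[np.arange(len(v_idx)), v_idx]
    gm_out = np.empty(len(v_idx), dtype=object)
    gm_conf = np.empty(len(v_idx), dtype=float)
    for variety in np.unique(varieties):
        if variety not in cascade.gm_registry:
            raise MissingModelError(str(variety))
        rows = np.flatnonzero(varieties == variety)
        sub = cascade.gm_registry[variety]
        proba2 = sub.predict_proba(sset.spectra[rows])
        g_idx = proba2.argmax(axis=1)
        gm_out[rows] = np.asarray(sub.class_names, dtype=object)[g_idx]
        gm_conf[rows] = proba2[np.arange(len(rows)), g_idx]
    return pd.DataFrame(
        {
            "sample_id": sset.sample_ids,
            "variety": varieties,
            "variety_conf": v_conf,
            "gm": gm_out,
            "gm_conf": gm_conf,
        }
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_classifier(
    clf: SpectrumClassifier, path: str | Path, train_cfg: TrainConfig | None = None
) -> None:
    """``.npz`` weights plus a JSON sidecar describing the model."""
    path = Path(path)
    arrays = {f"p{i}": p for i, (p, _) in enumerate(clf.net.params)}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "spec": asdict(clf.net.spec),
        "class_names": clf.class_names,
        "band_domain": clf.band_axis.domain,
        "band_values": [float(v) for v in clf.band_axis.values],
        "train_config": asdict(train_cfg) if train_cfg else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_classifier(path: str | Path) -> SpectrumClassifier:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec_d = dict(sidecar["spec"])
    spec_d["common_filters"] = tuple(spec_d["common_filters"])
    spec_d["kernel_sizes"] = tuple(spec_d["kernel_sizes"])
    spec = ModelSpec(**spec_d)
    net = CascadeNet(spec, rng_seed=0)
    with np.load(path.with_suffix(".npz")) as data:
        net.load_state([data[f"p{i}"] for i in range(len(net.params))])
    axis = BandAxis(sidecar["band_domain"], np.asarray(sidecar["band_values"]))
    return SpectrumClassifier(net, sidecar["class_names"], axis)
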