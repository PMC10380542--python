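"""Band axes and per-seed spectrum collections.

A :class:`SpectrumSet` is the currency every pipeline stage trades in: an
``(n_samples, n_bands)`` matrix of unitless reflectance or absorbance values,
a :class:`BandAxis` naming the band centers, and per-sample variety / GM-status
labels.  CSV round-tripping keeps one column per band, named by its center.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, InvalidArgumentError

#: Canonical GM-status label strings.
GM = "GM"
NON_GM = "non-GM"

_DOMAINS = {"nir": "nm", "thz": "THz"}


@dataclass(frozen=True)
class BandAxis:
    """Ordered band centers for one spectral domain.

    domain
        ``"nir"`` (wavelengths in nm) or ``"thz"`` (frequencies in THz).
    values
        Strictly increasing, finite, positive band centers.
    """

    domain: str
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "domain", str(self.domain).lower())
        if self.domain not in _DOMAINS:
            raise InvalidArgumentError(f"unknown domain {self.domain!r}; expected 'nir' or 'thz'")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise InvalidArgumentError("band axis needs at least 2 band centers")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise InvalidArgumentError("band centers must be finite and positive")
        if np.any(np.diff(vals) <= 0):
            raise InvalidArgumentError("band centers must be strictly increasing")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @property
    def units(self) -> str:
        return _DOMAINS[self.domain]

    def __len__(self) -> int:
        return int(self.values.size)

    def index_nearest(self, value: float) -> int:
        """Index of the band center closest to ``value``."""
        return int(np.argmin(np.abs(self.values - float(value))))

    def subset(self, indices: Sequence[int]) -> "BandAxis":
        return BandAxis(self.domain, self.values[np.asarray(indices, dtype=int)])

    def __eq__(self, other) -> bool:  # value equality, not identity
        return (
            isinstance(other, BandAxis)
            and self.domain == other.domain
            and self.values.shape == other.values.shape
            and bool(np.allclose(self.values, other.values))
        )


def make_band_axis(domain: str, n_bands: int, lo: float, hi: float) -> BandAxis:
    """Uniform inclusive grid of ``n_bands`` centers from ``lo`` to ``hi``."""
    if n_bands < 2:
        raise InvalidArgumentError(f"n_bands must be >= 2, got {n_bands}")
    if not lo < hi:
        raise InvalidArgumentError(f"need lo < hi, got lo={lo}, hi={hi}")
    return BandAxis(domain, np.linspace(float(lo), float(hi), int(n_bands)))


@dataclass
class SpectrumSet:
    """Matrix of per-seed spectra with labels.

    ``gm_labels`` is optional: segmentation output, for instance, has no
    GM ground truth until labels are joined from elsewhere.
    """

    spectra: np.ndarray
    band_axis: BandAxis
    variety_labels: np.ndarray
    gm_labels: np.ndarray | None = None
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        n, b = self.spectra.shape
        if b != len(self.band_axis):
            raise InvalidArgumentError(
                f"spectra have {b} bands but axis has {len(self.band_axis)}"
            )
        self.variety_labels = np.asarray(self.variety_labels, dtype=object)
        if self.variety_labels.shape != (n,):
            raise InvalidArgumentError("variety_labels length must match sample count")
        if self.gm_labels is not None:
            self.gm_labels = np.asarray(self.gm_labels, dtype=object)
            if self.gm_labels.shape != (n,):
                raise InvalidArgumentError("gm_labels length must match sample count")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i:05d}" for i in range(n)], dtype=object)
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
            if self.sample_ids.shape != (n,):
                raise InvalidArgumentError("sample_ids length must match sample count")

    # -- basic views ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    @property
    def X(self) -> np.ndarray:
        return self.spectra

    def joint_labels(self) -> np.ndarray:
        """``variety/gm`` composite labels (requires gm_labels)."""
        if self.gm_labels is None:
            raise InvalidArgumentError("joint labels need gm_labels")
        return np.array(
            [f"{v}/{g}" for v, g in zip(self.variety_labels, self.gm_labels)], dtype=object
        )

    def take(self, rows: Sequence[int] | np.ndarray) -> "SpectrumSet":
        rows = np.asarray(rows, dtype=int)
        return SpectrumSet(
            self.spectra[rows],
            self.band_axis,
            self.variety_labels[rows],
            None if self.gm_labels is None else self.gm_labels[rows],
            self.sample_ids[rows],
        )

    def select_bands(self, indices: Sequence[int]) -> "SpectrumSet":
        idx = np.asarray(indices, dtype=int)
        if idx.size == 0:
            raise EmptySelectionError("band selection is empty")
        return SpectrumSet(
            self.spectra[:, idx],
            self.band_axis.subset(idx),
            self.variety_labels,
            self.gm_labels,
            self.sample_ids,
        )

    def filter_variety(self, variety: str) -> "SpectrumSet":
        rows = np.flatnonzero(self.variety_labels == variety)
        return self.take(rows)

    # -- CSV round trip ------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cols = {
            "sample_id": self.sample_ids,
            "variety": self.variety_labels,
            "gm": self.gm_labels if self.gm_labels is not None else [""] * self.n_samples,
        }
        band_cols = {f"{v:.6g}": self.spectra[:, j] for j, v in enumerate(self.band_axis.values)}
        return pd.DataFrame({**cols, **band_cols})

    def to_csv(self, path: str | Path, domain_comment: bool = True) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if domain_comment:
                fh.write(f"# domain: {self.band_axis.domain}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, domain: str | None = None) -> "SpectrumSet":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# domain:"):
                domain = domain or first.split(":", 1)[1].strip()
            else:
                fh.seek(0)
            df = pd.read_csv(fh)
        if domain is None:
            raise InvalidArgumentError("domain not recorded in CSV; pass domain=")
        band_cols = [c for c in df.columns if c not in ("sample_id", "variety", "gm")]
        axis = BandAxis(domain, np.array([float(c) for c in band_cols]))
        gm = df["gm"].astype(object).to_numpy() if "gm" in df else None
        if gm is not None and all(not str(g).strip() or str(g) == "nan" for g in gm):
            gm = None
        return cls(
            df[band_cols].to_numpy(dtype=float),
            axis,
            df["variety"].astype(object).to_numpy(),
            gm,
            df["sample_id"].astype(object).to_numpy(),
        )


def concat_spectrum_sets(sets: Iterable[SpectrumSet]) -> SpectrumSet:
    sets = list(sets)
    if not sets:
        raise InvalidArgumentError("nothing to concatenate")
    axis = sets[0].band_axis
    for s in sets[1:]:
        if s.band_axis != axis:
            raise InvalidArgumentError("band axes differ between sets")
    gm = None
    if all(s.gm_labels is not None for s in sets):
        gm = np.concatenate([s.gm_labels for s in sets])
    return SpectrumSet(
        np.vstack([s.spectra for s in sets]),
        axis,
        np.concatenate([s.variety_labels for s in sets]),
        gm,
        np.concatenate([s.sample_ids for s in sets]),
    )
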