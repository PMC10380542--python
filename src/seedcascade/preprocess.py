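"""From raw spectral cubes to clean per-seed spectra.

The chain mirrors standard hyperspectral chemometrics practice: flat-field
calibration against dark/white references, adaptive-mean threshold
segmentation at a single reference band followed by connected-component
labeling, per-seed spatial averaging, moving-average smoothing, airPLS
baseline correction (terahertz), and trimming of noisy edge bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .cube import HyperCube
from .errors import (
    DegenerateCalibrationError,
    EmptySelectionError,
    InvalidArgumentError,
)
from .spectra import SpectrumSet


@dataclass
class PreprocessConfig:
    """Tunables of the preprocessing chain (defaults follow the NIR protocol).

    ref_band_value
        Band center (nm or THz) whose image drives segmentation; 1363 nm for
        the NIR instrument.
    adaptive_block
        Odd side length of the moving neighborhood whose mean is the local
        threshold.
    keep_interval
        Closed band-center interval retained after trimming, per domain.
    """

    ref_band_value: float = 1363.0
    adaptive_block: int = 11
    adaptive_offset: float = 0.0
    connectivity: int = 8
    min_component_px: int = 5
    ma_window: int = 5
    airpls_lambda: float = 1.0
    airpls_iters: int = 15
    keep_interval: dict = field(
        default_factory=lambda: {"nir": (958.0, 1630.0), "thz": (0.3, 2.0)}
    )

    def __post_init__(self):
        if self.adaptive_block < 3 or self.adaptive_block % 2 == 0:
            raise InvalidArgumentError("adaptive_block must be odd and >= 3")
        if self.ma_window < 1 or self.ma_window % 2 == 0:
            raise InvalidArgumentError("ma_window must be odd and >= 1")
        if self.airpls_iters < 1:
            raise InvalidArgumentError("airpls_iters must be >= 1")
        if self.connectivity not in (4, 8):
            raise InvalidArgumentError("connectivity must be 4 or 8")
        if self.min_component_px < 1:
            raise InvalidArgumentError("min_component_px must be >= 1")
        for lo, hi in self.keep_interval.values():
            if not lo < hi:
                raise InvalidArgumentError("keep_interval lo must be < hi")


@dataclass
class SeedMask:
    """Integer label image: 0 background, 1..n_seeds individual seeds."""

    labels: np.ndarray
    n_seeds: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or np.any(self.labels < 0):
            raise InvalidArgumentError("label image must be 2-D and nonnegative")
        present = np.unique(self.labels)
        present = present[present > 0]
        if present.size != self.n_seeds or (
            present.size and present.max() != self.n_seeds
        ):
            raise InvalidArgumentError("labels must be exactly 1..n_seeds")


def calibrate_reflectance(raw: HyperCube, dark: HyperCube, white: HyperCube) -> HyperCube:
    """Flat-field calibration ``(raw - dark) / (white - dark)``."""
    if raw.shape != dark.shape or raw.shape != white.shape:
        raise InvalidArgumentError("raw/dark/white cubes must share a shape")
    denom = white.values - dark.values
    bad = denom == 0
    if bad.any():
        pos = tuple(int(i) for i in np.argwhere(bad)[0])
        raise DegenerateCalibrationError(
            f"white == dark at voxel {pos}; calibration undefined there"
        )
    return HyperCube((raw.values - dark.values) / denom, raw.band_axis)


def segment_seeds(cube: HyperCube, cfg: PreprocessConfig | None = None) -> SeedMask:
    """Adaptive-mean threshold at the reference band + connected components.

    A pixel is foreground iff its reference-band intensity strictly exceeds
    the mean over the ``adaptive_block`` neighborhood plus
    ``adaptive_offset``; components smaller than ``min_component_px`` are
    dropped and survivors renumbered 1..n in scan order.
    """
    cfg = cfg or PreprocessConfig()
    lo, hi = cube.band_axis.values[0], cube.band_axis.values[-1]
    if not lo <= cfg.ref_band_value <= hi:
        raise InvalidArgumentError(
            f"reference band {cfg.ref_band_value} outside axis range [{lo}, {hi}]"
        )
    img = cube.band_image(cfg.ref_band_value)
    local_mean = ndimage.uniform_filter(img, size=cfg.adaptive_block, mode="nearest")
    # scale-relative guard so separable-filter rounding dust never flips the
    # strict comparison on flat regions
    guard = 1e-9 * max(float(np.abs(img).max()), 1.0)
    fg = img - local_mean > cfg.adaptive_offset + guard
    structure = np.ones((3, 3), bool) if cfg.connectivity == 8 else ndimage.generate_binary_structure(2, 1)
    labeled, n = ndimage.label(fg, structure=structure)
    if n == 0:
        return SeedMask(np.zeros_like(labeled), 0)
    counts = np.bincount(labeled.ravel(), minlength=n + 1)
    keep = np.flatnonzero(counts[1:] >= cfg.min_component_px) + 1
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)  # scipy labels in scan order already
    return SeedMask(remap[labeled], int(keep.size))


def extract_mean_spectra(cube: HyperCube, mask: SeedMask) -> SpectrumSet:
    """Arithmetic per-band mean over each labeled region, ordered by label."""
    if cube.shape[:2] != mask.labels.shape:
        raise InvalidArgumentError("cube and mask spatial shapes differ")
    n = mask.n_seeds
    spectra = np.empty((n, cube.shape[2]))
    for lab in range(1, n + 1):
        fp = mask.labels == lab
        spectra[lab - 1] = cube.values[fp, :].mean(axis=0)
    return SpectrumSet(
        spectra.reshape(n, cube.shape[2]),
        cube.band_axis,
        np.array(["unknown"] * n, dtype=object),
        None,
        np.array([f"seed{lab:03d}" for lab in range(1, n + 1)], dtype=object),
    )


def moving_average(sset: SpectrumSet, window: int = 5) -> SpectrumSet:
    """Centered boxcar smoothing; edges average over the truncated window."""
    if window % 2 == 0 or window < 1:
        raise InvalidArgumentError("window must be odd and >= 1")
    if window > sset.n_bands:
        raise InvalidArgumentError("window exceeds band count")
    kernel = np.ones(window)
    num = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, sset.spectra)
    den = np.convolve(np.ones(sset.n_bands), kernel, mode="same")
    return SpectrumSet(
        num / den[None, :], sset.band_axis, sset.variety_labels, sset.gm_labels, sset.sample_ids
    )


def airpls_baseline(
    spectrum: np.ndarray, lam: float = 1.0, iters: int = 15
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive iteratively reweighted penalized least-squares baseline.

    Fits the baseline ``z`` minimizing ``sum w_i (y_i - z_i)^2 +
    lam * sum (d2 z)^2`` with the weights re-estimated each round: points at
    or above the current baseline get weight 0 (peaks must not pull the
    baseline up), points below get an exponentially growing weight.  Stops
    early when the mass of negative residuals falls below 0.1% of the total
    absolute signal.  Returns ``(baseline, spectrum - baseline)``.
    """
    y = np.asarray(spectrum, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise InvalidArgumentError("airPLS needs at least 3 bands")
    if not np.all(np.isfinite(y)):
        raise InvalidArgumentError("airPLS input must be finite")
    if lam <= 0 or iters < 1:
        raise InvalidArgumentError("need lam > 0 and iters >= 1")
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    penalty = lam * (d2.T @ d2)
    w = np.ones(n)
    z = y.copy()
    total_abs = np.abs(y).sum()
    for it in range(1, iters + 1):
        lhs = sparse.csc_matrix(sparse.diags(w) + penalty)
        z = spsolve(lhs, w * y)
        d = y - z
        neg = d < 0
        dssn = float(np.abs(d[neg]).sum())
        if dssn < 0.001 * total_abs or not neg.any():
            break
        w[~neg] = 0.0
        w[neg] = np.exp(it * np.abs(d[neg]) / dssn)
        w[0] = np.exp(it * np.abs(d[neg]).max() / dssn)
        w[-1] = w[0]
    return z, y - z


def airpls_correct(sset: SpectrumSet, lam: float = 1.0, iters: int = 15) -> SpectrumSet:
    """Apply airPLS baseline removal row-wise to a SpectrumSet."""
    corrected = np.stack([airpls_baseline(r, lam, iters)[1] for r in sset.spectra])
    return SpectrumSet(
        corrected, sset.band_axis, sset.variety_labels, sset.gm_labels, sset.sample_ids
    )


def trim_bands(sset: SpectrumSet, interval: tuple[float, float] | None = None) -> SpectrumSet:
    """Keep exactly the bands whose center lies in the closed interval."""
    if interval is None:
        interval = PreprocessConfig().keep_interval[sset.band_axis.domain]
    lo, hi = interval
    if not lo < hi:
        raise InvalidArgumentError("interval lo must be < hi")
    keep = np.flatnonzero((sset.band_axis.values >= lo) & (sset.band_axis.values <= hi))
    if keep.size == 0:
        raise EmptySelectionError(f"no band centers inside [{lo}, {hi}]")
    return sset.select_bands(keep)


def preprocess_spectra(
    sset: SpectrumSet, cfg: PreprocessConfig | None = None, baseline: bool | None = None
) -> SpectrumSet:
    """Smoothing -> (terahertz-only by default) airPLS -> band trimming."""
    cfg = cfg or PreprocessConfig()
    out = moving_average(sset, cfg.ma_window)
    if baseline is None:
        baseline = sset.band_axis.domain == "thz"
    if baseline:
        out = airpls_correct(out, cfg.airpls_lambda, cfg.airpls_iters)
    return trim_bands(out, cfg.keep_interval[sset.band_axis.domain])
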