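"""Synthetic spectra and hyperspectral cubes for pipeline validation.

No public accession exists for paired GM / non-GM rice-seed spectra, so the
package bundles a generator that reproduces the statistical structure the
pipeline assumes:

* three varieties whose mean spectra differ by large, smooth shifts;
* a small, systematically *negative* GM offset confined to a known set of
  discriminative bands (non-GM reflectance/absorbance sits above GM);
* terahertz templates with absorption peaks near 0.3, 0.6, 1.0 and 1.25 THz
  riding on a smooth baseline drift;
* i.i.d. Gaussian per-band noise.

Because the discriminative bands are planted, segmentation, classification
and wavelength selection can all be scored against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import InvalidArgumentError, PlacementError
from .spectra import GM, NON_GM, BandAxis, SpectrumSet, make_band_axis

DEFAULT_VARIETIES = ("zheyou5", "chuan398A", "chuan345A")

#: Per-(variety, status) sample counts of the default terahertz design.
DEFAULT_THZ_CLASS_SIZES: dict[tuple[str, str], int] = {
    ("zheyou5", NON_GM): 550,
    ("zheyou5", GM): 554,
    ("chuan398A", NON_GM): 588,
    ("chuan398A", GM): 543,
    ("chuan345A", NON_GM): 578,
    ("chuan345A", GM): 565,
}


def _gaussian(x: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - center) / width) ** 2)


@dataclass
class SimDesign:
    """Full description of one synthetic experiment.

    ``templates`` holds one mean spectrum per variety (rows follow
    ``varieties``).  ``gm_offset`` is added to GM samples only; with the
    default designs it is non-positive and nonzero exactly at
    ``discriminative_band_indices``.
    """

    band_axis: BandAxis
    varieties: tuple[str, ...]
    templates: np.ndarray
    gm_offset: np.ndarray
    discriminative_band_indices: np.ndarray
    noise_sd: float
    class_sizes: Mapping[tuple[str, str], int]
    rng_seed: int = 0

    def __post_init__(self):
        self.varieties = tuple(self.varieties)
        if not self.varieties:
            raise InvalidArgumentError("at least one variety is required")
        n_bands = len(self.band_axis)
        self.templates = np.asarray(self.templates, dtype=float)
        if self.templates.shape != (len(self.varieties), n_bands):
            raise InvalidArgumentError("templates must be (n_varieties, n_bands)")
        self.gm_offset = np.asarray(self.gm_offset, dtype=float)
        if self.gm_offset.shape != (n_bands,):
            raise InvalidArgumentError("gm_offset must have one value per band")
        self.discriminative_band_indices = np.unique(
            np.asarray(self.discriminative_band_indices, dtype=int)
        )
        if self.discriminative_band_indices.size and (
            self.discriminative_band_indices.min() < 0
            or self.discriminative_band_indices.max() >= n_bands
        ):
            raise InvalidArgumentError("discriminative band indices out of range")
        if any(c <= 0 for c in self.class_sizes.values()):
            raise InvalidArgumentError("all class sizes must be positive")
        for v, _ in self.class_sizes:
            if v not in self.varieties:
                raise InvalidArgumentError(f"class size references unknown variety {v!r}")
        # GM shifts must stay small relative to variety spacing, otherwise the
        # two-phase premise (variety signal dominates) is violated.
        if len(self.varieties) > 1:
            dists = [
                float(np.sqrt(np.mean((self.templates[i] - self.templates[j]) ** 2)))
                for i in range(len(self.varieties))
                for j in range(i + 1, len(self.varieties))
            ]
            if np.max(np.abs(self.gm_offset)) >= min(dists):
                raise InvalidArgumentError(
                    "max |gm_offset| must be below the smallest between-variety RMS distance"
                )

    @property
    def total_samples(self) -> int:
        return int(sum(self.class_sizes.values()))


def default_thz_design(
    class_sizes: Mapping[tuple[str, str], int] | int | None = None,
    noise_sd: float = 0.01,
    rng_seed: int = 0,
) -> SimDesign:
    """Terahertz absorbance design: 93 bands over 0.3-2.0 THz.

    Templates carry absorption peaks near 0.3, 0.6, 1.0 and 1.25 THz on a
    gently rising baseline; chuan345A absorbs most strongly around 0.6 THz.
    Pass an integer ``class_sizes`` to run the same design at a uniform
    per-cell count (scaled validation experiments).
    """
    axis = make_band_axis("thz", 93, 0.3, 2.0)
    f = axis.values
    baseline = 0.25 + 0.10 * (f - 0.3) / 1.7
    peaks = {
        # variety: amplitudes for peaks at (0.3, 0.6, 1.0, 1.25) THz
        "zheyou5": (0.30, 0.22, 0.16, 0.12),
        "chuan398A": (0.26, 0.25, 0.13, 0.15),
        "chuan345A": (0.24, 0.34, 0.19, 0.10),
    }
    widths = (0.06, 0.09, 0.08, 0.07)
    centers = (0.3, 0.6, 1.0, 1.25)
    shifts = {"zheyou5": 0.00, "chuan398A": 0.045, "chuan345A": -0.035}
    templates = np.stack(
        [
            baseline
            + shifts[v]
            + sum(_gaussian(f, c, w, a) for c, w, a in zip(centers, widths, peaks[v]))
            for v in DEFAULT_VARIETIES
        ]
    )
    # GM effect: slightly weaker absorbance/reflectance than the parent line,
    # confined to bands around the 1.0 and 1.25 THz features.
    disc = np.array([36, 37, 38, 39, 50, 51, 52, 53], dtype=int)
    gm_offset = np.zeros(93)
    gm_offset[disc] = -0.025
    if class_sizes is None:
        sizes: Mapping[tuple[str, str], int] = dict(DEFAULT_THZ_CLASS_SIZES)
    elif isinstance(class_sizes, int):
        sizes = {(v, s): class_sizes for v in DEFAULT_VARIETIES for s in (NON_GM, GM)}
    else:
        sizes = dict(class_sizes)
    return SimDesign(axis, DEFAULT_VARIETIES, templates, gm_offset, disc, noise_sd, sizes, rng_seed)


def default_nir_design(
    class_sizes: Mapping[tuple[str, str], int] | int | None = None,
    noise_sd: float = 0.01,
    rng_seed: int = 0,
) -> SimDesign:
    """NIR reflectance design: 256 bands over 874-1734 nm, ~800 seeds/cell."""
    axis = make_band_axis("nir", 256, 874.0, 1734.0)
    wl = axis.values
    base = 0.55 + 0.08 * np.sin((wl - 874.0) / 860.0 * np.pi)
    # broad absorption dips typical of NIR seed reflectance (water/starch overtones)
    dips = _gaussian(wl, 1200.0, 60.0, 0.10) + _gaussian(wl, 1450.0, 55.0, 0.16)
    shifts = {"zheyou5": 0.00, "chuan398A": 0.05, "chuan345A": -0.04}
    scale = {"zheyou5": 1.0, "chuan398A": 0.92, "chuan345A": 1.08}
    templates = np.stack(
        [(base - scale[v] * dips) + shifts[v] for v in DEFAULT_VARIETIES]
    )
    disc = np.array([60, 61, 62, 100, 101, 102, 160, 161, 162, 200], dtype=int)
    gm_offset = np.zeros(256)
    gm_offset[disc] = -0.02
    if class_sizes is None:
        sizes: Mapping[tuple[str, str], int] = {
            (v, s): 800 for v in DEFAULT_VARIETIES for s in (NON_GM, GM)
        }
    elif isinstance(class_sizes, int):
        sizes = {(v, s): class_sizes for v in DEFAULT_VARIETIES for s in (NON_GM, GM)}
    else:
        sizes = dict(class_sizes)
    return SimDesign(axis, DEFAULT_VARIETIES, templates, gm_offset, disc, noise_sd, sizes, rng_seed)


def simulate_spectrum_set(design: SimDesign) -> SpectrumSet:
    """Draw a labeled SpectrumSet from a design; bit-deterministic per seed."""
    rng = np.random.default_rng(design.rng_seed)
    rows, varieties, statuses, ids = [], [], [], []
    for vi, v in enumerate(design.varieties):
        for status in (NON_GM, GM):
            n = int(design.class_sizes.get((v, status), 0))
            if n == 0:
                continue
            mean = design.templates[vi] + (design.gm_offset if status == GM else 0.0)
            noise = (
                rng.normal(0.0, design.noise_sd, size=(n, len(design.band_axis)))
                if design.noise_sd > 0
                else np.zeros((n, len(design.band_axis)))
            )
            rows.append(mean[None, :] + noise)
            varieties.extend([v] * n)
            statuses.extend([status] * n)
            ids.extend(f"{v}-{status}-{i:04d}" for i in range(n))
    if not rows:
        raise InvalidArgumentError("design produced no samples")
    return SpectrumSet(
        np.vstack(rows),
        design.band_axis,
        np.array(varieties, dtype=object),
        np.array(statuses, dtype=object),
        np.array(ids, dtype=object),
    )


# ---------------------------------------------------------------------------
# hyperspectral cube synthesis
# ---------------------------------------------------------------------------

def _ellipse_footprint(rows, cols, cy, cx, ry, rx):
    yy, xx = np.ogrid[:rows, :cols]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def simulate_hypercube(
    n_seeds: int,
    cube_shape: tuple[int, int],
    seed_spectra: SpectrumSet,
    rng_seed: int = 0,
    noise_sd: float = 0.0,
    background_level: float = 0.0,
    radius_range: tuple[float, float] = (3.0, 5.0),
    max_tries: int = 200,
):
    """Paint ``n_seeds`` elliptical seeds into a cube over a dark background.

    Each footprint is filled with one spectrum drawn (cyclically) from
    ``seed_spectra`` plus optional per-voxel noise.  Returns the cube together
    with the exact integer label image (0 = background, 1..n_seeds) so that
    segmentation can be scored pixel-by-pixel.

    Footprints are kept pairwise disjoint with a one-pixel gap; if a seed
    cannot be placed after ``max_tries`` attempts a PlacementError is raised.
    """
    from .cube import HyperCube  # local import to avoid a cycle

    rows, cols = map(int, cube_shape)
    if n_seeds < 0:
        raise InvalidArgumentError("n_seeds must be nonnegative")
    if n_seeds > 0 and seed_spectra.n_samples == 0:
        raise InvalidArgumentError("seed_spectra is empty")
    rng = np.random.default_rng(rng_seed)
    n_bands = len(seed_spectra.band_axis)
    labels = np.zeros((rows, cols), dtype=np.int32)
    occupied = np.zeros((rows, cols), dtype=bool)  # footprints dilated by 1 px
    assignments = []
    for s in range(n_seeds):
        for attempt in range(max_tries):
            ry = rng.uniform(*radius_range)
            rx = rng.uniform(radius_range[0] * 0.7, radius_range[1] * 0.9)
            cy = rng.uniform(ry + 1, rows - ry - 2)
            cx = rng.uniform(rx + 1, cols - rx - 2)
            fp = _ellipse_footprint(rows, cols, cy, cx, ry, rx)
            halo = _ellipse_footprint(rows, cols, cy, cx, ry + 1.5, rx + 1.5)
            if fp.any() and not (halo & occupied).any():
                labels[fp] = s + 1
                occupied |= halo
                assignments.append(s % seed_spectra.n_samples)
                break
        else:
            raise PlacementError(
                f"could not place seed {s + 1}/{n_seeds} after {max_tries} tries"
            )
    values = np.full((rows, cols, n_bands), float(background_level))
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=values.shape)
    for s, row_idx in enumerate(assignments):
        fp = labels == s + 1
        values[fp, :] = seed_spectra.spectra[row_idx][None, :]
        if noise_sd > 0:
            values[fp, :] += rng.normal(0.0, noise_sd, size=(int(fp.sum()), n_bands))
    return HyperCube(values, seed_spectra.band_axis), labels
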