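"""Hyperspectral cubes and minimal ENVI band-sequential I/O.

The on-disk layout is the classic ENVI pair: a small text header
(``samples``, ``lines``, ``bands``, ``interleave = bsq``, wavelength list)
next to a raw little-endian float32 array stored band-sequentially.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError
from .spectra import BandAxis


@dataclass
class HyperCube:
    """rows x cols x bands array of intensities with its band axis."""

    values: np.ndarray
    band_axis: BandAxis

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InvalidArgumentError("cube must be rows x cols x bands")
        if self.values.shape[2] != len(self.band_axis):
            raise InvalidArgumentError(
                f"cube has {self.values.shape[2]} bands but axis has {len(self.band_axis)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def band_image(self, value: float) -> np.ndarray:
        """2-D image at the band nearest to ``value`` (nm or THz)."""
        return self.values[:, :, self.band_axis.index_nearest(value)]


def write_envi(cube: HyperCube, path: str | Path) -> tuple[Path, Path]:
    """Write ``path``.raw + ``path``.hdr (BSQ, float32, little endian)."""
    path = Path(path)
    raw = path.with_suffix(".raw")
    hdr = path.with_suffix(".hdr")
    rows, cols, bands = cube.shape
    bsq = np.ascontiguousarray(np.moveaxis(cube.values, 2, 0), dtype="<f4")
    bsq.tofile(raw)
    wavelengths = ", ".join(f"{v:.6f}" for v in cube.band_axis.values)
    hdr.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"domain = {cube.band_axis.domain}\n"
        f"wavelength = {{ {wavelengths} }}\n"
    )
    return raw, hdr


def _parse_header(hdr: Path) -> dict:
    text = hdr.read_text()
    if not text.lstrip().startswith("ENVI"):
        raise InvalidArgumentError(f"{hdr} is not an ENVI header")
    # collapse brace-delimited multi-line values before splitting into fields
    fields: dict[str, str] = {}
    buf = ""
    for line in text.splitlines()[1:]:
        buf += line
        if buf.count("{") > buf.count("}"):
            buf += " "
            continue
        if "=" in buf:
            key, val = buf.split("=", 1)
            fields[key.strip().lower()] = val.strip()
        buf = ""
    return fields


def read_envi(path: str | Path) -> HyperCube:
    """Read a BSQ float cube written by :func:`write_envi` (or compatible)."""
    path = Path(path)
    hdr = path.with_suffix(".hdr")
    raw = path.with_suffix(".raw")
    if not raw.exists():
        raw = path.with_suffix(".img")
    fields = _parse_header(hdr)
    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise InvalidArgumentError("only band-sequential (bsq) cubes are supported")
    dtype = {"4": "<f4", "5": "<f8"}.get(fields.get("data type", "4"))
    if dtype is None:
        raise InvalidArgumentError(f"unsupported ENVI data type {fields.get('data type')}")
    data = np.fromfile(raw, dtype=dtype, count=rows * cols * bands)
    if data.size != rows * cols * bands:
        raise InvalidArgumentError(f"{raw} truncated: expected {rows * cols * bands} values")
    values = np.moveaxis(data.reshape(bands, rows, cols), 0, 2).astype(float)
    wl_text = fields.get("wavelength", "").strip("{} ")
    if wl_text:
        wavelengths = np.array([float(t) for t in wl_text.split(",") if t.strip()])
    else:
        wavelengths = np.arange(1.0, bands + 1.0)
    domain = fields.get("domain", "nir" if wavelengths.max() > 50 else "thz")
    return HyperCube(values, BandAxis(domain, wavelengths))
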