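"""Minimal planar raster I/O: TIFF pixels + sidecar georeferencing.

A raster is a ``(bands, height, width)`` integer array together with a
six-coefficient affine transform mapping pixel (col, row) to map (x, y)
and a coordinate-system tag. Pixels are written as plain TIFF via
:mod:`tifffile`; the transform and CRS travel in a small JSON sidecar
(``<name>.aux.json``) next to the TIFF, which keeps the on-disk format
text-auditable and dependency-light.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Affine", "RasterData", "write_raster", "read_raster"]


@dataclass(frozen=True)
class Affine:
    """Affine map from pixel (col, row) to map (x, y).

    ``x = a*col + b*row + c`` and ``y = d*col + e*row + f``; the common
    north-up raster has ``b = d = 0``, ``a = pixel size``, ``e = -pixel
    size``, and (c, f) at the outer corner of pixel (0, 0).
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def xy(self, col, row):
        """Map pixel coordinates (array-friendly) to map coordinates."""
        return (
            self.a * np.asarray(col) + self.b * np.asarray(row) + self.c,
            self.d * np.asarray(col) + self.e * np.asarray(row) + self.f,
        )

    def pixel_center(self, col, row):
        """Map coordinate of the center of pixel (col, row)."""
        return self.xy(np.asarray(col) + 0.5, np.asarray(row) + 0.5)

    def translate(self, col_off: int, row_off: int) -> "Affine":
        """Affine of a sub-window whose pixel (0, 0) is image pixel (col_off, row_off)."""
        x0, y0 = self.xy(col_off, row_off)
        return Affine(self.a, self.b, float(x0), self.d, self.e, float(y0))

    def to_list(self) -> list[float]:
        return [self.a, self.b, self.c, self.d, self.e, self.f]

    @classmethod
    def from_list(cls, coeffs) -> "Affine":
        return cls(*map(float, coeffs))

    @classmethod
    def north_up(cls, x_min: float, y_max: float, pixel_size: float) -> "Affine":
        if pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        return cls(pixel_size, 0.0, x_min, 0.0, -pixel_size, y_max)


@dataclass
class RasterData:
    """In-memory georeferenced raster: (bands, height, width) array + affine + CRS tag."""

    pixels: np.ndarray
    transform: Affine
    crs: str
    image_id: str = ""

    @property
    def n_bands(self) -> int:
        return self.pixels.shape[0]

    @property
    def height(self) -> int:
        return self.pixels.shape[1]

    @property
    def width(self) -> int:
        return self.pixels.shape[2]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".aux.json")


def write_raster(path, raster: RasterData) -> None:
    path = Path(path)
    tifffile.imwrite(path, raster.pixels, photometric="minisblack", tile=(256, 256))
    meta = {
        "transform": raster.transform.to_list(),
        "crs": raster.crs,
        "image_id": raster.image_id,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_raster(path) -> RasterData:
    path = Path(path)
    pixels = tifffile.imread(path)
    if pixels.ndim == 2:
        pixels = pixels[None, :, :]
    meta = json.loads(_sidecar(path).read_text())
    return RasterData(
        pixels=np.asarray(pixels),
        transform=Affine.from_list(meta["transform"]),
        crs=meta["crs"],
        image_id=meta.get("image_id", ""),
    )
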