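"""Raster product selection, normalization and fixed-size chipping.

A large satellite scene (e.g. a 10,980 x 10,980-pixel, 10 m tile) is cut
into square georeferenced chips — 224 x 224 pixels (2.24 km on a side)
by default — after normalizing raw integer reflectance into [0, 1].
Products with identical footprints (repeat passes over the same tile)
are deduplicated by keeping the largest-area, least-cloudy one; a
configurable exclusion list handles products removed by inspection.

Edge policy: a ragged final row/column of the chip grid is clamped —
the last window is shifted inward so it ends exactly at the image edge.
Every window is full-size and in bounds; a 10,980-pixel side with
224-pixel chips yields ceil(10980/224) = 50 windows per axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as _date
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .raster_io import Affine, RasterData

__all__ = [
    "ProductMeta",
    "ChipWindow",
    "Chip",
    "DEFAULT_CHIP_SIZE",
    "DEFAULT_DIVISOR",
    "select_products",
    "normalize_image",
    "plan_chip_grid",
    "chip_transform",
    "cut_chips",
]

DEFAULT_CHIP_SIZE = 224
DEFAULT_DIVISOR = 10000  # L2A surface-reflectance scaling convention


@dataclass(frozen=True)
class ProductMeta:
    """Metadata of one raster product: footprint, cloud cover, date."""

    product_id: str
    footprint: BaseGeometry
    cloud_pct: float
    date: Optional[_date] = None

    def __post_init__(self):
        if not (0.0 <= self.cloud_pct <= 100.0):
            raise ValueError("cloud_pct must lie in [0, 100]")
        if self.footprint.area <= 0:
            raise ValueError("footprint must have positive area")

    @property
    def area(self) -> float:
        return self.footprint.area


@dataclass(frozen=True)
class ChipWindow:
    """A fixed-size pixel window of a parent image, with georeferencing.

    ``pixel_window`` is (col_off, row_off, width, height), 0-based and
    half-open; ``transform`` maps chip pixel (col, row) to map (x, y).
    """

    image_id: str
    row_index: int
    col_index: int
    pixel_window: tuple[int, int, int, int]
    transform: Affine
    crs: str

    @property
    def chip_id(self) -> str:
        return f"{self.image_id}:{self.row_index}:{self.col_index}"

    @property
    def width(self) -> int:
        return self.pixel_window[2]

    @property
    def height(self) -> int:
        return self.pixel_window[3]

    def footprint(self) -> BaseGeometry:
        """Map-coordinate rectangle covered by this window."""
        w, h = self.width, self.height
        xs, ys = self.transform.xy(np.array([0, w, w, 0]), np.array([0, 0, h, h]))
        return shapely.polygons(np.column_stack([xs, ys]))


@dataclass
class Chip:
    """A chip window together with its normalized 3-band pixel array in [0, 1]."""

    window: ChipWindow
    pixels: np.ndarray  # (3, chip, chip) floats in [0, 1]


def select_products(
    products: Sequence[ProductMeta], exclusions: Iterable[str] = ()
) -> list[ProductMeta]:
    """Deduplicate identical footprints and apply the exclusion list.

    Among products sharing a footprint, the one maximizing (area, then
    lowest cloud percentage) is kept; then any product whose id appears
    in ``exclusions`` is dropped.
    """
    ids = [p.product_id for p in products]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate product ids: {dupes}")
    groups: dict[bytes, list[ProductMeta]] = {}
    for p in products:
        key = shapely.to_wkb(shapely.normalize(p.footprint))
        groups.setdefault(key, []).append(p)
    excluded = set(exclusions)
    kept = []
    for group in groups.values():
        best = max(group, key=lambda p: (p.area, -p.cloud_pct))
        if best.product_id not in excluded:
            kept.append(best)
    kept.sort(key=lambda p: p.product_id)
    return kept


def normalize_image(
    raw: np.ndarray, divisor: float = DEFAULT_DIVISOR, clip: bool = True
) -> np.ndarray:
    """Scale raw integer pixel values into [0, 1] by a fixed divisor."""
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    raw = np.asarray(raw)
    if np.any(raw < 0):
        raise ValueError("negative raw pixel values are not valid reflectance counts")
    out = raw.astype(np.float64) / divisor
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return out


def plan_chip_grid(
    width: int,
    height: int,
    chip_size: int = DEFAULT_CHIP_SIZE,
    image_transform: Affine = Affine(1, 0, 0, 0, -1, 0),
    image_id: str = "",
    crs: str = "",
) -> list[ChipWindow]:
    """Cover a width x height image with full-size chip windows.

    The grid has ceil(width/chip_size) columns and ceil(height/chip_size)
    rows; interior windows abut without overlap, and the last row/column
    is clamped inward so every window is full-size and inside bounds.
    """
    if chip_size <= 0:
        raise ValueError("chip_size must be positive")
    if width < chip_size or height < chip_size:
        raise ValueError(
            f"image of {width}x{height} px is smaller than the chip size {chip_size}"
        )
    n_cols = math.ceil(width / chip_size)
    n_rows = math.ceil(height / chip_size)
    windows = []
    for r in range(n_rows):
        row_off = min(r * chip_size, height - chip_size)
        for c in range(n_cols):
            col_off = min(c * chip_size, width - chip_size)
            windows.append(
                ChipWindow(
                    image_id=image_id,
                    row_index=r,
                    col_index=c,
                    pixel_window=(col_off, row_off, chip_size, chip_size),
                    transform=chip_transform((col_off, row_off), image_transform),
                    crs=crs,
                )
            )
    return windows


def chip_transform(offsets: tuple[int, int], image_transform: Affine) -> Affine:
    """Affine of a chip whose pixel (0,0) is image pixel (col_off, row_off)."""
    col_off, row_off = offsets
    if image_transform.a <= 0 or image_transform.e == 0:
        raise ValueError("image transform must have a positive pixel size")
    return image_transform.translate(col_off, row_off)


def cut_chips(
    raster: RasterData,
    windows: Sequence[ChipWindow],
    divisor: float = DEFAULT_DIVISOR,
    clip: bool = True,
) -> Iterator[Chip]:
    """Yield normalized chips for each window, in the given (row-major) order.

    Streaming contract: one chip's pixels are materialized at a time.
    """
    _, H, W = raster.pixels.shape
    for win in windows:
        col_off, row_off, w, h = win.pixel_window
        if col_off < 0 or row_off < 0 or col_off + w > W or row_off + h > H:
            raise ValueError(f"window {win.pixel_window} lies outside the {W}x{H} image")
        block = raster.pixels[:, row_off : row_off + h, col_off : col_off + w]
        yield Chip(window=win, pixels=normalize_image(block, divisor=divisor, clip=clip))
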