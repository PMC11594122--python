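"""Chip-tract intersection weights and pixel-weighted aggregation.

Imagery chips and census tracts are incompatible spatial partitions;
attributes move between them by areal interpolation with pixel counts
as weights. For a tract t intersected by chips C, the tract feature
vector is the weighted mean

    F_t = sum_{c in C} w_c F_c / sum_{c in C} w_c,

where w_c is the number of chip-c pixels whose centers fall inside t;
symmetrically, a chip c spanning tracts T gets the outcome rate

    o_c = sum_{t in T} w_t o_t / sum_{t in T} w_t.

Pixel membership is the standard rasterization rule: a pixel belongs to
the tract covering its center point; centers on a shared boundary go to
the tract with the lexicographically smallest id, which makes counts
deterministic and, when tracts partition a chip footprint, makes the
counts sum exactly to chip_size^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import shapely

from .chipping import ChipWindow
from .features import FeatureVector
from .raster_io import Affine
from .reconcile import JoinedTract

logger = logging.getLogger(__name__)

__all__ = [
    "IntersectionWeight",
    "TractFeature",
    "ChipOutcome",
    "label_pixels",
    "pixel_weights",
    "filter_usable_chips",
    "tract_feature",
    "chip_outcome",
    "aggregate_tract_features",
    "chip_outcomes",
    "build_design_matrix",
]


@dataclass(frozen=True)
class IntersectionWeight:
    """(chip, tract, pixel count) triple; the areal-interpolation weight."""

    chip_id: str
    tract_id: str
    pixel_count: int

    def __post_init__(self):
        if self.pixel_count < 0:
            raise ValueError("pixel_count must be non-negative")


@dataclass
class TractFeature:
    tract_id: str
    values: np.ndarray
    total_weight: int
    n_chips: int


@dataclass
class ChipOutcome:
    chip_id: str
    rate: float
    n_tracts: int


def label_pixels(
    transform: Affine,
    width: int,
    height: int,
    tracts: Sequence[tuple[str, shapely.Geometry]],
) -> np.ndarray:
    """Assign every pixel center of a grid to a tract.

    Returns an (height, width) integer array holding the index of the
    covering tract in **id-sorted order**, or -1 where no tract covers
    the center. Tracts are scanned in ascending id order and only
    unassigned pixels are tested, which implements the smallest-id
    tie-break for centers on shared boundaries.
    """
    if transform.b != 0 or transform.d != 0:
        raise ValueError("only axis-aligned transforms are supported")
    order = sorted(range(len(tracts)), key=lambda i: tracts[i][0])
    xs = transform.a * (np.arange(width) + 0.5) + transform.c
    ys = transform.e * (np.arange(height) + 0.5) + transform.f  # descending when e<0
    labels = np.full((height, width), -1, dtype=np.int32)
    for i in order:
        _, geom = tracts[i]
        if geom is None or geom.is_empty:
            continue
        minx, miny, maxx, maxy = geom.bounds
        cols = np.flatnonzero((xs >= minx) & (xs <= maxx))
        rows = np.flatnonzero((ys >= miny) & (ys <= maxy))
        if cols.size == 0 or rows.size == 0:
            continue
        sub = labels[np.ix_(rows, cols)]
        open_mask = sub == -1
        if not open_mask.any():
            continue
        rr, cc = np.nonzero(open_mask)
        pts = shapely.points(xs[cols[cc]], ys[rows[rr]])
        shapely.prepare(geom)
        covered = shapely.covers(geom, pts)
        sub[rr[covered], cc[covered]] = i
        labels[np.ix_(rows, cols)] = sub
    # map raw indices to id-sorted ranks
    rank_of = np.full(len(tracts) + 1, -1, dtype=np.int32)
    for rank, i in enumerate(order):
        rank_of[i] = rank
    out = labels.copy()
    mask = labels >= 0
    out[mask] = rank_of[labels[mask]]
    return out


def pixel_weights(
    window: ChipWindow,
    tracts: Sequence[JoinedTract],
    tracts_crs: Optional[str] = None,
) -> list[IntersectionWeight]:
    """Count, per tract, the chip pixels whose centers the tract covers.

    Zero-count pairs are omitted. The tract layer must already be in the
    chip's coordinate system.
    """
    if tracts_crs is not None and window.crs and tracts_crs != window.crs:
        raise ValueError(
            f"coordinate-system mismatch: chip is in {window.crs!r}, "
            f"tracts in {tracts_crs!r}"
        )
    pairs = [(t.base_id, t.geometry) for t in tracts]
    labels = label_pixels(window.transform, window.width, window.height, pairs)
    sorted_ids = sorted(t.base_id for t in tracts)
    counts = np.bincount(labels[labels >= 0].ravel(), minlength=len(sorted_ids))
    return [
        IntersectionWeight(chip_id=window.chip_id, tract_id=sorted_ids[i], pixel_count=int(n))
        for i, n in enumerate(counts)
        if n > 0
    ]


def window_weights_from_labels(
    window: ChipWindow, labels: np.ndarray, sorted_ids: Sequence[str]
) -> list[IntersectionWeight]:
    """Pixel weights of one chip window sliced from a whole-image label grid.

    ``labels`` is the parent image's :func:`label_pixels` result (indices
    into ``sorted_ids``). Equivalent to :func:`pixel_weights` on the
    window — the label grid already encodes the center-in-polygon rule
    and the smallest-id tie-break — but costs one slice and a bincount.
    """
    col_off, row_off, w, h = window.pixel_window
    block = labels[row_off : row_off + h, col_off : col_off + w]
    counts = np.bincount(block[block >= 0].ravel(), minlength=len(sorted_ids))
    return [
        IntersectionWeight(
            chip_id=window.chip_id, tract_id=sorted_ids[i], pixel_count=int(counts[i])
        )
        for i in np.flatnonzero(counts)
    ]


def filter_usable_chips(
    windows: Sequence[ChipWindow],
    state_boundary: shapely.Geometry,
    weights: Sequence[IntersectionWeight],
) -> list[ChipWindow]:
    """Keep chips fully inside the state boundary that intersect >= 1 tract."""
    chips_with_tracts = {w.chip_id for w in weights}
    shapely.prepare(state_boundary)
    kept = []
    for win in windows:
        if win.chip_id not in chips_with_tracts:
            continue
        if shapely.covers(state_boundary, win.footprint()):
            kept.append(win)
    return kept


def tract_feature(
    features: Mapping[str, np.ndarray], weights: Sequence[IntersectionWeight]
) -> TractFeature:
    """Pixel-weighted mean feature vector of one tract.

    ``weights`` must all refer to the same tract; ``features`` maps
    chip_id to that chip's feature vector.
    """
    tract_ids = {w.tract_id for w in weights}
    if len(tract_ids) != 1:
        raise ValueError(f"weights must refer to exactly one tract, got {tract_ids}")
    missing = [w.chip_id for w in weights if w.chip_id not in features]
    if missing:
        raise ValueError(f"missing feature vectors for chips {missing}")
    total = sum(w.pixel_count for w in weights)
    if total <= 0:
        raise ValueError("zero total pixel weight; tract mean undefined")
    acc = sum(
        (w.pixel_count * np.asarray(features[w.chip_id], dtype=float) for w in weights),
        start=0.0,
    )
    return TractFeature(
        tract_id=tract_ids.pop(),
        values=acc / total,
        total_weight=int(total),
        n_chips=len(weights),
    )


def chip_outcome(
    rates: Mapping[str, float], weights: Sequence[IntersectionWeight]
) -> ChipOutcome:
    """Pixel-weighted mean outcome rate of one chip across the tracts it spans."""
    chip_ids = {w.chip_id for w in weights}
    if len(chip_ids) != 1:
        raise ValueError(f"weights must refer to exactly one chip, got {chip_ids}")
    missing = [w.tract_id for w in weights if rates.get(w.tract_id) is None]
    if missing:
        raise ValueError(f"missing outcome rates for tracts {missing}")
    total = sum(w.pixel_count for w in weights)
    if total <= 0:
        raise ValueError("zero total pixel weight; chip rate undefined")
    value = sum(w.pixel_count * rates[w.tract_id] for w in weights) / total
    return ChipOutcome(chip_id=chip_ids.pop(), rate=float(value), n_tracts=len(weights))


def aggregate_tract_features(
    feature_vectors: Sequence[FeatureVector], weights: Sequence[IntersectionWeight]
) -> dict[str, TractFeature]:
    """Aggregate chip features into per-tract weighted means (all tracts)."""
    extractor_ids = {f.extractor_id for f in feature_vectors}
    if len(extractor_ids) > 1:
        raise ValueError(f"mixing extractors in one design matrix: {extractor_ids}")
    lookup = {f.chip_id: f.values for f in feature_vectors}
    by_tract: dict[str, list[IntersectionWeight]] = {}
    for w in weights:
        if w.chip_id in lookup:  # chips dropped upstream carry no features
            by_tract.setdefault(w.tract_id, []).append(w)
    return {tid: tract_feature(lookup, ws) for tid, ws in sorted(by_tract.items())}


def chip_outcomes(
    rates: Mapping[str, float], weights: Sequence[IntersectionWeight]
) -> dict[str, ChipOutcome]:
    """Per-chip weighted outcome rates (all chips with any weight)."""
    by_chip: dict[str, list[IntersectionWeight]] = {}
    for w in weights:
        by_chip.setdefault(w.chip_id, []).append(w)
    return {cid: chip_outcome(rates, ws) for cid, ws in sorted(by_chip.items())}


def build_design_matrix(
    tract_features: Mapping[str, TractFeature],
    outcomes: Mapping[str, Optional[float]],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Assemble (X, y, ids), rows ordered by tract id.

    Tracts lacking either a feature vector or an outcome rate are
    excluded and logged.
    """
    ids = sorted(set(tract_features) & {t for t, r in outcomes.items() if r is not None})
    dropped = sorted(
        (set(tract_features) | set(outcomes)) - set(ids)
    )
    if dropped:
        logger.info("design matrix excludes %d tracts: %s", len(dropped), dropped[:20])
    if not ids:
        raise ValueError("no tract has both features and an outcome rate")
    X = np.vstack([tract_features[t].values for t in ids])
    y = np.array([outcomes[t] for t in ids], dtype=float)
    return X, y, ids
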