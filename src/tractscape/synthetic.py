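"""Synthetic regions, rasters and outcomes with known statistical structure.

Every downstream stage of the pipeline (chipping, feature extraction,
pixel-weighted aggregation, cross-validated regression) is testable
offline against data whose ground truth is known by construction:

* a rectangular "state" is partitioned into census-tract-like polygons
  (Voronoi cells of seeded uniform random points, clipped to the extent);
* K latent environmental fields are smooth seeded surfaces (Gaussian-
  blurred white noise, standardized to mean 0 / variance 1);
* a 3-band raster is an affine mixture of the latent fields plus pixel
  noise, rescaled to the raw integer range a reflectance normalizer
  expects;
* each tract's outcome rate (a prevalence, in percent) is linear in the
  tract means of the latent fields plus Gaussian noise, so the
  explainable variance share — the R^2 an ideal regressor could reach —
  is known and recorded.

Everything is a pure function of the configuration: identical configs
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .raster_io import Affine, RasterData
from .reconcile import TractRecord

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_region",
    "generate_latent_fields",
    "render_rasters",
    "generate_outcomes",
    "tract_field_means",
    "subdivision_fixture",
    "reconciliation_fixture",
]

SYNTHETIC_CRS = "PLANAR:1m"  # one map unit = 1 m; no geodesy anywhere


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic region.

    Defaults describe a desk-scale region that mimics the structure of a
    statewide tract analysis: ~250 tracts of widely varying size, 10 m
    pixels, outcome rates centered near 39% with a latent smooth spatial
    signal explaining ~60% of the outcome variance. ``target_r2`` (when
    ``noise_sd`` is None) calibrates the outcome noise so that the
    explainable variance share hits the requested value for each
    realization.
    """

    seed: int = 0
    n_tracts: int = 250
    extent: tuple[float, float, float, float] = (0.0, 0.0, 12320.0, 12320.0)
    pixel_size: float = 10.0
    n_latent: int = 6
    field_length_scale: float = 2000.0
    beta: tuple[float, ...] = (3.0, -2.0, 1.5, -1.0, 1.0, 0.5)
    noise_sd: Optional[float] = None
    target_r2: Optional[float] = 0.6
    outcome_base: float = 39.2
    population_range: tuple[int, int] = (500, 8000)
    pixel_noise_sd: float = 0.1
    raw_scale: int = 10000

    def __post_init__(self):
        if self.n_tracts < 2:
            raise ValueError("n_tracts must be >= 2")
        if self.n_latent < 1:
            raise ValueError("n_latent must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_sd is None and self.target_r2 is None:
            raise ValueError("either noise_sd or target_r2 must be set")
        if self.target_r2 is not None and not (0.0 < self.target_r2 <= 1.0):
            raise ValueError("target_r2 must lie in (0, 1]")
        if len(self.beta) != self.n_latent:
            raise ValueError(f"beta must have n_latent={self.n_latent} coefficients")
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("extent must have positive width and height")

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(height, width) of the pixel grid covering the extent."""
        xmin, ymin, xmax, ymax = self.extent
        return (
            int(round((ymax - ymin) / self.pixel_size)),
            int(round((xmax - xmin) / self.pixel_size)),
        )

    @property
    def transform(self) -> Affine:
        xmin, _, _, ymax = self.extent
        return Affine.north_up(xmin, ymax, self.pixel_size)


@dataclass
class SyntheticTruth:
    """Ground truth of one realization: latent tract means and variance split."""

    latent_means: np.ndarray  # (n_tracts, K)
    signal_variance: float
    noise_variance: float
    true_r2: float
    noise_sd: float

    def __post_init__(self):
        if not (0.0 <= self.true_r2 <= 1.0):
            raise ValueError("true_r2 must lie in [0, 1]")


def _stream_rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


# stage tags keep the generator streams independent of each other
_TAG_POINTS, _TAG_POP, _TAG_FIELD, _TAG_MIX, _TAG_EPS = 11, 13, 17, 19, 23


def generate_region(config: SyntheticConfig):
    """Partition the extent into tract polygons (Voronoi cells of seeded points).

    Returns ``(boundary, tracts)`` where ``boundary`` is the extent
    rectangle and ``tracts`` is a list of :class:`TractRecord` whose
    polygons tile the boundary exactly. Identifiers follow the decimal
    tract-name convention ("0001.00", ...); populations are drawn
    uniformly from ``population_range``.
    """
    xmin, ymin, xmax, ymax = config.extent
    height, width = config.grid_shape
    if config.n_tracts > height * width:
        raise ValueError(
            f"extent of {height}x{width} pixels cannot host {config.n_tracts} tracts "
            "at >= 1 pixel per tract"
        )
    boundary = box(xmin, ymin, xmax, ymax)
    rng = _stream_rng(config.seed, _TAG_POINTS)
    xs = rng.uniform(xmin, xmax, config.n_tracts)
    ys = rng.uniform(ymin, ymax, config.n_tracts)
    seeds = shapely.points(xs, ys)
    cells = shapely.get_parts(
        shapely.voronoi_polygons(shapely.multipoints(seeds), extend_to=boundary)
    )
    cells = [shapely.intersection(c, boundary) for c in cells]
    # voronoi_polygons returns cells in arbitrary order; map back to seed points
    tree = shapely.STRtree(cells)
    order = tree.query(seeds, predicate="within")
    cell_of_point = dict(zip(order[0], order[1]))
    if len(cell_of_point) != config.n_tracts:  # point on a cell edge (measure zero)
        cell_of_point = {
            i: int(np.argmin([shapely.distance(p, c) for c in cells]))
            for i, p in enumerate(seeds)
        }
    pop_rng = _stream_rng(config.seed, _TAG_POP)
    lo, hi = config.population_range
    pops = pop_rng.integers(lo, hi + 1, config.n_tracts)
    tracts = [
        TractRecord(
            geoid=f"{i + 1:04d}.00",
            name=f"{i + 1:04d}.00",
            geometry=cells[cell_of_point[i]],
            population=int(pops[i]),
        )
        for i in range(config.n_tracts)
    ]
    return boundary, tracts


def generate_latent_fields(config: SyntheticConfig) -> np.ndarray:
    """K smooth standardized scalar fields over the extent, shape (K, H, W).

    Each field is seeded white noise blurred with a Gaussian kernel of
    sigma = field_length_scale / pixel_size pixels, then standardized to
    mean 0 and variance 1 over the extent.
    """
    height, width = config.grid_shape
    xmin, ymin, xmax, ymax = config.extent
    if config.field_length_scale > min(xmax - xmin, ymax - ymin):
        raise ValueError("extent is smaller than one blur radius; field would be flat")
    sigma = config.field_length_scale / config.pixel_size
    fields = np.empty((config.n_latent, height, width))
    for k in range(config.n_latent):
        rng = _stream_rng(config.seed, _TAG_FIELD + 100 * k)
        noise = rng.standard_normal((height, width))
        smooth = gaussian_filter(noise, sigma=sigma, mode="reflect")
        smooth -= smooth.mean()
        sd = smooth.std()
        if sd == 0:
            raise ValueError("degenerate field: blur wiped out all variance")
        fields[k] = smooth / sd
    return fields


def _default_mixing(config: SyntheticConfig, K: int) -> np.ndarray:
    """Band mixtures: beta direction first, then seeded orthogonal complements."""
    beta = np.asarray(config.beta, dtype=float)
    if len(beta) != K:
        raise ValueError("config.beta length must match the number of fields")
    norm = np.linalg.norm(beta)
    rows = [beta / norm if norm > 0 else np.eye(K)[0]]
    rng = _stream_rng(config.seed, _TAG_MIX)
    while len(rows) < 3:
        cand = rng.standard_normal(K)
        for r in rows:
            cand -= (cand @ r) * r
        n = np.linalg.norm(cand)
        if n > 1e-8:
            rows.append(cand / n)
    return np.vstack(rows)


def render_rasters(
    fields: np.ndarray,
    config: SyntheticConfig,
    mixing: Optional[np.ndarray] = None,
    pixel_noise_sd: Optional[float] = None,
) -> list[RasterData]:
    """Render the latent fields into one 3-band unsigned-16-bit raster.

    Each band is a fixed affine mixture of the K fields plus seeded
    pixel noise, min-max rescaled into ``[0, raw_scale]`` so that the
    downstream divisor normalization recovers values in [0, 1]. The
    rescaling is monotone per band, so each band remains a monotone
    transform of its mixture.

    Default mixing: a 3-band sensor observes only 3 of the K latent
    combinations, so the default puts the outcome-relevant combination
    (the beta direction) in band 1 and two seeded orthogonal unit
    mixtures in bands 2-3 — the imagery genuinely reflects the
    environmental signal that drives the outcome, which is the premise
    of regressing outcomes on visual features. Pass ``mixing`` to
    override (e.g. an identity for K=1 diagnostics).
    """
    K = fields.shape[0]
    if mixing is None:
        mixing = _default_mixing(config, K)
    mixing = np.asarray(mixing, dtype=float)
    if mixing.shape != (3, K):
        raise ValueError(f"mixing must have shape (3, {K})")
    if pixel_noise_sd is None:
        pixel_noise_sd = config.pixel_noise_sd

    bands = np.tensordot(mixing, fields, axes=(1, 0))  # (3, H, W)
    if pixel_noise_sd > 0:
        noise_rng = _stream_rng(config.seed, _TAG_MIX + 1)
        bands = bands + noise_rng.normal(0.0, pixel_noise_sd, bands.shape)
    raw = np.empty_like(bands)
    for b in range(3):
        lo, hi = bands[b].min(), bands[b].max()
        span = hi - lo if hi > lo else 1.0
        raw[b] = (bands[b] - lo) / span * config.raw_scale
    raster = RasterData(
        pixels=np.round(raw).astype(np.uint16),
        transform=config.transform,
        crs=SYNTHETIC_CRS,
        image_id="synthetic-000",
    )
    return [raster]


def tract_field_means(
    fields: np.ndarray, tracts: Sequence[TractRecord], config: SyntheticConfig
) -> np.ndarray:
    """Mean of each latent field over each tract, shape (n_tracts, K).

    Pixel membership uses the same center-in-polygon rule as the
    aggregation stage, so the recorded truth refers to exactly the
    pixels the pipeline will count.
    """
    from .aggregate import label_pixels

    height, width = config.grid_shape
    labels = label_pixels(
        config.transform, width, height, [(t.geoid, t.geometry) for t in tracts]
    )
    K = fields.shape[0]
    n = len(tracts)
    means = np.zeros((n, K))
    flat_labels = labels.ravel()
    counts = np.bincount(flat_labels[flat_labels >= 0], minlength=n).astype(float)
    if np.any(counts == 0):
        bad = [tracts[i].geoid for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"tracts with no pixel centers: {bad}")
    for k in range(K):
        sums = np.bincount(
            flat_labels[flat_labels >= 0],
            weights=fields[k].ravel()[flat_labels >= 0],
            minlength=n,
        )
        means[:, k] = sums / counts
    return means


def generate_outcomes(
    tracts: Sequence[TractRecord],
    fields: np.ndarray,
    config: SyntheticConfig,
) -> tuple[list[TractRecord], SyntheticTruth]:
    """Attach outcome rates: linear in latent tract means plus noise.

    ``outcome_t = outcome_base + sum_k beta_k * mean_k(t) + eps_t`` with
    ``eps_t ~ N(0, noise_sd^2)``, clipped to [0, 100]. When the config
    specifies ``target_r2`` instead of ``noise_sd``, the noise standard
    deviation is calibrated from the realized signal variance so that
    signal/(signal+noise_sd^2) equals the target.
    """
    means = tract_field_means(fields, tracts, config)
    beta = np.asarray(config.beta, dtype=float)
    signal = means @ beta
    signal_var = float(np.var(signal, ddof=1))
    if config.noise_sd is not None:
        noise_sd = config.noise_sd
    else:
        r = config.target_r2
        noise_sd = float(np.sqrt(signal_var * (1.0 - r) / r)) if r < 1.0 else 0.0
    eps = _stream_rng(config.seed, _TAG_EPS).normal(0.0, noise_sd, len(tracts)) if noise_sd > 0 else np.zeros(len(tracts))
    rates = np.clip(config.outcome_base + signal + eps, 0.0, 100.0)
    noise_var = float(np.var(eps, ddof=1)) if noise_sd > 0 else 0.0
    denom = signal_var + noise_sd**2
    truth = SyntheticTruth(
        latent_means=means,
        signal_variance=signal_var,
        noise_variance=noise_var,
        true_r2=signal_var / denom if denom > 0 else 0.0,
        noise_sd=noise_sd,
    )
    out = [replace_rate(t, float(r)) for t, r in zip(tracts, rates)]
    return out, truth


def replace_rate(tract: TractRecord, rate: float) -> TractRecord:
    return TractRecord(
        geoid=tract.geoid,
        name=tract.name,
        geometry=tract.geometry,
        population=tract.population,
        outcome_rate=rate,
    )


# ---------------------------------------------------------------------------
# Identifier-bookkeeping fixtures
# ---------------------------------------------------------------------------


def subdivision_fixture(
    n_unsubdivided: int,
    n_subdivided: int,
    n_sub_bases: int,
    dialect: str = "name",
    seed: int = 0,
    with_rates: bool = True,
) -> list[TractRecord]:
    """Tract records emulating a layer with subdivided identifiers.

    ``n_unsubdivided`` records get unique base ids with trailing "00";
    ``n_subdivided`` records are spread round-robin over ``n_sub_bases``
    fresh bases with nonzero subdivision suffixes, so dissolving yields
    exactly ``n_unsubdivided + n_sub_bases`` joined tracts. Geometries
    are unit squares on a grid; rates and populations are seeded.
    """
    if n_sub_bases > n_subdivided:
        raise ValueError("cannot spread fewer subdivided records than bases")
    rng = np.random.default_rng(seed)

    def make_id(base: int, sub: int) -> str:
        if dialect == "name":
            return f"{base:04d}.{sub:02d}"
        if dialect == "geoid":
            return f"29099{base:04d}{sub:02d}"
        raise ValueError(f"unknown dialect {dialect!r}")

    records = []
    idx = 0

    def add(base, sub):
        nonlocal idx
        col, row = idx % 64, idx // 64
        records.append(
            TractRecord(
                geoid=make_id(base, sub),
                name=make_id(base, sub) if dialect == "name" else None,
                geometry=box(col, row, col + 1, row + 1),
                population=int(rng.integers(100, 8000)),
                outcome_rate=float(rng.uniform(23.0, 53.7)) if with_rates else None,
            )
        )
        idx += 1

    for i in range(n_unsubdivided):
        add(i + 1, 0)
    for j in range(n_subdivided):
        base = n_unsubdivided + 1 + (j % n_sub_bases)
        sub = 1 + (j // n_sub_bases)
        add(base, sub)
    return records


def reconciliation_fixture(seed: int = 0):
    """Two layers whose joined base sets overlap partially.

    Layer A ("boundary" side, decimal names): 740 unsubdivided + 914
    subdivided over 323 bases -> 1063 joined. Layer B ("outcome" side,
    11-digit GEOIDs): 881 unsubdivided + 506 subdivided over 178 bases
    -> 1059 joined, engineered so the two joined sets share exactly 1055
    tract codes. Returns ``(layer_a_records, layer_b_records)``.
    """
    layer_a = subdivision_fixture(740, 914, 323, dialect="name", seed=seed)
    # B reuses A's base codes 1..1055 and adds 4 codes absent from A
    rng = np.random.default_rng(seed + 1)
    records_b: list[TractRecord] = []
    idx = 0

    def add_b(base, sub):
        nonlocal idx
        col, row = idx % 64, idx // 64
        records_b.append(
            TractRecord(
                geoid=f"29099{base:04d}{sub:02d}",
                geometry=box(col, row, col + 1, row + 1),
                population=int(rng.integers(100, 8000)),
                outcome_rate=float(rng.uniform(23.0, 53.7)),
            )
        )
        idx += 1

    unsub_bases = list(range(1, 882))  # 881 unsubdivided
    sub_bases = list(range(882, 1056)) + [9001, 9002, 9003, 9004]  # 178 bases
    for base in unsub_bases:
        add_b(base, 0)
    for j in range(506):
        add_b(sub_bases[j % len(sub_bases)], 1 + j // len(sub_bases))
    return layer_a, records_b
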