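"""Per-chip visual feature vectors via a pluggable extractor.

The pipeline's regression stage consumes one fixed-length feature
vector per chip. Two backends implement the contract:

``surrogate``
    A deterministic, dependency-free image descriptor: per band the
    mean, standard deviation, skewness, min, max, mean and standard
    deviation of the gradient magnitude, and 16 block means on a 4x4
    spatial grid (23 features per band, 69 total), followed by a seeded
    fixed Gaussian random projection up to the working dimension D
    (default 2048, mirroring a deep network's penultimate-layer width
    and exercising the p >> n regression regime).

``deep``
    The penultimate-layer activations of an ImageNet-pretrained 50-layer
    residual network (2048-d). Optional: it requires torch/torchvision
    at run time and raises with fallback instructions when absent.

Chips are standardized per band with the published ImageNet statistics
before either backend runs. Standardization is applied directly to the
[0, 1]-normalized reflectance values.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .chipping import Chip

__all__ = [
    "IMAGENET_MEAN",
    "IMAGENET_SD",
    "ExtractorSpec",
    "FeatureVector",
    "standardize_chip",
    "surrogate_features",
    "extract_features",
    "N_BASE_FEATURES",
]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_SD = (0.229, 0.224, 0.225)

_BLOCK_GRID = 4
N_BASE_FEATURES = 3 * (7 + _BLOCK_GRID * _BLOCK_GRID)  # 69


@dataclass(frozen=True)
class ExtractorSpec:
    """Which extractor to run and how: kind, dimension, seed, standardization."""

    kind: str = "surrogate"
    D: int = 2048
    seed: int = 0
    mean: tuple[float, float, float] = IMAGENET_MEAN
    sd: tuple[float, float, float] = IMAGENET_SD

    def __post_init__(self):
        if self.kind not in ("surrogate", "deep"):
            raise ValueError(f"unknown extractor kind {self.kind!r}")
        if any(s <= 0 for s in self.sd):
            raise ValueError("standardization sd must be positive for every band")
        if self.D < N_BASE_FEATURES:
            raise ValueError(f"D must be >= {N_BASE_FEATURES}")

    @property
    def extractor_id(self) -> str:
        return f"{self.kind}-d{self.D}-s{self.seed}"


@dataclass
class FeatureVector:
    chip_id: str
    values: np.ndarray
    extractor_id: str

    @property
    def D(self) -> int:
        return len(self.values)


def standardize_chip(chip: Chip, spec: ExtractorSpec) -> np.ndarray:
    """Map band b to (value - mean_b) / sd_b."""
    pixels = np.asarray(chip.pixels, dtype=np.float64)
    if pixels.shape[0] != len(spec.mean):
        raise ValueError(
            f"chip has {pixels.shape[0]} bands but the spec standardizes {len(spec.mean)}"
        )
    mean = np.asarray(spec.mean)[:, None, None]
    sd = np.asarray(spec.sd)[:, None, None]
    return (pixels - mean) / sd


def _block_means(band: np.ndarray, grid: int = _BLOCK_GRID) -> np.ndarray:
    rows = np.array_split(band, grid, axis=0)
    return np.array(
        [blk.mean() for row in rows for blk in np.array_split(row, grid, axis=1)]
    )


def _base_features(pixels: np.ndarray) -> np.ndarray:
    feats = []
    for band in pixels:
        flat = band.ravel()
        gy, gx = np.gradient(band)
        gmag = np.hypot(gx, gy)
        sd = flat.std()
        # constant bands: skew is 0 by convention (guard against 0/0)
        skew = stats.skew(flat) if sd > 1e-12 * (1.0 + abs(flat.mean())) else 0.0
        feats.extend(
            [flat.mean(), sd, skew, flat.min(), flat.max(), gmag.mean(), gmag.std()]
        )
        feats.extend(_block_means(band))
    return np.asarray(feats, dtype=np.float64)


@lru_cache(maxsize=8)
def _projection(D: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    return rng.standard_normal((D, N_BASE_FEATURES)) / np.sqrt(N_BASE_FEATURES)


def surrogate_features(pixels: np.ndarray, D: int, seed: int) -> np.ndarray:
    """Deterministic 69-dim image descriptor lifted to D dims by a fixed
    seeded random projection (injective on the base space w.p. 1)."""
    base = _base_features(pixels)
    return _projection(D, seed) @ base


def _deep_features(pixels: np.ndarray, spec: ExtractorSpec) -> np.ndarray:
    try:
        import torch  # noqa: F401
        from torchvision.models import resnet50  # noqa: F401
    except ImportError as exc:
        raise RuntimeError(
            "the deep extractor backend needs torch and torchvision, which are not "
            "installed; fall back to the surrogate extractor "
            "(ExtractorSpec(kind='surrogate'))"
        ) from exc
    import torch
    from torchvision.models import ResNet50_Weights, resnet50

    model = resnet50(weights=ResNet50_Weights.IMAGENET1K_V2)
    model.fc = torch.nn.Identity()
    model.eval()
    with torch.no_grad():
        out = model(torch.from_numpy(pixels[None]).float())
    return out.numpy().ravel()


def extract_features(chip: Chip, spec: ExtractorSpec) -> FeatureVector:
    """Standardize a chip and run the configured extractor backend.

    Pure function of (pixels, spec): the same chip and spec always give
    bit-identical vectors.
    """
    std = standardize_chip(chip, spec)
    if spec.kind == "surrogate":
        values = surrogate_features(std, spec.D, spec.seed)
    else:
        values = _deep_features(std, spec)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-finite feature values for chip {chip.window.chip_id}")
    return FeatureVector(
        chip_id=chip.window.chip_id, values=values, extractor_id=spec.extractor_id
    )


def extract_all(chips, spec: ExtractorSpec) -> list[FeatureVector]:
    """Extract features for an iterable of chips, enforcing one extractor per run."""
    return [extract_features(chip, spec) for chip in chips]
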