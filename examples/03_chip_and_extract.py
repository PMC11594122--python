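"""Tile a raster into georeferenced chips and extract feature vectors.

Chips are full-size square windows; a ragged edge is handled by
clamping the last row/column inward, so a 10,980-px satellite tile
yields exactly 50 x 50 windows. Each chip is normalized to [0, 1],
standardized with the ImageNet per-band statistics, and mapped to a
2048-d feature vector by the surrogate extractor.
"""

import numpy as np

import tractscape as ts

# the statewide bookkeeping: 33 full-size tiles at 224-px chips
per_tile = ts.plan_chip_grid(10980, 10980, 224)
print(f"one 10,980 px tile -> {len(per_tile)} chip windows; "
      f"33 tiles -> {33 * len(per_tile)} chips")

# a desk-scale raster from the synthetic generator
config = ts.SyntheticConfig(seed=7, n_tracts=20, extent=(0, 0, 2240, 2240),
                            field_length_scale=500.0)
fields = ts.generate_latent_fields(config)
(raster,) = ts.render_rasters(fields, config)

windows = ts.plan_chip_grid(
    raster.width, raster.height, 28,
    image_transform=raster.transform, image_id=raster.image_id, crs=raster.crs,
)
spec = ts.ExtractorSpec(kind="surrogate", D=2048, seed=7)
vectors = ts.extract_all(ts.cut_chips(raster, windows), spec)

v = np.vstack([fv.values for fv in vectors])
print(f"raster {raster.height}x{raster.width} px -> {len(windows)} chips of 28 px")
print(f"feature matrix: {v.shape[0]} chips x {v.shape[1]} dims, "
      f"values finite: {np.isfinite(v).all()}")
print(f"chip (0,0) footprint origin: {windows[0].transform.xy(0, 0)}")
# Each chip carries its own affine transform, so every feature vector
# is tied to an exact ground footprint for the aggregation step.
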