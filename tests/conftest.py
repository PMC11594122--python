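import numpy as np
import pytest
import shapely
from hypothesis import settings

import tractscape as ts

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    """A fast desk-scale region: 30 tracts over a 2.24 km square (224 px grid)."""
    return ts.SyntheticConfig(
        seed=7, n_tracts=30, extent=(0.0, 0.0, 2240.0, 2240.0), field_length_scale=400.0
    )


@pytest.fixture(scope="session")
def small_region(small_config):
    return ts.generate_region(small_config)


@pytest.fixture(scope="session")
def small_fields(small_config):
    return ts.generate_latent_fields(small_config)


def brute_force_weights(window, tracts):
    """Per-pixel enumeration oracle for chip-tract pixel counts.

    Walks every pixel center of the window, finds the tracts covering
    it, and assigns the pixel to the lexicographically smallest tract
    id — the same membership rule as the production path, implemented
    as a plain double loop.
    """
    counts = {}
    ordered = sorted(tracts, key=lambda t: t.base_id)
    for row in range(window.height):
        for col in range(window.width):
            x, y = window.transform.pixel_center(col, row)
            pt = shapely.Point(float(x), float(y))
            for t in ordered:
                if t.geometry is not None and t.geometry.covers(pt):
                    counts[t.base_id] = counts.get(t.base_id, 0) + 1
                    break
    return counts


def voronoi_tracts(n, extent, seed):
    """n small Voronoi tracts over an extent, as JoinedTracts with seeded rates."""
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = extent
    pts = shapely.points(
        rng.uniform(xmin, xmax, n), rng.uniform(ymin, ymax, n)
    )
    bbox = shapely.box(xmin, ymin, xmax, ymax)
    cells = shapely.get_parts(
        shapely.voronoi_polygons(shapely.multipoints(pts), extend_to=bbox)
    )
    return [
        ts.JoinedTract(
            base_id=f"{i + 1:04d}.00",
            geometry=shapely.intersection(c, bbox),
            population=int(rng.integers(100, 5000)),
            outcome_rate=float(rng.uniform(23.0, 53.7)),
            n_members=1,
        )
        for i, c in enumerate(cells)
    ]
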