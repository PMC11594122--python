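"""Pixel-count weights and weighted aggregation against per-pixel oracles."""

import numpy as np
import pytest
from shapely.geometry import box

import tractscape as ts
from tractscape.aggregate import window_weights_from_labels
from tractscape.raster_io import Affine

from conftest import brute_force_weights, voronoi_tracts


def _window(size, pixel=10.0, origin=(0.0, None), image_id="img"):
    x0 = origin[0]
    y_max = origin[1] if origin[1] is not None else size * pixel
    return ts.ChipWindow(
        image_id=image_id, row_index=0, col_index=0,
        pixel_window=(0, 0, size, size),
        transform=Affine.north_up(x0, y_max, pixel), crs="PLANAR:1m",
    )


def _tract(base_id, geometry, rate=40.0):
    return ts.JoinedTract(base_id=base_id, geometry=geometry, population=1000,
                          outcome_rate=rate, n_members=1)


def test_full_cover_chip_has_chip_size_squared_pixels():
    win = _window(224)
    weights = ts.pixel_weights(win, [_tract("0001.00", box(-10, -10, 2250, 2250))])
    assert len(weights) == 1
    assert weights[0].pixel_count == 224 * 224


def test_half_cover_split_at_pixel_column():
    win = _window(224)
    # left half: x < 1120 m covers pixel centers of columns 0..111
    weights = ts.pixel_weights(win, [_tract("0001.00", box(0, 0, 1120, 2240))])
    assert weights[0].pixel_count == 112 * 224


def test_disjoint_polygon_emits_nothing():
    win = _window(32)
    assert ts.pixel_weights(win, [_tract("0001.00", box(-500, -500, -100, -100))]) == []


def test_crs_mismatch_errors():
    win = _window(16)
    with pytest.raises(ValueError, match="mismatch"):
        ts.pixel_weights(win, [_tract("0001.00", box(0, 0, 160, 160))],
                         tracts_crs="EPSG:32615")


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("size,n_tracts", [(16, 3), (32, 5), (64, 4)])
def test_pixel_weights_match_bruteforce_enumeration(seed, size, n_tracts):
    extent = (0.0, 0.0, size * 10.0, size * 10.0)
    tracts = voronoi_tracts(n_tracts, extent, seed)
    win = _window(size)
    fast = {w.tract_id: w.pixel_count for w in ts.pixel_weights(win, tracts)}
    assert fast == brute_force_weights(win, tracts)


def test_partition_conservation():
    """Tracts partitioning the chip footprint account for every pixel."""
    extent = (0.0, 0.0, 320.0, 320.0)
    tracts = voronoi_tracts(5, extent, seed=4)
    win = _window(32)
    weights = ts.pixel_weights(win, tracts)
    assert sum(w.pixel_count for w in weights) == 32 * 32


def test_window_slice_equals_direct_weights():
    extent = (0.0, 0.0, 640.0, 640.0)
    tracts = voronoi_tracts(5, extent, seed=2)
    pairs = [(t.base_id, t.geometry) for t in tracts]
    labels = ts.label_pixels(Affine.north_up(0.0, 640.0, 10.0), 64, 64, pairs)
    sorted_ids = sorted(t.base_id for t in tracts)
    for row in range(2):
        for col in range(2):
            win = ts.ChipWindow(
                image_id="img", row_index=row, col_index=col,
                pixel_window=(col * 32, row * 32, 32, 32),
                transform=Affine.north_up(col * 320.0, 640.0 - row * 320.0, 10.0),
                crs="PLANAR:1m",
            )
            direct = ts.pixel_weights(win, tracts)
            sliced = window_weights_from_labels(win, labels, sorted_ids)
            assert {(w.tract_id, w.pixel_count) for w in direct} == {
                (w.tract_id, w.pixel_count) for w in sliced
            }


def test_filter_usable_chips_rules():
    boundary = box(0, 0, 640, 640)
    inside = _window(32, origin=(0.0, 320.0))          # 0..320 x 0..320
    straddling = _window(32, origin=(480.0, 320.0))    # 480..800 exceeds boundary
    no_tract = ts.ChipWindow(
        image_id="img", row_index=9, col_index=9, pixel_window=(0, 0, 32, 32),
        transform=Affine.north_up(320.0, 640.0, 10.0), crs="PLANAR:1m",
    )
    weights = [
        ts.IntersectionWeight(inside.chip_id, "0001.00", 10),
        ts.IntersectionWeight(straddling.chip_id, "0001.00", 10),
    ]
    kept = ts.filter_usable_chips([inside, straddling, no_tract], boundary, weights)
    assert kept == [inside]


@pytest.mark.parametrize(
    "weights,vectors,expected",
    [
        ([5], [(1.5, -2.0)], (1.5, -2.0)),
        ([3, 3], [(0.0, 0.0), (4.0, 8.0)], (2.0, 4.0)),
        ([1, 3], [(0.0, 0.0), (4.0, 8.0)], (3.0, 6.0)),
    ],
)
def test_tract_feature_weighted_mean(weights, vectors, expected):
    features = {f"img:0:{i}": np.array(v) for i, v in enumerate(vectors)}
    ws = [
        ts.IntersectionWeight(f"img:0:{i}", "0001.00", w)
        for i, w in enumerate(weights)
    ]
    tf = ts.tract_feature(features, ws)
    assert np.allclose(tf.values, expected)
    assert tf.total_weight == sum(weights)
    assert tf.n_chips == len(weights)


def test_tract_feature_errors():
    with pytest.raises(ValueError, match="missing feature"):
        ts.tract_feature({}, [ts.IntersectionWeight("img:0:0", "t", 5)])
    with pytest.raises(ValueError, match="zero total"):
        ts.tract_feature(
            {"img:0:0": np.zeros(2)}, [ts.IntersectionWeight("img:0:0", "t", 0)]
        )


@pytest.mark.parametrize(
    "counts,rates,expected",
    [
        ([100], [39.2], 39.2),
        ([10, 10], [30.0, 50.0], 40.0),
        ([25088, 25088], [23.0, 53.7], 38.35),
    ],
)
def test_chip_outcome_weighted_mean(counts, rates, expected):
    ws = [
        ts.IntersectionWeight("img:0:0", f"{i:04d}.00", c)
        for i, c in enumerate(counts)
    ]
    rate_map = {f"{i:04d}.00": r for i, r in enumerate(rates)}
    out = ts.chip_outcome(rate_map, ws)
    assert out.rate == pytest.approx(expected, abs=1e-12)
    assert out.n_tracts == len(counts)


def test_chip_outcome_missing_rate_errors():
    ws = [ts.IntersectionWeight("img:0:0", "0001.00", 10)]
    with pytest.raises(ValueError, match="missing outcome"):
        ts.chip_outcome({"0001.00": None}, ws)


def test_aggregates_stay_in_componentwise_range():
    rng = np.random.default_rng(8)
    features = {f"img:0:{i}": rng.normal(size=6) for i in range(5)}
    ws = [
        ts.IntersectionWeight(f"img:0:{i}", "0001.00", int(rng.integers(1, 100)))
        for i in range(5)
    ]
    tf = ts.tract_feature(features, ws)
    stack = np.vstack(list(features.values()))
    assert np.all(tf.values >= stack.min(axis=0) - 1e-12)
    assert np.all(tf.values <= stack.max(axis=0) + 1e-12)


def test_aggregation_is_order_invariant():
    rng = np.random.default_rng(3)
    features = {f"img:0:{i}": rng.normal(size=4) for i in range(6)}
    ws = [
        ts.IntersectionWeight(f"img:0:{i}", "0001.00", int(rng.integers(1, 50)))
        for i in range(6)
    ]
    fwd = ts.tract_feature(features, ws)
    rev = ts.tract_feature(features, list(reversed(ws)))
    assert np.allclose(fwd.values, rev.values, rtol=1e-12)


def test_weighted_means_match_direct_summation():
    """End-to-end aggregation oracle on a tiny raster with 4 tracts."""
    extent = (0.0, 0.0, 640.0, 640.0)
    tracts = voronoi_tracts(4, extent, seed=6)
    wins = [
        ts.ChipWindow(
            image_id="img", row_index=r, col_index=c,
            pixel_window=(c * 32, r * 32, 32, 32),
            transform=Affine.north_up(c * 320.0, 640.0 - r * 320.0, 10.0),
            crs="PLANAR:1m",
        )
        for r in range(2) for c in range(2)
    ]
    weights = [w for win in wins for w in ts.pixel_weights(win, tracts)]
    rng = np.random.default_rng(0)
    features = {w.chip_id: rng.normal(size=3) for w in wins}
    by_tract = {}
    for w in weights:
        by_tract.setdefault(w.tract_id, []).append(w)
    for tid, ws in by_tract.items():
        tf = ts.tract_feature(features, ws)
        num = sum(w.pixel_count * features[w.chip_id] for w in ws)
        den = sum(w.pixel_count for w in ws)
        assert np.allclose(tf.values, num / den, rtol=1e-12)
    rates = {t.base_id: t.outcome_rate for t in tracts}
    by_chip = {}
    for w in weights:
        by_chip.setdefault(w.chip_id, []).append(w)
    for cid, ws in by_chip.items():
        oc = ts.chip_outcome(rates, ws)
        expected = sum(w.pixel_count * rates[w.tract_id] for w in ws) / sum(
            w.pixel_count for w in ws
        )
        assert oc.rate == pytest.approx(expected, rel=1e-12)


def test_build_design_matrix_alignment_and_exclusions():
    feats = {
        "0001.00": ts.TractFeature("0001.00", np.array([1.0, 2.0]), 10, 1),
        "0002.00": ts.TractFeature("0002.00", np.array([3.0, 4.0]), 10, 1),
        "0003.00": ts.TractFeature("0003.00", np.array([5.0, 6.0]), 10, 1),
    }
    outcomes = {"0001.00": 30.0, "0002.00": 40.0, "0003.00": None}
    X, y, ids = ts.build_design_matrix(feats, outcomes)
    assert ids == ["0001.00", "0002.00"]
    assert X.shape == (2, 2)
    assert np.allclose(X[0], feats["0001.00"].values)
    assert np.allclose(y, [30.0, 40.0])

    with pytest.raises(ValueError, match="no tract"):
        ts.build_design_matrix({}, {"0001.00": 30.0})
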