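"""Raster workflow: HID tiles, area tiles, aggregation, statistics."""

import numpy as np
import pandas as pd
import pytest

from hexeco.geodesy import WGS84
from hexeco.grid import cell_area_km2, cell_count
from hexeco.rasters import (Affine, CRS, ContingencyTable, RasterTile,
                            WeightedSums, accumulate_weighted,
                            build_area_tile, build_hid_tile,
                            counts_to_area_weights, crosstab_discrete,
                            read_ascii_grid, stat_centroid, stat_fraction,
                            stat_mean, stat_mode, write_ascii_grid)

KOPPEN_LEGEND = ["Af", "Am", "Aw", "BWh", "BWk", "BSh", "BSk",
                 "Csa", "Csb", "Csc", "Cwa", "Cwb", "Cwc",
                 "Cfa", "Cfb", "Cfc", "Dsa", "Dsb", "Dsc", "Dsd",
                 "Dwa", "Dwb", "Dwc", "Dwd", "Dfa", "Dfb", "Dfc", "Dfd",
                 "ET", "EF"]


def geo_tile(values, lat_max=30.0, lon_min=0.0, pixel=0.5, nodata=None):
    return RasterTile(np.asarray(values),
                      Affine.from_origin(lon_min, lat_max, pixel, pixel),
                      CRS.geographic(), nodata=nodata)


# ----------------------------------------------------------------------
def test_hid_tile_total_and_oracle(grid, rng):
    tile = geo_tile(np.zeros((60, 120)))
    ht = build_hid_tile(tile, 4, grid)
    assert ht.hids.shape == tile.shape
    assert ht.hids.min() >= 1 and ht.hids.max() <= cell_count(4)
    # per-pixel agreement with direct point location; pixels exactly on a
    # cell boundary (the grid's symmetry meridian crosses this lattice)
    # may tie either way, so any disagreement must be an exact tie
    from hexeco.geodesy import great_circle_km
    lon, lat = tile.pixel_centroids_lonlat()
    direct = grid.locate(lat.ravel(), lon.ravel(), 4)
    diff = np.nonzero(ht.hids.ravel() != direct)[0]
    assert len(diff) <= tile.values.size * 1e-3
    for i in diff:
        la, lo = lat.ravel()[i], lon.ravel()[i]
        d1 = great_circle_km(la, lo, *grid.centroid(int(direct[i]), 4))
        d2 = great_circle_km(la, lo, *grid.centroid(int(ht.hids.ravel()[i]), 4))
        assert abs(d1 - d2) < 1e-6


def test_abutting_tiles_agree_on_shared_seam(grid):
    left = geo_tile(np.zeros((40, 40)), lon_min=0.0)
    right = geo_tile(np.zeros((40, 40)), lon_min=20.0)
    hl = build_hid_tile(left, 5, grid)
    hr = build_hid_tile(right, 5, grid)
    # pixels immediately left/right of the seam belong to a continuous map
    merged = geo_tile(np.zeros((40, 80)), lon_min=0.0)
    hm = build_hid_tile(merged, 5, grid)
    assert (hm.hids[:, :40] == hl.hids).all()
    assert (hm.hids[:, 40:] == hr.hids).all()


def test_area_tile_monotone_and_global_sum():
    tile = RasterTile(np.zeros((180, 360)),
                      Affine.from_origin(-180, 90, 1.0, 1.0))
    at = build_area_tile(tile)
    north = at.values[:90, 0]
    assert (np.diff(north) > 0).all()          # shrinks toward the pole
    assert at.values.sum() == pytest.approx(WGS84.total_area_km2, rel=1e-9)


def test_area_tile_authalic_warns_and_is_constant():
    tile = RasterTile(np.zeros((5, 5)),
                      Affine.from_origin(0, 1e6, 463.31, 463.31),
                      CRS.sinusoidal(), authalic=True)
    with pytest.warns(UserWarning):
        at = build_area_tile(tile)
    assert np.allclose(at.values, at.values[0, 0])


# ----------------------------------------------------------------------
def test_crosstab_against_bruteforce_oracle(grid, rng):
    vals = rng.integers(0, 4, size=(100, 100)).astype(float)
    vals[rng.random((100, 100)) < 0.1] = -1          # nodata speckle
    tile = geo_tile(vals, nodata=-1, pixel=0.2)
    ht = build_hid_tile(tile, 4, grid)
    at = build_area_tile(tile)
    table = crosstab_discrete(tile, ht, at)

    oracle = {}
    for r in range(100):
        for c in range(100):
            if vals[r, c] == -1:
                continue
            key = (ht.hids[r, c], vals[r, c])
            oracle[key] = oracle.get(key, 0.0) + at.values[r, c]
    assert len(table.weights) == len(oracle)
    for key, w in oracle.items():
        assert table.weights[key] == pytest.approx(w, rel=1e-12)


def test_crosstab_weight_conservation(grid, rng):
    vals = rng.integers(0, 3, size=(50, 50)).astype(float)
    tile = geo_tile(vals, pixel=0.2)
    ht = build_hid_tile(tile, 4, grid)
    at = build_area_tile(tile)
    table = crosstab_discrete(tile, ht, at)
    per_hid = table.total_per_hid()
    totals = pd.Series(at.values.ravel()).groupby(ht.hids.ravel()).sum()
    assert np.allclose(per_hid.sort_index(), totals.sort_index(), rtol=1e-12)


def test_crosstab_requires_alignment(grid):
    tile = geo_tile(np.zeros((10, 10)))
    ht = build_hid_tile(geo_tile(np.zeros((10, 11))), 4, grid)
    with pytest.raises(ValueError):
        crosstab_discrete(tile, ht)


def test_tile_merge_is_order_independent(grid, rng):
    tiles = [geo_tile(rng.integers(0, 3, (20, 20)).astype(float),
                      lon_min=20.0 * i, pixel=0.5) for i in range(4)]
    parts = []
    for t in tiles:
        ht = build_hid_tile(t, 4, grid)
        parts.append(crosstab_discrete(t, ht, build_area_tile(t)))
    fwd = parts[0] + parts[1] + parts[2] + parts[3]
    rev = parts[3] + parts[1] + parts[0] + parts[2]
    pd.testing.assert_series_equal(fwd.weights.sort_index(),
                                   rev.weights.sort_index())


# ----------------------------------------------------------------------
def test_stat_centroid_constant_nodata_and_oracle(grid):
    vals = np.full((120, 120), 3.25)
    tile = geo_tile(vals, lat_max=30.0, pixel=0.5, nodata=-9999.0)
    hids = np.unique(build_hid_tile(tile, 4, grid).hids)
    col = stat_centroid(tile, hids, 4, grid, null_value=-100.0)
    lat, lon = grid.centroid(hids, 4)
    inside = (lat < 29.0) & (lat > -29.0) & (lon > 1.0) & (lon < 59.0)
    assert (col[hids[inside]] == 3.25).all()
    # centroids outside the raster footprint carry the null flag
    far = stat_centroid(tile, np.array([1]), 4, grid, null_value=-100.0)
    assert far.iloc[0] == -100.0
    # nodata at the centroid also nulls
    vals2 = vals.copy()
    tile2 = geo_tile(vals2, lat_max=30.0, pixel=0.5, nodata=-9999.0)
    h0 = int(hids[inside][0])
    la, lo = grid.centroid(h0, 4)
    c, r = tile2.transform.inverse(tile2.crs.from_lonlat(lo, la))
    tile2.values[int(r), int(c)] = -9999.0
    assert stat_centroid(tile2, np.array([h0]), 4, grid).iloc[0] == -100.0


def test_koppen_legend_yields_thirty_fraction_columns(grid):
    vals = np.zeros((30, 60))           # one class only ("Af")
    tile = geo_tile(vals, pixel=1.0)
    ht = build_hid_tile(tile, 3, grid)
    table = crosstab_discrete(tile, ht, build_area_tile(tile))
    table = ContingencyTable(table.weights.rename(
        index={0.0: "Af"}, level="klass"))
    frac = stat_fraction(table, 3, KOPPEN_LEGEND)
    assert list(frac.columns) == KOPPEN_LEGEND
    assert len(frac.columns) == 30
    assert (frac[KOPPEN_LEGEND[1:]].to_numpy() == 0).all()
    mode = stat_mode(frac)
    assert set(mode.unique()) <= {"Af", -1}


def test_fraction_all_ocean_cell_is_zero():
    table = ContingencyTable()
    frac = stat_fraction(table, 3, ["A", "B"])
    assert frac.empty and list(frac.columns) == ["A", "B"]


def test_fraction_of_global_constant_raster_near_one(grid):
    tile = geo_tile(np.zeros((360, 720)), lat_max=90.0, lon_min=-180.0,
                    pixel=0.5)
    ht = build_hid_tile(tile, 3, grid)
    table = crosstab_discrete(tile, ht, build_area_tile(tile))
    frac = stat_fraction(table, 3, [0.0])
    # every cell is fully covered up to pixel-assignment noise
    assert len(frac) == cell_count(3)
    assert frac[0.0].median() == pytest.approx(1.0, abs=2e-3)
    assert frac[0.0].min() > 0.97


def test_fraction_pentagon_uses_five_sixths_denominator(grid):
    tile = geo_tile(np.zeros((360, 720)), lat_max=90.0, lon_min=-180.0,
                    pixel=0.5)
    ht = build_hid_tile(tile, 3, grid)
    table = crosstab_discrete(tile, ht, build_area_tile(tile))
    frac = stat_fraction(table, 3, [0.0])
    assert frac.loc[1:12, 0.0].min() > 0.97    # would be ~0.83 otherwise


def test_fraction_counts_on_authalic_grid():
    w = pd.Series({(50, "A"): 100.0, (50, "B"): 60.0})
    w.index.names = ["hid", "klass"]
    pixel_area = cell_area_km2(9) / 200.0
    table = counts_to_area_weights(ContingencyTable(w), pixel_area)
    frac = stat_fraction(table, 9, ["A", "B"])
    assert frac.loc[50, "A"] == pytest.approx(0.5)
    assert frac.loc[50, "B"] == pytest.approx(0.3)


def test_fraction_integrity_error():
    w = pd.Series({(50, "A"): cell_area_km2(9) * 1.5})
    w.index.names = ["hid", "klass"]
    with pytest.raises(ValueError):
        stat_fraction(ContingencyTable(w), 9, ["A"])


# ----------------------------------------------------------------------
def _frac_frame(d):
    df = pd.DataFrame([d])
    df.index = pd.Index([1], name="HID")
    return df


def test_mode_majority_threshold_and_tiebreak():
    assert stat_mode(_frac_frame({"A": 0.4, "B": 0.3, "C": 0.3})).iloc[0] == "A"
    assert stat_mode(_frac_frame({"A": 0.1, "B": 0.05})).iloc[0] == -1
    # tie: first class in legend order wins
    assert stat_mode(_frac_frame({"A": 0.3, "B": 0.3})).iloc[0] == "A"
    assert stat_mode(_frac_frame({"B": 0.3, "A": 0.3})).iloc[0] == "B"


def test_mean_examples():
    sums = WeightedSums(pd.Series({1: 1 * 10.0 + 3 * 20.0}),
                        pd.Series({1: 4.0}))
    assert stat_mean(sums).loc[1] == pytest.approx(17.5)
    # equal weights reduce to the simple mean
    sums = WeightedSums(pd.Series({1: 2.0 + 4.0 + 9.0}), pd.Series({1: 3.0}))
    assert stat_mean(sums).loc[1] == pytest.approx(5.0)
    # zero weight -> null flag
    sums = WeightedSums(pd.Series({1: 0.0}), pd.Series({1: 0.0}))
    assert stat_mean(sums, null_value=-1000.0).loc[1] == -1000.0


def test_mean_bounded_by_pixel_values(grid, rng):
    vals = rng.uniform(-5, 35, (80, 80))
    tile = geo_tile(vals, pixel=0.25)
    ht = build_hid_tile(tile, 4, grid)
    sums = accumulate_weighted(tile, ht, build_area_tile(tile))
    mean = stat_mean(sums)
    for hid in mean.index[:50]:
        pix = vals[ht.hids == hid]
        assert pix.min() - 1e-9 <= mean[hid] <= pix.max() + 1e-9


def test_constant_field_mean_is_constant(grid):
    tile = geo_tile(np.full((60, 60), 8.125), pixel=0.25)
    ht = build_hid_tile(tile, 4, grid)
    mean = stat_mean(accumulate_weighted(tile, ht, build_area_tile(tile)))
    assert np.allclose(mean.to_numpy(), 8.125)


def test_tiled_equals_monolithic(grid, rng):
    """Two half tiles accumulate to the same statistics as one tile."""
    vals = rng.uniform(0, 1, (60, 120))
    whole = geo_tile(vals, pixel=0.25)
    left = geo_tile(vals[:, :60], pixel=0.25, lon_min=0.0)
    right = geo_tile(vals[:, 60:], pixel=0.25, lon_min=15.0)
    sums_w = accumulate_weighted(whole, build_hid_tile(whole, 4, grid),
                                 build_area_tile(whole))
    s1 = accumulate_weighted(left, build_hid_tile(left, 4, grid),
                             build_area_tile(left))
    s2 = accumulate_weighted(right, build_hid_tile(right, 4, grid),
                             build_area_tile(right))
    merged = s1 + s2
    pd.testing.assert_series_equal(stat_mean(sums_w), stat_mean(merged),
                                   rtol=1e-12)


# ----------------------------------------------------------------------
def test_ascii_grid_round_trip(tmp_path, rng):
    vals = rng.uniform(0, 100, (12, 17)).round(3)
    vals[0, 0] = -9999.0
    tile = geo_tile(vals, nodata=-9999.0, pixel=0.5)
    path = tmp_path / "t.asc"
    write_ascii_grid(tile, path)
    back = read_ascii_grid(path)
    assert back.values.shape == tile.values.shape
    assert np.allclose(back.values, tile.values)
    assert back.nodata == -9999.0
    assert back.crs.is_geographic
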