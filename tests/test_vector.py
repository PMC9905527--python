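"""Vector workflow: dissolve, validity, cell polygons, overlay, checks."""

import numpy as np
import pytest
from shapely.geometry import MultiPolygon, Polygon, box

from hexeco.geodesy import WGS84
from hexeco.grid import cell_count
from hexeco.vectors import (ClassedPolygonSet, IntersectionRecord,
                            cell_polygons, cross_resolution_index, dissolve,
                            geodesic_geom_area_km2, intersect,
                            read_geojson, records_to_fractions,
                            validate_simple_features, verify, write_geojson)


def sq(x0, y0, w):
    return box(x0, y0, x0 + w, y0 + w)


@pytest.fixture(scope="module")
def cells_r3(grid):
    """All resolution-3 cell polygons, built once."""
    return cell_polygons(3, grid=grid)


# ----------------------------------------------------------------------
def test_dissolve_merges_within_class():
    pset = ClassedPolygonSet([("a", sq(0, 0, 1)), ("a", sq(1, 0, 1)),
                              ("b", sq(5, 5, 1))])
    d = dissolve(pset)
    assert sorted(lbl for lbl, _ in d.polygons) == ["a", "b"]
    a = dict(d.polygons)["a"]
    # abutting squares: areas add
    assert d.class_areas_km2["a"] == pytest.approx(
        geodesic_geom_area_km2(sq(0, 0, 1)) * 2, rel=1e-6)
    # overlapping squares: union smaller than the sum
    ov = dissolve(ClassedPolygonSet([("a", sq(0, 0, 1)),
                                     ("a", sq(0.5, 0, 1))]))
    assert ov.class_areas_km2["a"] < 2 * geodesic_geom_area_km2(sq(0, 0, 1))


def test_dissolve_global_collapses_classes():
    pset = ClassedPolygonSet([("a", sq(0, 0, 1)), ("b", sq(1, 0, 1))])
    d = dissolve(pset, by_class=False)
    assert len(d.polygons) == 1


def test_validate_flags_and_repairs():
    bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
    good = sq(10, 10, 1)
    pset = ClassedPolygonSet([("bad", bowtie), ("ok", good)])
    out = validate_simple_features(pset)
    kinds = {f[0] for f in out.flags}
    assert "repaired" in kinds
    labels = [lbl for lbl, _ in out.polygons]
    assert "ok" in labels and "bad" in labels
    fixed = dict(out.polygons)["bad"]
    assert fixed.is_valid
    # the valid geometry passes through unchanged
    assert dict(out.polygons)["ok"].equals(good)


def test_validate_handles_duplicate_vertices():
    ring = Polygon([(0, 0), (1, 0), (1, 0), (1, 1), (0, 1)])
    out = validate_simple_features(ClassedPolygonSet([("x", ring)]))
    assert len(out.polygons) == 1
    assert out.polygons[0][1].is_valid


# ----------------------------------------------------------------------
def test_cell_polygons_respects_hid_range(grid):
    pset = cell_polygons(3, hid_range=(40, 60), grid=grid)
    hids = [h for h, _ in pset.polygons]
    assert hids == list(range(40, 61))


def test_cell_polygons_partition_covers_globe(grid):
    pset = cell_polygons(2, grid=grid, densify_per_edge=120)
    total = sum(pset.class_areas_km2.values())
    assert total == pytest.approx(WGS84.total_area_km2, rel=1e-4)


def test_staircase_matches_analytic_areas(grid):
    """Raster-polygonized (30 arc-second) cell footprints reproduce the
    analytic cell areas within the 0.5% fidelity bound."""
    hids = [40, 41]
    ana = cell_polygons(6, hids=hids, grid=grid)
    stair = cell_polygons(6, hids=hids, grid=grid, mode="pixel_staircase",
                          staircase_pixel_deg=1 / 120.0)
    for h in hids:
        assert stair.class_areas_km2[h] == pytest.approx(
            ana.class_areas_km2[h], rel=5e-3)


# ----------------------------------------------------------------------
def test_intersect_identity_and_total_cover(grid):
    cells = cell_polygons(3, hid_range=(100, 130), grid=grid)
    one = dict(cells.polygons)[115]
    classes = ClassedPolygonSet([("self", one)], cells.crs,
                                {"self": cells.class_areas_km2[115]})
    recs = intersect(cells, classes)
    own = [r for r in recs if r.hid == 115]
    assert len(own) == 1
    assert own[0].fraction == pytest.approx(1.0, abs=1e-6)
    # neighbors receive nothing but boundary slivers
    assert all(r.fraction < 1e-6 for r in recs if r.hid != 115)


def test_intersect_conservation_random_polygons(grid, rng, cells_r3):
    """Sum of per-cell intersected areas equals the dissolved area."""
    for trial in range(3):
        pts = rng.uniform(-1, 1, (12, 2)) * np.array([30.0, 20.0]) \
            + np.array([rng.uniform(-120, 120), rng.uniform(-40, 40)])
        from shapely.geometry import MultiPoint
        poly = MultiPoint(pts).convex_hull
        pset = dissolve(ClassedPolygonSet([("sp", poly)]))
        recs = intersect(cells_r3, pset)
        total = sum(r.area_km2 for r in recs)
        assert total == pytest.approx(pset.class_areas_km2["sp"], rel=1e-6)


def test_intersect_requires_matching_crs(grid):
    from hexeco.rasters import CRS
    cells = cell_polygons(2, grid=grid)
    classes = ClassedPolygonSet([("a", sq(0, 0, 10))], CRS.sinusoidal())
    with pytest.raises(ValueError):
        intersect(cells, classes)


def test_intersect_order_independent(grid, rng):
    cells = cell_polygons(3, hid_range=(50, 120), grid=grid)
    polys = [("a", sq(-20, -10, 15)), ("b", sq(0, 0, 12)),
             ("c", sq(-5, -20, 9))]
    p1 = dissolve(ClassedPolygonSet(polys))
    p2 = dissolve(ClassedPolygonSet(polys[::-1]))
    r1 = intersect(cells, p1)
    r2 = intersect(cells, p2)
    k1 = [(r.hid, r.klass, round(r.area_km2, 6)) for r in r1]
    k2 = [(r.hid, r.klass, round(r.area_km2, 6)) for r in r2]
    assert k1 == k2


# ----------------------------------------------------------------------
def test_verify_clean_run_passes(grid, cells_r3):
    cells = cells_r3
    pset = dissolve(ClassedPolygonSet([("sp", sq(-30, -10, 25))]))
    recs = intersect(cells, pset)
    rep = verify(recs, cells, pset)
    assert rep.passed
    assert not rep.containment_failures and not rep.fraction_violations


def test_verify_detects_injected_faults(grid, cells_r3):
    cells = cells_r3
    pset = dissolve(ClassedPolygonSet([("sp", sq(-30, -10, 25))]))
    recs = intersect(cells, pset)
    # duplicated record inflates the class total
    doubled = recs + [recs[0]]
    rep = verify(doubled, cells, pset)
    _, _, err = rep.conservation["sp"]
    assert err == pytest.approx(recs[0].area_km2 / pset.class_areas_km2["sp"],
                                rel=1e-6)
    assert not rep.passed
    # displaced piece fails containment
    import shapely.affinity
    bad = IntersectionRecord(recs[0].hid, "sp", recs[0].area_km2,
                             recs[0].fraction,
                             shapely.affinity.translate(recs[0].geometry,
                                                        xoff=30.0))
    rep2 = verify(recs + [bad], cells, pset)
    assert any(reason == "not contained"
               for _, _, reason in rep2.containment_failures)


def test_records_to_fractions_shape():
    recs = [IntersectionRecord(5, "a", 10.0, 0.1),
            IntersectionRecord(5, "b", 20.0, 0.2),
            IntersectionRecord(9, "a", 5.0, 0.05)]
    wide = records_to_fractions(recs, legend=["a", "b", "c"])
    assert list(wide.columns) == ["a", "b", "c"]
    assert wide.loc[5, "b"] == 0.2 and wide.loc[9, "c"] == 0.0


# ----------------------------------------------------------------------
def test_cross_resolution_index_superset(grid, cells_r3):
    pset = dissolve(ClassedPolygonSet([("sp", sq(-20, 0, 18))]))
    coarse = intersect(cell_polygons(2, grid=grid), pset)
    cand = cross_resolution_index(coarse, 2, 3, grid)
    exact = {r.hid for r in intersect(cells_r3, pset)}
    assert exact <= set(cand.tolist())


def test_cross_resolution_index_edge_cases(grid):
    assert len(cross_resolution_index([], 2, 3, grid)) == 0
    with pytest.raises(ValueError):
        cross_resolution_index([], 2, 4, grid)
    globe = [IntersectionRecord(h, 1, 1.0, 0.5)
             for h in range(1, cell_count(1) + 1)]
    cand = cross_resolution_index(globe, 1, 2, grid)
    assert len(cand) == cell_count(2)


# ----------------------------------------------------------------------
def test_geojson_round_trip(tmp_path):
    pset = ClassedPolygonSet([("sp1", sq(0, 0, 5)),
                              ("sp2", MultiPolygon([sq(10, 0, 2),
                                                    sq(14, 0, 2)]))])
    pset = dissolve(pset)
    path = tmp_path / "r.geojson"
    write_geojson(pset, path)
    back = read_geojson(path)
    assert sorted(lbl for lbl, _ in back.polygons) == ["sp1", "sp2"]
    g1 = dict(pset.polygons)["sp2"]
    g2 = dict(back.polygons)["sp2"]
    assert g1.equals(g2)
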