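"""Projection-distortion and niche-comparison analyses.

Equal-angle (plate-carree) raster pixels shrink with latitude, so
statistics computed over raw pixels over-represent high-latitude
conditions relative to statistics computed over equal-area grid cells.
This module quantifies that areal-unit bias: a per-cell area-distortion
profile, species ranking by the spread of distortion across each range,
and the pixel-based versus cell-based comparison of bioclimatic niche
medians, plus the centroid-versus-mode correspondence rate for
categorical themes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geodesy
from .grid import ISEA3HGrid

__all__ = [
    "SpeciesPresence", "DistortionSummary", "NicheComparison",
    "distortion_profile", "presence_from_fractions",
    "distortion_percentile_rank", "niche_median_comparison",
    "correspondence_rate", "expected_pixel_load", "pixel_count_statistics",
]


@dataclass
class SpeciesPresence:
    """Cells in which a species is present (fraction >= threshold)."""
    species: str
    hids: np.ndarray
    threshold: float = 0.5


@dataclass
class DistortionSummary:
    """Distortion percentiles of one species' occupied cells.

    ``percentiles`` holds Q0..Q100 in steps of 10; the Q10-Q90 range is
    the ranking key of the species selection procedure.
    """
    species: str
    cell_count: int
    percentiles: np.ndarray

    @property
    def q10(self):
        return self.percentiles[1]

    @property
    def q50(self):
        return self.percentiles[5]

    @property
    def q90(self):
        return self.percentiles[9]

    @property
    def q10_q90_range(self):
        return self.q90 - self.q10


@dataclass
class NicheComparison:
    """Pixel-based vs cell-based medians per variable.

    ``difference = pixel_median - cell_median``: negative values mean the
    pixel-based median is colder/drier than the equal-area one.
    """
    species: str
    pixel_median: pd.Series
    cell_median: pd.Series

    @property
    def difference(self) -> pd.Series:
        return self.pixel_median - self.cell_median


# ----------------------------------------------------------------------
def distortion_profile(hids, resolution: int,
                       grid: ISEA3HGrid | None = None,
                       radius_deg: float = 0.25,
                       ell: geodesy.EllipsoidSpec = geodesy.AUTHALIC_SPHERE
                       ) -> pd.Series:
    """Per-cell area-distortion fraction at each cell centroid.

    A plate-carree circle of ``radius_deg`` is drawn at each centroid
    latitude; its geodesic area over the equatorial reference circle's is
    the distortion fraction (1 at the equator, near 0 at the poles).
    Since the measure depends on latitude alone, distinct latitudes are
    evaluated once and broadcast.
    """
    grid = grid or ISEA3HGrid()
    hids = np.asarray(hids, dtype=np.int64)
    lat, _ = grid.centroid(hids, resolution)
    lat_r = np.round(lat, 6)
    uniq, inv = np.unique(lat_r, return_inverse=True)
    vals = geodesy.area_distortion(uniq, radius_deg, ell)
    return pd.Series(np.asarray(vals)[inv],
                     index=pd.Index(hids, name="HID"), name="distortion")


def presence_from_fractions(fractions: pd.Series, species: str = "",
                            threshold: float = 0.5) -> SpeciesPresence:
    """Cells whose range fraction is >= the presence threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    f = fractions.dropna()
    hids = f.index.to_numpy(dtype=np.int64)[f.to_numpy() >= threshold]
    return SpeciesPresence(species, np.unique(hids), threshold)


def distortion_percentile_rank(presences, profile: pd.Series,
                               interpolation: str = "linear") -> list:
    """Rank species by the spread of distortion across their ranges.

    Per species, distortion percentiles 0..100 by 10 are computed over
    the occupied cells (linear interpolation between order statistics by
    default) and species are sorted by descending Q10-Q90 range.
    Species with no occupied cells are excluded.
    """
    out = []
    for p in presences:
        if len(p.hids) == 0:
            continue
        vals = profile.loc[p.hids].to_numpy()
        q = np.percentile(vals, np.arange(0, 101, 10), method=interpolation)
        out.append(DistortionSummary(p.species, len(p.hids), q))
    out.sort(key=lambda s: -s.q10_q90_range)
    return out


# ----------------------------------------------------------------------
def niche_median_comparison(species: str,
                            pixel_values: pd.DataFrame,
                            cell_values: pd.DataFrame) -> NicheComparison:
    """Compare variable medians under the two sampling schemes.

    ``pixel_values``: one row per raster pixel whose centroid falls in
    the species range (deliberately unweighted -- that equal-angle pixel
    sample is the baseline bias being measured).  ``cell_values``: one
    row per occupied equal-area cell (centroid sampling).  Columns are
    the variables.
    """
    if len(cell_values) == 0 or len(pixel_values) == 0:
        raise ValueError("empty presence sample")
    return NicheComparison(species,
                           pixel_values.median(), cell_values.median())


def correspondence_rate(centroid_col: pd.Series, mode_col: pd.Series,
                        groups: pd.Series | None = None,
                        null_values=(-1, -100)) -> pd.Series:
    """Percent of cells whose centroid class equals their mode class.

    Cells flagged null in either column are excluded from denominators.
    Returns per-group rates (if ``groups`` given) plus a ``Global`` row,
    in percent.
    """
    df = pd.DataFrame({"c": centroid_col, "m": mode_col}).dropna()
    for nv in null_values:
        df = df[(df["c"] != nv) & (df["m"] != nv)]
    match = (df["c"] == df["m"])
    out = {}
    if groups is not None:
        g = groups.reindex(df.index)
        for name, sub in match.groupby(g):
            out[name] = 100.0 * sub.mean() if len(sub) else math.nan
    out["Global"] = 100.0 * match.mean() if len(match) else math.nan
    return pd.Series(out, name="correspondence_pct")


def pixel_count_statistics(resolution: int = 9, pixels_per_degree: int = 120,
                           grid: ISEA3HGrid | None = None,
                           rows_per_chunk: int = 24) -> dict:
    """Assign the global equal-angle pixel lattice to cells and tally.

    Builds the ``(360 * ppd) x (180 * ppd)`` lattice of pixel centroids
    (30 arc-seconds for the default 120 per degree), locates every
    centroid at the requested resolution in latitude-row chunks, and
    returns per-cell counts plus the summary numbers of interest: the
    minimum and median over hexagonal cells (the twelve pentagons, with
    5/6 the area, are tallied separately) and the median over all cells.
    """
    from .grid import cell_count as _cc
    grid = grid or ISEA3HGrid()
    try:
        from ._fastlocate import locate_bulk as _locate
    except ImportError:                              # pragma: no cover
        def _locate(g, la, lo, r):
            return g.locate(la, lo, r)
    N = _cc(resolution, grid.spec)
    nlat = 180 * pixels_per_degree
    nlon = 360 * pixels_per_degree
    lons = -180.0 + (np.arange(nlon) + 0.5) * (360.0 / nlon)
    counts = np.zeros(N + 1, dtype=np.int64)
    for i0 in range(0, nlat, rows_per_chunk):
        i1 = min(i0 + rows_per_chunk, nlat)
        lats = -90.0 + (np.arange(i0, i1) + 0.5) * (180.0 / nlat)
        h = _locate(grid, np.repeat(lats, nlon), np.tile(lons, i1 - i0),
                    resolution)
        counts += np.bincount(h, minlength=N + 1)
    counts = counts[1:]
    hex_counts = counts[12:]
    return {
        "counts": counts,
        "min_hexagon": int(hex_counts.min()),
        "median_hexagon": float(np.median(hex_counts)),
        "median_all": float(np.median(counts)),
        "min_all": int(counts.min()),
        "pentagon_counts": counts[:12].copy(),
    }


def expected_pixel_load(resolution: int, pixel_side_m: float = 463.31257,
                        grid: ISEA3HGrid | None = None,
                        round_to: int = 10) -> int:
    """Expected equal-area pixels per hexagonal cell.

    Cell area divided by the square pixel area of a sinusoidal product
    (default: the 463.31 m MODIS land grid), rounded to the nearest
    ``round_to`` -- about 12,070 pixels per resolution-9 cell.
    """
    grid = grid or ISEA3HGrid()
    cell = grid.cell_area_km2(resolution) * 1e6        # m^2
    n = cell / pixel_side_m ** 2
    return int(round(n / round_to) * round_to)
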