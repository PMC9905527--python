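# hexeco

**hexeco** builds the Icosahedral Snyder Equal Area aperture-3 hexagonal
(ISEA3H) discrete global grid and resamples raster and vector geodata into
its equal-area cells. It is written for macroecologists and data engineers
who assemble training tables for species distribution models (SDMs) and
ecometric models: such models need *equivalent observational units*, and
the equal-angle raster pixels most global datasets ship with are not —
a 30 arc-second WGS84 pixel covers ≈ 0.85 km² at the equator and nearly
nothing near the poles, so raw-pixel statistics systematically
over-represent high-latitude conditions.

## The grid and the statistics

The toolkit implements, from first principles:

- **The ISEA projection** (Snyder's equal-area map onto the icosahedron's
  20 faces), forward and inverse, exact to machine precision, oriented by
  default with a vertex at 58.28252559° N, 11.25° E (the de-facto standard
  DGGS orientation, which this package reproduces numerically).
- **ISEA3H addressing** at resolutions 0–12: at resolution *r* the sphere
  is tiled by `N(r) = 10·3^r + 2` cells — `N − 12` hexagons of area
  `A = 4πR²/(10·3^r)` on the authalic sphere (R = 6371.0071809 km) and 12
  pentagons of area `5A/6` centered on the icosahedron vertices, so
  `12·(5A/6) + (N−12)·A = 4πR²` exactly. Cells carry sequential integer
  HIDs (the database primary key), support O(1) point location
  (vectorized and numba-compiled), neighbor queries, and exact boundary
  polygons (cell corners are resolution-`r+1` cell centers, an
  aperture-3 identity).
- **Summary statistics** per cell: `centroid` (point sample),
  `fraction` (per-class share of cell area), `mode` (dominant class,
  subject to a 0.2 total-coverage threshold), and the area-weighted
  `mean`  x̄ = Σwᵢxᵢ / Σwᵢ  with wᵢ the geodesic pixel area — reducing
  to the simple mean on equal-area grids.
- **Vector overlay** with shapely: dissolve → OGC validity check →
  cell-polygon intersection in the dataset's native CRS → per-(cell,
  class) geodesic-area fractions, with three integrity checks
  (containment, per-class area conservation to 1e-6, fraction ≤ 1).
- **Geodesy**: closed-form ellipsoidal polygon/pixel areas (Green's
  theorem with plate-carrée edges), geodesic IDW interpolation, and the
  plate-carrée-circle area-distortion metric (≈ cos lat).
- **The tabular product**: HID-keyed, tab-delimited files under the
  `ISEA3H<RR>/<Dataset>_V<Version>/ISEA3H<RR>_..._<Theme>_<Stat>.txt`
  convention, with per-theme null codes, joins on HID, the derived
  *Terra* fraction, and a layout linter.
- **Bias analysis**: per-cell distortion profiles, species ranking by the
  Q10–Q90 distortion spread of their ranges, pixel-vs-cell niche-median
  comparison, and centroid-vs-mode correspondence rates.

Everything is testable offline: `hexeco.fixtures` generates seeded
WorldClim-like climate fields, MODIS-like categorical cover, and
IUCN-like sparse-vertex range polygons.

## A worked example

```sh
python examples/01_grid_basics.py
```

```
res     cells      area km2   spacing km
  5      2432    209903.55     452.5
  6      7292     69967.85     261.2
  7     21872     23322.62     150.8
  8     65612      7774.21      87.1
  9    196832      2591.40      50.3
 10    590492       863.80      29.0

(60.17, 24.94) falls in resolution-9 cell HID 45078
its centroid sits at (60.0742, 24.8875)
it touches 6 neighbors: [45187, 45186, 341, 37409, 342, 45079]
corner ring has 6 vertices (pentagon: False), area 2591.4 km2
```

Every resolution-9 cell covers 2 591.4 km²; the ~50 km centroid spacing
matches the point grids traditionally used for ecometric model training.
`examples/04_areal_unit_bias.py` shows why the equal-area cells matter:

```
pixel-based median T: 24.57 C
cell-based  median T: 26.66 C
difference (pixel - cell): -2.09 C
```

For a synthetic wide-latitude species on a 30·cos(lat) temperature
field, the raw-pixel median is 2.1 °C colder than the equal-area cell
median — the same cold bias the equal-area resampling removes in real
bioclimatic tables. The other examples demonstrate raster sampling
(`02`) and the vector range workflow with its verification report
(`03`); the `hexeco` command-line tool wraps the same library calls
(`hexeco grid-info --resolution 9`, `hexeco sample-raster ...`,
`hexeco lint-db ...`).

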