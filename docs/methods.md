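# Methods

This note documents the models, algorithms, numerical choices and known
limitations of hexeco. It states how quantities are computed; every
empirical number it mentions is produced by the test suite or the
acceptance script.

## The equal-area projection

The grid rests on Snyder's equal-area projection for polyhedral globes,
specialized to the icosahedron. For a point at spherical distance *z*
and azimuth *Az* from a face center, the azimuth is folded into a 60°
sector using the face's sixfold symmetry and mapped through the
spherical-triangle relations

    H   = arccos(sin Az · sin 36° · cos g − cos Az · cos 36°)
    A_G = Az + 36° + H − 180°                       (spherical excess)
    Az′ = atan2(2 A_G, R′² tan² g − 2 A_G cot 30°)  (planar azimuth)
    q   = atan2(tan g, cos Az + sin Az cot 30°)     (distance to the edge)
    ρ   = 2 R′ · [d′/(2 R′ sin(q/2))] · sin(z/2)

where *g* is the arc from a face center to a vertex and *d′* the planar
distance to the face edge along *Az′*. Both constants are **derived at
construction time from the icosahedron itself** rather than copied from
tables: *g* = 37.37736814° falls out of the vertex geometry, and the
scale R′ = 0.9103832815 (in sphere radii) is fixed by requiring the 20
planar triangles to cover exactly 4π. The inverse solves the excess
equation for *Az* by Newton iteration (quadratic convergence, 12
iteration cap, seeded at *Az′*).

Properties verified by the suite: forward∘inverse round trips are at
machine precision (≤ 5·10⁻¹⁵ rad; the acceptance bound is 10⁻⁹), and
the numerical Jacobian |∂(x,y)/∂(λ,φ)| equals cos φ to 5·10⁻⁶
everywhere, which is the equal-area property in differential form. A
Monte-Carlo sampling check (uniform cap points stay uniform in the
plane) confirms the same at its statistical resolution (~2%); point
counting cannot reach the 10⁻⁶ level, which is why the Jacobian test
carries that tolerance.

### Orientation

The icosahedron orientation is configurable (`GridSpec`): a designated
vertex position plus the azimuth toward one neighbor vertex. The default
— vertex at 58.28252559° N, 11.25° E, azimuth 0 — is the de-facto
standard of reference DGGS software; it is symmetric about the equator
and places four vertices (hence four pentagons) exactly on it.
Reorienting by ψ about the vertex axis changes neighbor azimuths exactly
linearly, which the constructor exploits to calibrate ψ; when the vertex
sits on a geographic pole the azimuth itself is degenerate and the
calibration uses the continuous limit from a slightly tilted proxy.

## ISEA3H addressing

At resolution *r*, cell centers form a triangular lattice of spacing
`L/3^(r/2)` on each planar face (side *L*): aligned with the face edges
at even *r* (class I), rotated 30° at odd *r* (class II). Face corners
are lattice points in both classes, so the twelve icosahedron vertices
carry (pentagonal) cells at every resolution. The lattice is
mirror-symmetric about every face edge, so adjacent faces' lattices
agree on the unfolded plane; cells are the planar Voronoi (hexagon)
regions of the lattice, and cells straddling a face edge are regular
hexagons in the unfolded pair of faces. Pentagons arise at vertices
where only 300° of plane surrounds the point: five 60° hexagon wedges,
hence exactly 5/6 of the hexagon area.

**Point location** projects a point to its face (nearest face center;
ties within 10⁻¹² of the maximum dot product — i.e. points on shared
edges or vertices — resolve to the lowest face id), quantizes in lattice
coordinates by hex (cube) rounding, and, if the rounded lattice point
lies beyond a face edge, maps it into the adjacent face through a
precomputed planar unfold isometry. Two implementations exist — a
vectorized numpy path and a numba-compiled per-point kernel for bulk
workloads — and the suite asserts their agreement; points lying exactly
on a cell boundary (the orientation's symmetry meridian intersects
regular pixel lattices) may tie either way at the last floating-point
ulp, which is immaterial because both candidate cells are equidistant.

**HID ordering.** Cells are numbered 1..N per resolution: pentagons
1–12 in vertex order, then icosahedron-edge cells (edge-major, 30
edges in sorted vertex-pair order, positions running from the
lower-numbered vertex), then face-interior cells (face-major,
row-major in lattice coordinates). The ordering is deterministic and
stable across runs; no computed statistic depends on it.

**Cell geometry.** The aperture-3 interleaving identity — the
resolution-`r+1` lattice is exactly the resolution-`r` centers plus the
resolution-`r` hexagon corners — gives exact cell corners as inverse
projections of `r+1` lattice points. Boundary edges are straight in the
unfolded face plane; they are densified there (default 50 points per
edge) and inverse-projected, with out-of-face points folded into the
adjacent face. At that default the geodesic ring area of a resolution-9
cell matches the theoretical cell area to better than 10⁻⁴ relative
(the acceptance bound); coarse cells (r ≤ 2) have much longer, more
curved edges and need ~100–200 points per edge for the same relative
fidelity — the partition tests use exactly that.

**Neighbors** are the six (five at pentagons) unit lattice steps, with
the same unfold maps across faces; corners and neighbors are exact, not
search-based.

**Nominal spacing.** The conventional per-resolution "centroid spacing"
reported by grid tables is the icosahedron edge arc divided by
`3^(r/2)` — the spacing measured where the projection is most
compressed (50.3 km at r = 9). The planar lattice spacing
`sqrt(2A/√3)` is ≈ 9% larger, and the measured mean spherical
nearest-neighbor spacing lies between the two; the tables' convention
is reproduced by `centroid_spacing_km` and treated as descriptive.

## Geodesic measurement

Polygon areas use Green's theorem on the ellipsoid: the area element
integrates in closed form over latitude,

    q(φ) = (b²/2) [ sin φ / (1 − e² sin²φ) + atanh(e sin φ)/e ],

so the enclosed area is ∮ q dλ along the ring. Edges are interpreted as
**straight lines in plate-carrée (λ, φ) space** — the same rule the
vector workflow applies to source polygons, on the principle that a
dataset's arcs are as drawn in its native CRS — and each edge integral
is evaluated by 8-point Gauss–Legendre quadrature on ≤ 1° subsegments
(near machine precision; the 1°×1° quadrangle agrees with an
independent numerical surface integral to 10⁻⁹). Listed edges are
literal (a ring that sweeps 360° of longitude encircles a pole; the
winding number triggers the pole correction, and of the two
complementary regions the smaller is returned); only the implicit
closing edge wraps the short way. Vertices exactly on a pole are split
so both adjacent edges become meridional. Geographic pixel areas reduce
to the exact closed form `Δλ · (q(φ₂) − q(φ₁))`; a 30 arc-second pixel
at the equator measures 0.8548 km² on WGS84.

The grid itself lives on the authalic sphere (R = 6371.0071809 km, the
sphere with the WGS84 surface area) — that is what makes the published
cell areas exact — while measurement operations default to WGS84. The
two differ locally by up to ±0.45% in area density, which is why
equal-area assertions about *cells* are evaluated on the sphere.

**Area distortion** is measured as in the validation analysis: a small
circle drawn in degree space (default radius 0.25°, 360 vertices) at a
given latitude, its geodesic area divided by the same circle's area at
the equator. On the sphere this equals cos φ up to O(radius²) (within
1% for |φ| ≤ 85°, and invariant to radius over 0.1°–1° within 0.5%);
on WGS84 an extra (1 − e² sin²φ)⁻² factor raises it by up to +1.34%
at 85°. The distortion profile therefore defaults to the sphere, with
the ellipsoid selectable.

**IDW** interpolation uses great-circle distances on the authalic
sphere (k-nearest via a 3-D KD-tree on chord length, which is monotone
in arc length), weight d⁻ᵖ with defaults p = 2, k = 4, and an
exact-hit rule at d = 0.

## Sampling statistics

Pixels are atomic: each is assigned wholly to the cell containing its
centroid. Class weights are pixel counts on authalic grids and geodesic
pixel areas otherwise; all aggregates (contingency tables, weighted
sums) are additive, so tiled inputs merge associatively in any order —
asserted bit-for-bit against a monolithic run.

The `fraction` denominator is the **theoretical cell area** (5/6 for
pentagons), not the sum of assigned pixel weights, so land-clipped
sources yield partial coverage and the 0.2 `mode` threshold and the
summed-fraction "total cover" are meaningful. Consequence of atomic
pixels: per-cell totals fluctuate around 1 by a boundary term that
grows with the pixel:cell size ratio (measured ~0.5% for 0.1° pixels in
resolution-5 cells, ~0.2% for 30″ pixels at resolution 9); totals above
1 + 2% raise an integrity error, and vector-derived fractions — exact
geometry — keep a strict 1 + 10⁻⁹ bound. `mode` ties break to the
class earliest in legend order; cells below the coverage threshold,
wholly-nodata cells, and centroids over nodata receive per-theme null
codes (defaults −1000 / −100 / −1 following the published conventions).

The global pixel-load statistic assigns all 43 200 × 21 600 30″ pixel
centroids to resolution-9 cells: hexagonal cells receive a minimum of
2978 and a median of 3485 centroids (pentagons, with 5/6 the area, get
2512 at the equator, 2952 at ±31.7°, 4780 at ±58.3°). The expected
load of 463.31 m equal-area pixels is cell area / pixel area ≈ 12 070.

## Vector workflow

Dissolve (per class or global) → validity check against the OGC
simple-feature rules (single-pass repair via `make_valid`, every repair
flagged; unrepairable geometries excluded with a flag) → cell polygons
in the source CRS → shapely intersection (STRtree-indexed) → geodesic
piece areas and fractions. Cell polygons are analytic (densified true
boundaries) by default; a `pixel_staircase` mode polygonizes an HID
raster at a chosen pixel size for fidelity comparisons and agrees with
the analytic areas within 0.5% at 30″ pixels. The verification step
checks piece-in-cell containment (1e-9° buffer for shared boundaries,
≥ 4 ring coordinates), per-class area conservation (1e-6 relative —
exact in practice), and fraction ≤ 1. A prior intersection at an
adjacent resolution can serve as a spatial index: candidate cells are
those whose centroids fall in retained cells, expanded by one neighbor
ring, which is provably a superset of the coincident set.

## Synthetic fixtures

The generators emulate the *structure* of the source data, not its
spatial covariance: WGS84 grids with a zonal cosine law (T = a·cos φ,
default a = 30 °C — a realistic equator-to-pole span) plus optional
seeded Gaussian noise (default σ = 0 so closed-form checks are exact)
and optional row-band nodata clipping; categorical cover as seeded
Voronoi patches around uniform sphere nuclei (patch scale set by the
nucleus count) or i.i.d. mixtures; and latitude-band range polygons
with sparse vertices, optionally fragmented into longitude slices.
Everything is a pure function of (seed, config). Passing tests
demonstrate the machinery is correct on fields whose truth is known in
closed form; they do not certify behavior on real data's anisotropic
covariance, missing-data patterns, or datum quirks.

## Sizes and determinism

Default problem sizes keep the full suite at a few minutes on one CPU:
exhaustive grid checks at resolutions ≤ 5, sampled checks (10⁴–10⁵
points, 200 cells) at resolution 9, the global 30″ pixel-load
computation in 24-row chunks, and the bias sign test on 20 seeded
species at resolution 5. All randomness flows from explicit seeds;
summary tables use fixed decimal formatting (fractions 6 dp, means
4 dp, integral values verbatim) so reruns are byte-identical.

## Known limitations

- Apertures other than 3, non-hexagonal variants, and resolutions
  beyond 12 are out of scope.
- The CRS registry covers geographic and sphere-based sinusoidal
  systems only — the two families the emulated sources use; raster I/O
  is the plain-text ESRI ASCII grid with a JSON sidecar.
- Plate-carrée edge semantics require rings to be supplied unwrapped
  (or split) across the antimeridian; cell exports do this splitting
  automatically.
- Vector line and point themes are not handled; geometry repair is
  single-pass.
- Spherical nearest-centroid assignment is not exact: cells are
  *planar* Voronoi regions, and the projection's scale anisotropy lets
  a small fraction of near-boundary points (~3% at resolution 6) lie
  spherically nearer a neighbor's centroid, bounded well within a 1.25
  distance ratio.
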