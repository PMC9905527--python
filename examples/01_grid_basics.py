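"""Construct the ISEA3H grid and inspect cells.

Builds the default-orientation grid, prints the specification table for
the commonly used resolutions, locates a point, and walks a cell's
neighborhood.  Cell counts follow 10*3^r + 2; areas are exact equal-area
shares of the authalic sphere; spacing is the conventional
along-icosahedron-edge measure.
"""

import numpy as np

from hexeco import ISEA3HGrid, cell_area_km2, cell_count, centroid_spacing_km

grid = ISEA3HGrid()

print("res     cells      area km2   spacing km")
for r in range(5, 11):
    print(f"{r:3d} {cell_count(r):9d} {cell_area_km2(r):12.2f} "
          f"{centroid_spacing_km(r):9.1f}")

# where is Helsinki?
lat, lon = 60.17, 24.94
hid = grid.locate(lat, lon, 9)
clat, clon = grid.centroid(hid, 9)
print(f"\n({lat}, {lon}) falls in resolution-9 cell HID {hid}")
print(f"its centroid sits at ({clat:.4f}, {clon:.4f})")

nbrs = grid.neighbors(int(hid), 9)
print(f"it touches {len(nbrs)} neighbors: {nbrs.tolist()}")

geom = grid.cell_geometry(int(hid), 9, densify_per_edge=0)
print(f"corner ring has {len(geom.boundary) - 1} vertices "
      f"(pentagon: {geom.is_pentagon}), area {geom.area_km2:.1f} km2")
# every cell of a resolution has this same area: that is the point of
# the equal-area grid -- cells are directly comparable observation units
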