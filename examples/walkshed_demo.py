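"""Golden-window walkshed of a single arrest location.

Snaps the point to the walking network, spends the snap offset, then walks
outward for the remaining budget (3 min at 1.5 m/s = 270 m), including
partial edges.  The result is a corridor polygon around every reachable road
segment — a drawable stand-in for a map-service isochrone.
"""

import numpy as np

from aed_golden import CityConfig, WalkWindow, generate_city, walkshed

city = generate_city(CityConfig(seed=7))
origin = city.event_xy[0]
window = WalkWindow()

shed = walkshed(origin, city.graph, window)
disk_bound = np.pi * window.budget ** 2
print(f"origin: ({origin[0]:.0f}, {origin[1]:.0f}) m")
print(f"route budget: {window.budget:.0f} m")
print(f"walkshed area: {shed.area / 1e6:.4f} km^2")
print(f"straight-line disk bound: {disk_bound / 1e6:.4f} km^2")
print(f"area ratio: {shed.area / disk_bound:.2f} "
      "(the network-constrained region is a fraction of the free-space disk)")

import shapely

inside = shapely.contains(shed, shapely.points(city.device_xy)).sum()
print(f"devices inside the walkshed corridor: {inside}")
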