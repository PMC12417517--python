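# Methods

## The model

The unit of analysis is a city: a set of arrest locations (demand), a set of
device locations (supply), a walking network, and a region polygon. All
geometry is planar, in metres east/north of a reference point, obtained from
longitude/latitude by a local equirectangular projection
`x = R cos(φ₀)(λ−λ₀)π/180`, `y = R(φ−φ₀)π/180`. Over the ~10 km urban-core
footprint the model targets, the projected-distance error against the
great-circle distance is below 0.1 %; geodesic ellipsoid math would add
nothing at this scale. Datum offsets of the originating map services are
ignored: all inputs to one analysis must share a coordinate system, and
distances are then internally consistent.

Three constructs sit on top:

* **Distance summaries.** Seven-number summaries (min, quartiles, max, mean,
  SD) of (a) spacing between each device and its nearest other device and
  (b) distance from each case to its nearest device. Duplicate coordinates
  are never deduplicated — real inventories register several devices at one
  address, and the zero lower quartile of the spacing distribution is
  informative, not an artefact.
* **Benefit profile.** For a radius grid (default 100 m to 450 m in 20 m
  steps; deployment beyond 450 m is not recommended even in complex
  terrain), `avg(r)` = mean devices within `r` of a case and `pct(r)` =
  percent of cases with ≥ 1 device within `r`. "Within" is closed (`≤ r`),
  so a co-located device covers its case at every radius. Both rows are
  nondecreasing and `avg ≥ pct/100` identically. The profile exists in a
  straight-line and a walking-route metric.
* **Target state and radius search.** The deployment target is
  `(avg, pct) = (1, 40 %)`: one device per case on average (economic
  efficiency) at the coverage proportion of developed East Asian cities.
  The score of a profile point is
  `J = w₁((avg−1)/1)² + w₂((pct−40)/40)²` with default equal weights — a
  dimensionless, symmetric-in-relative-error distance chosen here because
  the source analyses eyeball "closest to optimal" without stating a
  functional form. `J` is enumerated on the profile grid; ties break toward
  the smaller (cheaper) radius, and the band of radii within 5 % of the best
  score is reported alongside the argmin, since a deployment recommendation
  is a band, not a point. On the published coarse grid (50 m columns) the
  argmin is 300 m (`J = 0.0364` vs `0.1155` at 250 m); the 270–280 m
  optimum reported for the real city came from a finer 20 m grid that was
  not published, and is bracketed by those two columns.

## Walking routes and walksheds

The network is an undirected graph with node coordinates and edge lengths
(every length ≥ the straight line between its endpoints). Off-graph points
snap to the nearest *node*; the straight-line snap offset is added to every
route from that point. Node snapping (rather than projecting into edge
interiors) keeps the routing simple and its error bounded by the local node
spacing — which is why the synthetic generator builds a dense pedestrian
grid (50 m default spacing). Route distance is snap offset + Dijkstra
shortest path + snap offset; by the triangle inequality it never falls below
the straight-line distance, so straight-line coverage always dominates
route coverage at equal budget. Unreachable pairs are returned as `inf`,
counted, and logged — never dropped silently; downstream summaries exclude
them and report the exclusion count.

The walk window defaults to 180 s at 1.5 m/s (270 m budget). No walking
speed is canonical — published isochrones come from proprietary routers —
so the speed is a configuration knob; 1.5 m/s makes the 3-minute budget
coincide with the 270 m deployment scale. A walkshed is the union of
5 m-buffered reachable sub-edges (with interpolated cut points on partially
reachable edges): a drawable, area-computable stand-in for a map-service
isochrone. If the budget does not survive the snap offset the walkshed
degenerates to a point, with a warning.

## The synthetic city

The generator's role is to reproduce the *statistical structure* that makes
the method's conclusions non-trivial, not any particular city's map:

* **Walking network**: a jittered square grid (50 m spacing, 8 m jitter)
  clipped to the region, with each cell diagonal present independently with
  probability 0.7, standing in for the alleys and mid-block cut-throughs
  that pedestrian routers exploit. The resulting shortest-path detour over
  straight-line distance is ~1.05 (median); with snap offsets included, the
  median route/straight ratio over case-to-nearest-device pairs is ~1.2,
  within the [1.0, 1.3] band that brackets the modest detours observed for
  real walking routes.
* **Devices**: a cluster process — 60 uniform cluster centres with Gaussian
  offspring (sd 60 m) for 70 % of base devices, the remaining 30 % as
  isolated singletons (uniform background), plus 15 % exact co-located
  duplicates appended last. The mix is what produces the observed
  heavy-tailed spacing law: zero lower quartile (duplicates), small median
  (tight clusters), mean ≫ median with SD > mean (isolated devices). On a
  10 km square, multi-offspring clusters alone cannot produce that regime —
  the singleton fraction is essential. Median/mean spacing ratio at the
  defaults: ≈ 0.36. When the offspring sd is set at or above the region
  diameter the generator draws positions uniformly — the truncated-Gaussian
  offspring law is flat at that scale, and the direct draw makes the
  Poisson special case exact (nearest-neighbour distances then follow
  `1 − exp(−λπr²)`, verified by Kolmogorov–Smirnov).
* **Events**: location types drawn from a community-dominated mixture
  (78.4 % community; devices only 28.4 %), scattered (sd 300 m) around
  per-type uniform anchor points. The type mismatch plus the independence
  of event and device clustering yields overdispersed per-case device
  counts, which is exactly why the `(1, 40 %)` target is approachable:
  under Poisson placement the radius with `avg = 1` forces
  `pct = 100(1−1/e) ≈ 63.2 %`, and only clustered placement pushes coverage
  at that radius below it.
* **Scale**: 1,350 events and 1,238 devices on a 10 km × 10 km core,
  with a 3.2 M resident count used only for per-capita reporting. Event
  timestamps are uniform over 2021–2023; device availability defaults to
  06:00–19:00 daily. Availability filtering is *off* in the default
  pipeline (the headline tables ignore time-of-day); the filter exists for
  night-time sensitivity analyses.

What the generator does **not** emulate: real street topology (rivers,
arterials, gated superblocks), incidence dynamics over time, survival
outcomes, socioeconomic gradients, multi-floor vertical distance, or any
particular city's absolute distance scale. Passing tests therefore
demonstrate correctness of the machinery and of the structural claims
(clustering necessity, route dominance, spacing regime), not agreement with
any specific city's printed distance tables.

## Placement experiment

Point 1 is a chosen origin device. Each subsequent point is drawn
area-uniformly from the annulus [250 m, 300 m] around an existing point
chosen uniformly (branching growth, not a line — "a neighbouring point"
does not mean "the previous point"), rejected if outside the region or
within 250 m of any existing point. The published description states only
the upper constraint (every point has a neighbour within the optimal
distance); a lower separation is implied, because without one the
"improved" placement could collapse into the same stacked-disk pattern it
is meant to fix — the deployment band's own lower edge (250 m) is used.
The result satisfies: every point's nearest neighbour lies in [250, 300] m,
re-verified by an independent brute-force pass, never by the sampler's own
bookkeeping. The baseline is the `n` devices nearest the origin by
straight-line distance. Coverage is the polygon union of 270 m disks
(64-segment polygonal approximation, ~0.16 % area deficit; an independent
grid-counting oracle agrees within 1 %), clipped to the region; the outcome
reports both areas in km² (2 decimals), the relative improvement, and —
when events are supplied — the coverage percentage change.

## Numerical choices and degenerate inputs

* Quartiles use linear interpolation; SD is sample (n−1) by default with a
  population option. Single-value vectors are legal in population mode.
* Availability windows are inclusive at both ends; unparseable times raise
  an error naming the record.
* Empty point sets, non-increasing radius grids, non-positive radii,
  single-point nearest-neighbour queries, and zero-area regions are
  rejected with explicit errors rather than returning empty results.
* Malformed input rows are collected with line numbers; a read aborts if
  more than 1 % of rows are malformed.
* Route-metric profiles use one truncated single-source Dijkstra per event
  rather than a full distance matrix; results are identical where both are
  defined.
* All randomness flows from a single root seed via spawned child streams,
  so identical seeds give byte-identical artifacts and individual stages
  can be re-run independently.

## Problem sizes

The test suite and the acceptance script run the full-scale synthetic city
(1,350 × 1,238 on the 50 m grid, ≈ 40k nodes) where the claim depends on
scale (spacing regime, clustering necessity, route ratios), and compact
cities (~3 km, 100–200 points) for routing unit tests. Monte-Carlo checks
use 5 seeds (closed-form agreement), 20 seeds (placement improvement
direction), and 2,000–20,000 events for the Poisson/lattice limits —
enough for three-standard-error and 2 % tolerances respectively.

## Known limitations

* Node snapping biases route distances upward for points far from the
  network; with the default dense grid the bias is bounded by ~2 × 25 m.
* The walkshed is a corridor union, not a filled isochrone hull; its area
  is a lower bound on the reachable open space.
* The synthetic optimum radius (~140–160 m) is smaller than the 270–280 m
  scale of the real-city analyses, because the generator places devices
  closer to cases than the real inventory does; the optimizer's checks
  therefore use closed-form cities (Poisson, lattice) and the published
  table, not the synthetic optimum's absolute value.
* The equirectangular projection is inappropriate beyond ~30 km spans or
  |latitude| ≥ 85°; the constructor rejects the latter.
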