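# Methods

## Model

The package implements a floating-catchment accessibility model for
walkable elderly care. Supply is facility bed capacity Sⱼ (optionally
scaled by a per-facility quality multiplier, capacity = beds × quality,
quality defaulting to 1); demand is the elderly population Pₖ at
residential points or zone centroids. The engine is agnostic to the
aggregation level — it operates on points.

Within a catchment radius d₀, interaction is discounted by a truncated
Gaussian kernel

    f(d, d0) = (e^{-(1/2)(d/d0)²} − e^{-1/2}) / (1 − e^{-1/2})

which equals 1 at d = 0, decreases strictly, and reaches exactly 0 at
d = d₀. A dichotomous kernel (1 inside, 0 outside) is kept as the
classical baseline. Both kernels use the half-open convention [0, d₀): the
weight at exactly d₀ is 0, so the kernels always agree on catchment
membership and the Gaussian's analytic zero at the boundary is respected.

Step 1 computes each facility's supply–population ratio
Rⱼ = Sⱼ / Σₖ Pₖ f(dₖⱼ); step 2 each demand point's score
Aᵢ = Σⱼ f(dᵢⱼ) Rⱼ. The Huff extension multiplies the population terms by
choice probabilities Probᵢⱼ = Sⱼ f(dᵢⱼ) / Σₖ Sₖ f(dᵢₖ), normalized over
the facilities reachable from i, which model competition between
facilities: a resident within reach of several facilities does not load
all of them with their full population.

### The two readings of the Huff-adjusted score

The combined two-step formula, written in one line, reads

    Aᵢ = Σⱼ Probᵢⱼ f(dᵢⱼ) · Sⱼ f(dᵢⱼ) / Σₖ Pₖ f(dₖⱼ) Probₖⱼ

with the decay weight appearing twice — once inside the adjusted ratio's
numerator and once in the outer sum — while the step-1 definition of the
adjusted ratio contains it only once. Both readings are genuinely
defensible, so both are implemented behind `huff_reading`:

* `literal` (default): decay applied in both steps, exactly as the
  one-line formula composes. Total delivered access then satisfies
  Σᵢ Pᵢ Aᵢ ≤ Σ_served Sⱼ, with equality only when all in-catchment decay
  weights are 1.
* `conservative`: Aᵢ = Σⱼ Probᵢⱼ f(dᵢⱼ) Rⱼ with the Huff-adjusted Rⱼ —
  decay applied once. This satisfies the exact conservation identity
  Σᵢ Pᵢ Aᵢ = Σ_served Sⱼ (an algebraic consequence of the definitions),
  which the test suite verifies to 1e-9 relative on every synthetic city.

Supply conservation also holds exactly for the plain Gaussian variant, and
it is the decisive correctness check for the whole pipeline: any error in
the OD matrix, the kernels, or the ratio bookkeeping breaks it.

### Variants

* **A** (baseline): Euclidean distances, binary decay, no probabilities —
  the classical 2SFCA before any optimization. The engine enforces
  metric/kernel consistency (Euclidean + binary for A, network + Gaussian
  for B/C) and rejects mismatches.
* **B**: network shortest-path distances, Gaussian decay.
* **C**: network distances, Gaussian decay, Huff probabilities (either
  reading).

## Network and distances

Road centerlines become a directed graph. The direction attribute
(field name configurable, default `Directiona`) takes four values: two-way,
one-way along the digitizing direction, one-way against it, and unknown;
unknown and unrecognized values are traversed both ways (unrecognized ones
are counted in a warning). Node identity for polyline input is the
endpoint coordinate rounded to 1e-6 m. Edge length defaults to the
geometry length when no attribute is present; parallel arcs collapse to
the shortest.

OD distances are Dijkstra shortest paths run demand → facility (the
resident walks to the facility), so one-way streets are honored in that
direction; the reverse choice would differ only on asymmetric networks and
is not exposed. Only pairs within d₀ are stored; unreachable pairs are
absent, and a disconnected network is legal. Facilities and demand points
snap to the **nearest network node** (ties to the smallest node id;
entities beyond the snapping tolerance raise an error listing their ids).
Node snapping is a deliberate approximation — it keeps distances exactly
reproducible by exhaustive path enumeration, at the cost of up to roughly
half an edge length of error per endpoint; with ~200 m urban block edges
this is small relative to d₀ = 800 m.

Coordinates must be planar meters. A heuristic refuses input whose
coordinates all lie within ±360 (it is almost certainly lon/lat degrees);
`allow_geographic` overrides it for genuinely small planar extents.

## Parameters

| parameter | default | meaning |
|---|---|---|
| d₀ | 800 m | catchment radius: the neighborhood-unit walking range |
| walking speed | 0.8 m/s | elderly walking pace (time-based threshold mode) |
| walk duration | 15 min | acceptable walk; 0.8 m/s × 15 min = 720 m |
| snapping tolerance | 500 m | max point-to-node distance before erroring |
| decay kind | gaussian | `binary` reproduces the classical model |
| huff_reading | literal | see above |
| levels k | 10 | decile classification of Aᵢ |

Exactly one of d₀ / the time-based pair may be configured; unset, the
800 m default applies.

## Supporting statistics

* **Density**: elderly persons per km² per reporting zone.
* **Average nearest neighbor** (Clark–Evans): observed mean NN distance
  over expected 0.5/√(n/A), with z = (obs − exp)/(0.26136/√(n²/A)) — the
  constant follows the convention of the standard desktop-GIS tool, so
  reports are comparable with common practice. ann < 1 indicates
  clustering. Duplicate points are allowed (NN distance 0).
* **Classification**: quantile (equal-count) breaks at the i/k empirical
  quantiles, ties assigned to the lower level, all-equal input collapsing
  to level 1. Quantile breaks were chosen over Jenks or equal intervals
  because they are deterministic, scale-free and monotone; with heavily
  tied scores (many exact zeros) the populated levels can be fewer than k.
* **Variant comparison**: mean/min/max/standard deviation of Aᵢ per
  variant. The standard deviation uses the population (n) denominator,
  since the demand set is a full enumeration of reporting units, not a
  sample; at n ≈ 50+ the two conventions differ by under 1%.

## Synthetic cities

Real facility/population/road layers for a whole city are rarely
shareable, so the generator emulates their shape: a rows × cols planar
road lattice (default 15 × 15 at 200 m spacing — a 2.8 km square, i.e.
d₀ spans four blocks), a seeded fraction of one-way streets (default 0.2,
orientation random), facilities at network nodes with capacities uniform
in 20–200 beds, and demand points with elderly populations uniform in
50–500. A clustering knob in [0, 1] interpolates the facility placement
pool from the whole grid (0) down to the nodes nearest the center (1),
emulating a dense-core/sparse-periphery facility pattern (default 0.3).
All draws come from one `numpy.random.default_rng(seed)`; no global state
is touched, and identical specs produce bit-identical cities. Entities sit
exactly on nodes so snapping is exact in tests; a jitter option displaces
them by at most spacing/4 (so the placement node remains nearest) to
exercise the snapper.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: real street fabrics are incomplete and irregular,
so true walking detours (network/Euclidean ratios of 1.3–1.7+, barriers,
dead ends) are far larger than a complete lattice's bound of √2;
populations are not uniform; facility capacities correlate with location.
One consequence is worth stating plainly: on lattice cities the Gaussian
network variant does **not** produce a lower mean and standard deviation
of Aᵢ than the Euclidean binary baseline — the catchments barely shrink,
while the Gaussian kernel concentrates each facility's supply on its
nearest neighborhoods, *raising* dispersion. On real cities the dominant
effect is usually the severe shrinkage of network catchments relative to
Euclidean circles, which pulls the mean and spread down. The quantity that
is ordered by construction on any input is the population-weighted total
Σᵢ Pᵢ Aᵢ: network catchments can only lose served facilities relative to
Euclidean ones, so delivered supply under variant B never exceeds
variant A's.

The test suite runs the model ensembles on 100 seeded 8 × 8 cities
(25 demand points, 6 facilities) and verifies the shortest-path engine
against exhaustive simple-path enumeration on random directed graphs of up
to 12 nodes; `scripts/acceptance.py` uses the full default city. These
sizes were chosen because every invariant checked is size-independent
(conservation, normalization and oracle equivalence are exact identities),
so small instances prove as much as large ones.

## Numerical choices and degenerate inputs

* Facilities whose decay-weighted (and probability-weighted) catchment
  population is zero get Rⱼ = 0 and an `unserviced` flag rather than
  NaN/error — isolated facilities are a normal feature of real data, and
  reported minima of 0 stay meaningful.
* Demand points with empty catchments get Aᵢ = 0 exactly.
* Huff rows with empty catchments produce no probability entries (no
  0/0).
* Duplicate entity ids are rejected; OD entries referencing unknown ids
  are an error.
* Result CSVs print 9 significant digits; reruns on identical inputs are
  byte-identical.
* A brute-force dense oracle (`oracle_accessibility`, triple loops, no
  sparsity) ships in the package, size-guarded to 200 × 50, and the
  implementation must agree with it to 1e-10 relative in tests.

## Known limitations

* Node snapping (no edge-interior projection) and no turn restrictions,
  road-class speeds, or multimodal thresholds.
* The Euclidean baseline ignores the network entirely, by design.
* Quantile classification of heavily tied scores occupies few levels.
* The ANN z-score assumes complete spatial randomness in a rectangle-like
  study area; irregular city boundaries bias it, as with any Clark–Evans
  report.
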