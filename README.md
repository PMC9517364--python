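# elderaccess

Spatial accessibility of elderly care facilities, measured with an improved
two-step floating catchment area (2SFCA) model: Gaussian distance decay,
Huff destination-choice probabilities, and shortest-path catchments on a
directed road network.

The tool is aimed at health geographers and urban planners who need
per-neighborhood accessibility scores from three inputs: facility locations
with bed capacities, residential points (or zone centroids) with elderly
population counts, and a road centerline layer carrying one-way direction
codes. Because elderly residents travel mainly on foot, the default
catchment is the 800 m neighborhood-unit radius; a time-based mode derives
it from walking speed × duration (0.8 m/s × 15 min = 720 m).

## The model

For a catchment radius d₀ and travel distance d, the truncated Gaussian
decay weight is

    f(d, d0) = (exp(-(1/2)(d/d0)²) − exp(-1/2)) / (1 − exp(-1/2)),  d < d0
    f(d, d0) = 0,                                                   d ≥ d0

**Step 1** — supply–population ratio of each facility *j* with capacity Sⱼ:

    Rⱼ = Sⱼ / Σₖ Pₖ f(dₖⱼ)          (sum over demand k with dₖⱼ ≤ d0)

**Step 2** — accessibility score of each demand point *i*:

    Aᵢ = Σⱼ f(dᵢⱼ) Rⱼ               (sum over facilities j with dᵢⱼ ≤ d0)

The Huff extension weights the population in Step 1 by the probability
that it chooses facility *j*,

    Probᵢⱼ = Sⱼ f(dᵢⱼ) / Σₖ Sₖ f(dᵢₖ),

and weights Step 2 by Probᵢⱼ as well. Three variants are exposed for
comparison: **A** — Euclidean distances, dichotomous decay (the classical
baseline); **B** — network shortest-path distances, Gaussian decay; **C** —
network distances, Gaussian decay and Huff probabilities. Variant C ships
with two readings of the combined formula (`literal`, which applies the
decay weight in both steps, and `conservative`, which applies it once and
conserves total supply exactly); see `docs/methods.md`.

Distances are directed shortest paths (Dijkstra) on the road graph;
one-way streets are honored in the demand→facility direction. All
coordinates must be planar meters.

## Worked example

No real facility/population layers are bundled, so generate a synthetic
city (a 15×15 road lattice at 200 m spacing with 12 facilities and 80
demand points) and run the full pipeline:

```sh
elderaccess synth --seed 42 --out-dir city
cat > config.yaml <<EOF
network: city/network.geojson
facilities: city/facilities.csv
demand: city/demand.csv
out_dir: out
variant: c
EOF
elderaccess run --config config.yaml
cat out/comparison.csv
```

which prints the three-variant summary of the accessibility scores Aᵢ
(beds per elderly person, over the 80 demand points):

```
variant,mean,min,max,sd
a_baseline,0.0527186813,0,0.120046531,0.0349852239
b_network_gaussian,0.0528919844,0,0.234696045,0.0540844058
c_network_gaussian_huff:literal,0.0373640791,0,0.137370523,0.0387877412
```

A mean of 0.053 says the average neighborhood commands ~5.3 beds per 100
elderly residents within its walkable catchment; the minima of 0 are
demand points with no facility within 800 m of network travel. `out/` also
contains the OD matrices, per-demand and per-facility CSVs for every
variant, a decile (10-level) classification of the chosen variant, and a
run manifest with input checksums.

Facility clustering (average nearest neighbor, Clark–Evans) over the city
extent:

```sh
elderaccess ann --facilities city/facilities.csv --study-area-m2 7840000
```

```
{"n": 12, ..., "ann": 1.1198211343327928, "z": 0.7940629495138224}
```

`ann < 1` with a large negative z indicates significant clustering; this
seed's facilities are slightly dispersed (ann ≈ 1.12, z ≈ 0.79, not
significant).

Every stage is also callable as a library function (`elderaccess.
accessibility_score`, `od_distances`, `classify_levels`, …) or as an
individual subcommand (`synth`, `validate`, `od`, `access`, `compare`,
`ann`, `classify`).

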