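"""Seeded synthetic cities for testing and demonstration.

The original study's inputs (a city road-centerline layer with one-way
codes, elderly care facilities with bed capacities, and street-office
elderly populations) are not publicly deposited, so this module generates
structurally equivalent synthetic cities: a planar road lattice with a mix
of two-way and one-way streets, facilities placed at network nodes with a
tunable degree of spatial clustering (emulating the observed "dense core,
sparse periphery" facility pattern), and demand points with positive
elderly populations.  Everything is driven by a single seed; the same spec
yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .accessibility import DemandPoint, Facility, HuffReading, ModelVariant
from .network import DirectionCode, RoadNetwork

__all__ = ["CitySpec", "generate_city", "linear_city_fixture", "LINEAR_CITY_EXPECTED"]


@dataclass(frozen=True)
class CitySpec:
    """Parameters of one synthetic city.

    Defaults sketch a mid-sized urban district: a 15 x 15 street grid at
    200 m spacing (a 2.8 km square), a fifth of streets one-way, a dozen
    facilities of 20–200 beds with mild core clustering, and 80 residential
    demand points of 50–500 elderly residents each.

    ``clustering`` in [0, 1] controls facility placement: 0 samples
    facilities uniformly over all nodes, 1 packs them into the tightest
    possible neighborhood around the city center.
    """

    rows: int = 15
    cols: int = 15
    spacing_m: float = 200.0
    one_way_fraction: float = 0.2
    n_facilities: int = 12
    capacity_range: Tuple[int, int] = (20, 200)
    n_demand: int = 80
    population_range: Tuple[int, int] = (50, 500)
    clustering: float = 0.3
    jitter: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1 or self.n_facilities < 1 or self.n_demand < 1:
            raise ValueError("all counts must be >= 1")
        if not self.spacing_m > 0:
            raise ValueError("spacing must be positive")
        if not (0 <= self.one_way_fraction <= 1 and 0 <= self.clustering <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        lo, hi = self.capacity_range
        if not (0 < lo <= hi):
            raise ValueError("capacity range must be positive and ordered")
        lo, hi = self.population_range
        if not (0 <= lo <= hi):
            raise ValueError("population range must be nonnegative and ordered")


def generate_city(spec: CitySpec) -> Tuple[RoadNetwork, List[Facility], List[DemandPoint]]:
    """Generate one synthetic city from a :class:`CitySpec`.

    The lattice has ``rows x cols`` nodes at ``spacing_m`` intervals; each
    street segment is independently one-way with probability
    ``one_way_fraction`` (orientation drawn at random).  Facilities and
    demand points sit on distinct network nodes (plus a small off-network
    offset when ``jitter`` is set, to exercise snapping).
    """
    rng = np.random.default_rng(spec.seed)
    n_nodes = spec.rows * spec.cols
    if spec.n_facilities > n_nodes:
        raise ValueError(f"cannot place {spec.n_facilities} facilities on {n_nodes} nodes")
    if spec.n_demand > n_nodes:
        raise ValueError(f"cannot place {spec.n_demand} demand points on {n_nodes} nodes")

    nodes: Dict[int, Tuple[float, float]] = {
        r * spec.cols + c: (c * spec.spacing_m, r * spec.spacing_m)
        for r in range(spec.rows)
        for c in range(spec.cols)
    }
    edges = []
    for r in range(spec.rows):
        for c in range(spec.cols):
            u = r * spec.cols + c
            for v in ((u + 1) if c + 1 < spec.cols else None, (u + spec.cols) if r + 1 < spec.rows else None):
                if v is None:
                    continue
                if rng.random() < spec.one_way_fraction:
                    code = DirectionCode.ONE_WAY_FORWARD if rng.random() < 0.5 else DirectionCode.ONE_WAY_BACKWARD
                else:
                    code = DirectionCode.TWO_WAY
                edges.append((u, v, spec.spacing_m, code))
    net = RoadNetwork(nodes=nodes, edges=edges)

    # facility placement: sample without replacement from the pool of nodes
    # nearest the city center; the pool shrinks from all nodes (clustering 0)
    # to exactly n_facilities nodes (clustering 1, the tightest neighborhood)
    center = ((spec.cols - 1) / 2 * spec.spacing_m, (spec.rows - 1) / 2 * spec.spacing_m)
    by_center = sorted(nodes, key=lambda nid: (math.dist(nodes[nid], center), nid))
    pool_size = spec.n_facilities + round((1 - spec.clustering) * (n_nodes - spec.n_facilities))
    fac_nodes = rng.choice(by_center[:pool_size], size=spec.n_facilities, replace=False)
    capacities = rng.integers(spec.capacity_range[0], spec.capacity_range[1] + 1, size=spec.n_facilities)

    dem_nodes = rng.choice(n_nodes, size=spec.n_demand, replace=False)
    populations = rng.integers(spec.population_range[0], spec.population_range[1] + 1, size=spec.n_demand)

    def place(nid: int) -> Tuple[float, float]:
        x, y = nodes[int(nid)]
        if spec.jitter:
            # offset bounded by spacing/4 so the placement node stays nearest
            radius = rng.uniform(0, spec.spacing_m / 4)
            theta = rng.uniform(0, 2 * math.pi)
            return (x + radius * math.cos(theta), y + radius * math.sin(theta))
        return (x, y)

    facilities = [
        Facility(id=f"F{k}", x=loc[0], y=loc[1], capacity=float(capacities[k]))
        for k, loc in enumerate(place(nid) for nid in fac_nodes)
    ]
    demand = [
        DemandPoint(id=f"D{k}", x=loc[0], y=loc[1], population=float(populations[k]))
        for k, loc in enumerate(place(nid) for nid in dem_nodes)
    ]
    return net, facilities, demand


# ---------------------------------------------------------------------------
# Hard-coded linear-city fixture
#
# A 5-node path graph (all streets two-way, d0 = 800 m):
#
#   node:      0 ---- 1 ---- 2 ---- 3 -------- 4
#   x (m):     0     200    500    800       1700
#   demand:   D1(P=100) D2(P=60)            D3(P=120)
#   facility:          F1(S=50)       F2(S=80)
#
# Pairwise distances (network = Euclidean on this straight line):
#   D1-F1 200, D1-F2 800 (catchment boundary, decay weight 0),
#   D2-F1 0,   D2-F2 600, D3-F1 1500 (absent), D3-F2 900 (absent).
#
# The expected scores below were computed once by an independent
# plain-arithmetic script at fixture creation and frozen here.
# ---------------------------------------------------------------------------

LINEAR_CITY_D0 = 800.0

#: expected per-variant results; variant C keyed by huff reading.
LINEAR_CITY_EXPECTED: Dict[str, Dict] = {
    "a": {
        "access": {"D1": 0.3125, "D2": 1.6458333333333333, "D3": 0.0},
        "facility_ratio": {"F1": 0.3125, "F2": 1.3333333333333333},
    },
    "b": {
        "access": {"D1": 0.3028658634636357, "D2": 1.6618902275606071, "D3": 0.0},
        "facility_ratio": {"F1": 0.3285568942272738, "F2": 3.5373847254077315},
    },
    "c_literal": {
        "access": {"D1": 0.3278052040553596, "D2": 0.74321548205428, "D3": 0.0},
        "facility_ratio": {"F1": 0.38577702627775556, "F2": 9.402895988945824},
        "choice_prob": {
            ("D1", "F1"): 1.0,
            ("D1", "F2"): 0.0,
            ("D2", "F1"): 0.6237983776948793,
            ("D2", "F2"): 0.3762016223051207,
        },
    },
    "c_conservative": {
        "access": {"D1": 0.35561175011358875, "D2": 1.573980416477352, "D3": 0.0},
        "facility_ratio": {"F1": 0.38577702627775556, "F2": 9.402895988945824},
        "choice_prob": {
            ("D1", "F1"): 1.0,
            ("D1", "F2"): 0.0,
            ("D2", "F1"): 0.6237983776948793,
            ("D2", "F2"): 0.3762016223051207,
        },
    },
}


def linear_city_fixture():
    """The hard-coded 5-node path-graph instance with frozen expectations.

    Returns ``(net, facilities, demand, expected)`` where ``expected`` maps
    variant keys (``"a"``, ``"b"``, ``"c_literal"``, ``"c_conservative"``)
    to dicts with frozen ``access`` (A_i), ``facility_ratio`` (R_j) and,
    for variant C, ``choice_prob`` values.
    """
    xs = {0: 0.0, 1: 200.0, 2: 500.0, 3: 800.0, 4: 1700.0}
    nodes = {nid: (x, 0.0) for nid, x in xs.items()}
    lengths = {(0, 1): 200.0, (1, 2): 300.0, (2, 3): 300.0, (3, 4): 900.0}
    edges = [(u, v, L, DirectionCode.TWO_WAY) for (u, v), L in lengths.items()]
    net = RoadNetwork(nodes=nodes, edges=edges)
    facilities = [
        Facility(id="F1", x=200.0, y=0.0, capacity=50.0),
        Facility(id="F2", x=800.0, y=0.0, capacity=80.0),
    ]
    demand = [
        DemandPoint(id="D1", x=0.0, y=0.0, population=100.0),
        DemandPoint(id="D2", x=200.0, y=0.0, population=60.0),
        DemandPoint(id="D3", x=1700.0, y=0.0, population=120.0),
    ]
    return net, facilities, demand, {k: dict(v) for k, v in LINEAR_CITY_EXPECTED.items()}
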