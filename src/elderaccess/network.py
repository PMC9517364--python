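"""Directed road networks, point snapping and within-threshold OD distances.

The road network is a directed planar graph built from centerline records.
Each centerline carries a direction attribute (by convention the field
``"Directiona"``) with four recognized values:

* ``"Two Way"`` — traversable in both directions;
* ``"One Way (Digitizing direction)"`` — traversable only from the first to
  the last vertex of the line element;
* ``"One way (Against digitizing direction)"`` — traversable only from the
  last to the first vertex;
* ``"Unknown"`` — direction uncertain, treated as two-way.

Unrecognized direction strings also map to two-way and are counted in a
warning.  Catchments are distance-limited: the OD matrix stores the
shortest directed-path distance from each demand point to each facility,
but only for pairs within the catchment radius ``d0`` (a Euclidean variant
is provided as the baseline for model comparison).  Coordinates must be
planar and in meters; geographic lon/lat degrees are refused.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, List, Mapping, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DirectionCode",
    "RoadNetwork",
    "ODMatrix",
    "build_network",
    "snap_points",
    "od_distances",
    "euclidean_od",
    "walk_threshold",
]

logger = logging.getLogger(__name__)

#: Coordinates are rounded to this precision (meters) for node identity.
NODE_COORD_DECIMALS = 6

#: Default name of the direction attribute on centerline records.
DEFAULT_DIRECTION_FIELD = "Directiona"

#: Default catchment radius, meters (neighborhood-unit walking range).
DEFAULT_D0_M = 800.0

#: Default elderly walking speed, m/s, and trip duration, minutes.
DEFAULT_WALK_SPEED_MPS = 0.8
DEFAULT_WALK_MINUTES = 15.0


class DirectionCode(enum.Enum):
    """Traversal semantics of a centerline record."""

    TWO_WAY = "two_way"
    ONE_WAY_FORWARD = "one_way_forward"
    ONE_WAY_BACKWARD = "one_way_backward"
    UNKNOWN = "unknown"

    @property
    def arcs(self) -> Tuple[Tuple[int, int], ...]:
        """Directed arcs generated by an edge (u, v), as (tail, head) index pairs."""
        if self is DirectionCode.ONE_WAY_FORWARD:
            return ((0, 1),)
        if self is DirectionCode.ONE_WAY_BACKWARD:
            return ((1, 0),)
        return ((0, 1), (1, 0))  # TWO_WAY and UNKNOWN traverse both ways


_DIRECTION_STRINGS = {
    "two way": DirectionCode.TWO_WAY,
    "one way (digitizing direction)": DirectionCode.ONE_WAY_FORWARD,
    "one way (against digitizing direction)": DirectionCode.ONE_WAY_BACKWARD,
    "unknown": DirectionCode.UNKNOWN,
}


def parse_direction(value) -> Tuple[DirectionCode, bool]:
    """Map a raw direction attribute to a :class:`DirectionCode`.

    Returns ``(code, recognized)``; unrecognized values map to ``UNKNOWN``
    (two-way) with ``recognized=False``.
    """
    if isinstance(value, DirectionCode):
        return value, True
    if value is None:
        return DirectionCode.UNKNOWN, False
    key = str(value).strip().lower()
    if key in _DIRECTION_STRINGS:
        return _DIRECTION_STRINGS[key], True
    return DirectionCode.UNKNOWN, False


@dataclass
class RoadNetwork:
    """A directed planar road graph.

    Attributes
    ----------
    nodes:
        Map node-id -> ``(x, y)`` planar coordinates in meters.
    edges:
        List of ``(u, v, length_m, direction)`` centerline edges; the arc
        expansion (``graph``) follows the direction semantics.
    """

    nodes: Dict[Hashable, Tuple[float, float]]
    edges: List[Tuple[Hashable, Hashable, float, DirectionCode]]
    _graph: nx.DiGraph = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for u, v, length, _code in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u}, {v}) references a node not in the node set")
            if not (length > 0 and math.isfinite(length)):
                raise ValueError(f"edge ({u}, {v}) has nonpositive or non-finite length {length}")

    @property
    def graph(self) -> nx.DiGraph:
        """Arc expansion as a :class:`networkx.DiGraph` with ``length`` weights."""
        if self._graph is None:
            g = nx.DiGraph()
            for nid, xy in self.nodes.items():
                g.add_node(nid, x=xy[0], y=xy[1])
            for u, v, length, code in self.edges:
                ends = (u, v)
                for a, b in code.arcs:
                    tail, head = ends[a], ends[b]
                    # keep the shortest arc when parallel edges collapse
                    if not g.has_edge(tail, head) or g[tail][head]["length"] > length:
                        g.add_edge(tail, head, length=length)
            self._graph = g
        return self._graph

    def node_array(self) -> Tuple[List[Hashable], np.ndarray]:
        """Node ids in sorted order and their coordinates as an (n, 2) array."""
        ids = sorted(self.nodes, key=lambda k: (str(type(k)), k))
        xy = np.array([self.nodes[i] for i in ids], dtype=float)
        return ids, xy


@dataclass
class ODMatrix:
    """Sparse within-threshold demand x facility distance table.

    Only pairs with distance ``<= d0`` are stored; pairs beyond the
    threshold or unreachable are absent.  ``metric`` records whether the
    distances are directed network shortest paths or straight lines.
    """

    entries: Dict[Tuple[Hashable, Hashable], float]
    d0: float
    metric: str  # "network" | "euclidean"

    def __post_init__(self) -> None:
        if self.metric not in ("network", "euclidean"):
            raise ValueError(f"unknown OD metric {self.metric!r}")
        if not self.d0 > 0:
            raise ValueError("d0 must be positive")
        for pair, d in self.entries.items():
            if not (0 <= d <= self.d0):
                raise ValueError(f"OD entry {pair} distance {d} outside [0, d0={self.d0}]")

    def facilities_of(self, demand_id) -> Dict[Hashable, float]:
        """Facilities reachable from one demand point, with distances."""
        return {j: d for (i, j), d in self.entries.items() if i == demand_id}

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns demand_id, facility_id, distance_m, metric."""
        rows = [
            {"demand_id": i, "facility_id": j, "distance_m": d, "metric": self.metric}
            for (i, j), d in sorted(self.entries.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1])))
        ]
        return pd.DataFrame(rows, columns=["demand_id", "facility_id", "distance_m", "metric"])


def _check_planar(coords: Iterable[Tuple[float, float]], allow_geographic: bool = False) -> None:
    pts = list(coords)
    for xy in pts:
        if not all(math.isfinite(c) for c in xy):
            raise ValueError(f"non-finite coordinate {xy}")
    if pts and not allow_geographic and all(abs(c) <= 360 for xy in pts for c in xy):
        raise ValueError(
            "coordinates all lie within ±360; they look like geographic lon/lat degrees. "
            "This tool requires planar meters (project first, or pass allow_geographic=True "
            "if the extent genuinely is a small planar patch)."
        )


def build_network(
    records: Sequence[Mapping],
    direction_field: str = DEFAULT_DIRECTION_FIELD,
    allow_geographic: bool = False,
) -> RoadNetwork:
    """Build a :class:`RoadNetwork` from centerline records.

    Each record is a mapping with either explicit endpoints
    (``u``, ``v`` node ids plus per-node coordinates via ``u_xy``/``v_xy``
    or a shared coordinate convention) or a ``coordinates`` polyline
    (a sequence of ``(x, y)`` vertices, as read from GeoJSON LineStrings),
    a ``length`` in meters (defaulting to the geometry length when absent
    or null), and a direction attribute under ``direction_field``.

    Node identity for polyline input is the endpoint coordinate rounded to
    1e-6 m.  Unrecognized direction values are treated as two-way and
    counted in a warning log.
    """
    records = list(records)
    if not records:
        raise ValueError("empty network: no centerline records")

    nodes: Dict[Hashable, Tuple[float, float]] = {}
    edges: List[Tuple[Hashable, Hashable, float, DirectionCode]] = []
    unrecognized = 0

    def coord_node(xy: Tuple[float, float]) -> Tuple[float, float]:
        key = (round(float(xy[0]), NODE_COORD_DECIMALS), round(float(xy[1]), NODE_COORD_DECIMALS))
        nodes.setdefault(key, key)
        return key

    for idx, rec in enumerate(records):
        code, ok = parse_direction(rec.get(direction_field, rec.get("direction")))
        if not ok:
            unrecognized += 1
        if "coordinates" in rec:
            coords = [(float(x), float(y)) for x, y in rec["coordinates"]]
            if len(coords) < 2:
                raise ValueError(f"record {idx}: polyline needs at least two vertices")
            for xy in coords:
                if not all(math.isfinite(c) for c in xy):
                    raise ValueError(f"record {idx}: non-finite coordinate {xy}")
            length = rec.get("length")
            if length is None or (isinstance(length, float) and math.isnan(length)):
                length = sum(math.dist(a, b) for a, b in zip(coords, coords[1:]))
            u = coord_node(coords[0])
            v = coord_node(coords[-1])
        else:
            u, v = rec["u"], rec["v"]
            for end, key in ((u, "u_xy"), (v, "v_xy")):
                if key in rec:
                    xy = (float(rec[key][0]), float(rec[key][1]))
                    if not all(math.isfinite(c) for c in xy):
                        raise ValueError(f"record {idx}: non-finite coordinate {xy}")
                    nodes[end] = xy
            length = rec.get("length")
            if length is None:
                if u in nodes and v in nodes:
                    length = math.dist(nodes[u], nodes[v])
                else:
                    raise ValueError(f"record {idx}: no length and no coordinates to derive one")
        length = float(length)
        if not (length > 0 and math.isfinite(length)):
            raise ValueError(f"record {idx}: nonpositive or non-finite length {length}")
        edges.append((u, v, length, code))

    missing = {e for u, v, _l, _c in edges for e in (u, v) if e not in nodes}
    if missing:
        raise ValueError(f"edge endpoints without coordinates: {sorted(map(str, missing))[:5]}")
    _check_planar(nodes.values(), allow_geographic=allow_geographic)
    if unrecognized:
        logger.warning(
            "%d centerline record(s) had unrecognized direction values; treated as two-way",
            unrecognized,
        )
    return RoadNetwork(nodes=nodes, edges=edges)


def snap_points(
    points: Mapping[Hashable, Tuple[float, float]],
    net: RoadNetwork,
    tolerance: float,
) -> Dict[Hashable, Hashable]:
    """Snap located entities to their nearest network node.

    Ties are broken toward the smallest node id (in sorted node order).
    Entities farther than ``tolerance`` from every node raise an error
    listing the offending ids, so the caller can raise the tolerance.
    """
    if not tolerance > 0:
        raise ValueError("snapping tolerance must be positive")
    ids, xy = net.node_array()
    assignment: Dict[Hashable, Hashable] = {}
    too_far: List[Hashable] = []
    for pid, p in points.items():
        d = np.hypot(xy[:, 0] - p[0], xy[:, 1] - p[1])
        k = int(np.argmin(d))  # first occurrence = smallest node id among ties
        if d[k] > tolerance:
            too_far.append(pid)
        else:
            assignment[pid] = ids[k]
    if too_far:
        raise ValueError(
            f"point(s) beyond snapping tolerance {tolerance} m from every network node: "
            f"{sorted(map(str, too_far))}"
        )
    return assignment


def od_distances(
    demand_nodes: Mapping[Hashable, Hashable],
    facility_nodes: Mapping[Hashable, Hashable],
    net: RoadNetwork,
    d0: float = DEFAULT_D0_M,
) -> ODMatrix:
    """Within-threshold directed shortest-path OD distances.

    ``demand_nodes`` / ``facility_nodes`` map entity ids to network node
    ids (as produced by :func:`snap_points`).  Paths run demand -> facility
    (the resident walks to the facility), so one-way streets are honored
    in that direction.  An entry is present iff the shortest directed path
    is ``<= d0``; unreachable pairs are simply absent.
    """
    if not d0 > 0:
        raise ValueError("d0 must be positive")
    g = net.graph
    for label, mapping in (("demand", demand_nodes), ("facility", facility_nodes)):
        bad = [eid for eid, n in mapping.items() if n not in net.nodes]
        if bad:
            raise ValueError(f"{label} entities snapped to unknown nodes: {sorted(map(str, bad))}")

    entries: Dict[Tuple[Hashable, Hashable], float] = {}
    # group demand entities by node so Dijkstra runs once per source node
    by_node: Dict[Hashable, List[Hashable]] = {}
    for did, n in demand_nodes.items():
        by_node.setdefault(n, []).append(did)
    for src, dids in by_node.items():
        lengths = nx.single_source_dijkstra_path_length(g, src, cutoff=d0, weight="length")
        for fid, fnode in facility_nodes.items():
            d = lengths.get(fnode)
            if d is not None and d <= d0:
                for did in dids:
                    entries[(did, fid)] = float(d)
    return ODMatrix(entries=entries, d0=float(d0), metric="network")


def euclidean_od(
    demand_points: Mapping[Hashable, Tuple[float, float]],
    facility_points: Mapping[Hashable, Tuple[float, float]],
    d0: float = DEFAULT_D0_M,
) -> ODMatrix:
    """Straight-line OD distances with the same threshold semantics.

    Provided as the baseline for the pre-optimization model variant.
    """
    if not d0 > 0:
        raise ValueError("d0 must be positive")
    _check_planar(list(demand_points.values()) + list(facility_points.values()), allow_geographic=True)
    entries: Dict[Tuple[Hashable, Hashable], float] = {}
    for did, p in demand_points.items():
        for fid, q in facility_points.items():
            d = math.dist(p, q)
            if d <= d0:
                entries[(did, fid)] = d
    return ODMatrix(entries=entries, d0=float(d0), metric="euclidean")


def walk_threshold(
    speed_mps: float = DEFAULT_WALK_SPEED_MPS,
    minutes: float = DEFAULT_WALK_MINUTES,
) -> float:
    """Catchment radius (meters) covered by a walk of ``minutes`` at ``speed_mps``.

    The defaults encode the elderly walking range: 0.8 m/s for 15 minutes,
    i.e. 720 m.
    """
    if not speed_mps > 0:
        raise ValueError("walking speed must be positive")
    if not minutes > 0:
        raise ValueError("duration must be positive")
    return speed_mps * minutes * 60.0
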