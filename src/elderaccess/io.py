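"""File I/O: CSV and GeoJSON readers/writers for the pipeline's formats.

Expected schemas
----------------
* facilities CSV: ``id, x, y, beds[, quality]`` (capacity = beds * quality,
  quality defaulting to 1.0); GeoJSON points with the same property names.
* demand CSV: ``id, x, y, pop_elderly``; GeoJSON point equivalent.
* road network: GeoJSON FeatureCollection of LineStrings with a direction
  property (default ``"Directiona"``), or a CSV edge list with columns
  ``u, v, length, direction`` plus node coordinates ``u_x, u_y, v_x, v_y``.

All coordinates are planar meters.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Hashable, List, Mapping, Tuple, Union

import pandas as pd

from .accessibility import AccessibilityResult, DemandPoint, Facility
from .network import DEFAULT_DIRECTION_FIELD, ODMatrix, RoadNetwork, build_network

__all__ = [
    "read_facilities",
    "read_demand",
    "read_network",
    "write_od_csv",
    "write_access_csv",
    "write_facility_csv",
    "write_network_geojson",
    "write_points_geojson",
    "validate_inputs",
]

PathLike = Union[str, Path]


def _read_point_records(path: PathLike, props: List[str]) -> pd.DataFrame:
    """Read point records from CSV or a GeoJSON FeatureCollection."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        with open(path) as fh:
            gj = json.load(fh)
        rows = []
        for feat in gj.get("features", []):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Point":
                raise ValueError(f"{path}: expected Point features, got {geom.get('type')}")
            x, y = geom["coordinates"][:2]
            rows.append({"x": x, "y": y, **(feat.get("properties") or {})})
        return pd.DataFrame(rows)
    df = pd.read_csv(path)
    missing = [c for c in props + ["x", "y"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_facilities(path: PathLike) -> List[Facility]:
    """Load facilities; capacity is ``beds * quality`` (quality default 1)."""
    df = _read_point_records(path, ["id", "beds"])
    if "id" not in df.columns or "beds" not in df.columns:
        raise ValueError(f"{path}: facilities need 'id' and 'beds'")
    quality = df["quality"] if "quality" in df.columns else 1.0
    df = df.assign(capacity=df["beds"] * quality)
    return [
        Facility(id=row.id, x=float(row.x), y=float(row.y), capacity=float(row.capacity))
        for row in df.itertuples()
    ]


def read_demand(path: PathLike) -> List[DemandPoint]:
    """Load demand points with elderly population counts."""
    df = _read_point_records(path, ["id", "pop_elderly"])
    if "id" not in df.columns or "pop_elderly" not in df.columns:
        raise ValueError(f"{path}: demand needs 'id' and 'pop_elderly'")
    return [
        DemandPoint(id=row.id, x=float(row.x), y=float(row.y), population=float(row.pop_elderly))
        for row in df.itertuples()
    ]


def read_network(
    path: PathLike,
    direction_field: str = DEFAULT_DIRECTION_FIELD,
    allow_geographic: bool = False,
) -> RoadNetwork:
    """Load a road network from GeoJSON LineStrings or a CSV edge list."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        with open(path) as fh:
            gj = json.load(fh)
        records = []
        for feat in gj.get("features", []):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "LineString":
                raise ValueError(f"{path}: expected LineString features, got {geom.get('type')}")
            records.append({"coordinates": geom["coordinates"], **(feat.get("properties") or {})})
        return build_network(records, direction_field=direction_field, allow_geographic=allow_geographic)
    df = pd.read_csv(path)
    needed = ["u", "v", "length", "direction"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: edge list missing column(s) {missing}")
    records = []
    for row in df.itertuples():
        rec = {"u": row.u, "v": row.v, "length": row.length, "direction": row.direction}
        if {"u_x", "u_y", "v_x", "v_y"} <= set(df.columns):
            rec["u_xy"] = (row.u_x, row.u_y)
            rec["v_xy"] = (row.v_x, row.v_y)
        records.append(rec)
    return build_network(records, direction_field="direction", allow_geographic=allow_geographic)


# CSV numeric formatting: 9 significant digits.
_FLOAT_FMT = "%.9g"


def write_od_csv(od: ODMatrix, path: PathLike) -> None:
    od.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_access_csv(result: AccessibilityResult, path: PathLike) -> None:
    """Demand-side scores: demand_id, A_i, variant, d0_m."""
    rows = [
        {"demand_id": i, "A_i": a, "variant": result.variant.value, "d0_m": result.od.d0}
        for i, a in sorted(result.access.items(), key=lambda kv: str(kv[0]))
    ]
    pd.DataFrame(rows, columns=["demand_id", "A_i", "variant", "d0_m"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_facility_csv(result: AccessibilityResult, path: PathLike) -> None:
    """Facility-side ratios: facility_id, R_j, unserviced."""
    rows = [
        {"facility_id": j, "R_j": r, "unserviced": j in result.unserviced}
        for j, r in sorted(result.facility_ratio.items(), key=lambda kv: str(kv[0]))
    ]
    pd.DataFrame(rows, columns=["facility_id", "R_j", "unserviced"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_network_geojson(net: RoadNetwork, path: PathLike, direction_field: str = DEFAULT_DIRECTION_FIELD) -> None:
    """Write the centerlines as a GeoJSON FeatureCollection of LineStrings."""
    code_to_string = {
        "two_way": "Two Way",
        "one_way_forward": "One Way (Digitizing direction)",
        "one_way_backward": "One way (Against digitizing direction)",
        "unknown": "Unknown",
    }
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [list(net.nodes[u]), list(net.nodes[v])],
            },
            "properties": {direction_field: code_to_string[code.value], "length": length},
        }
        for u, v, length, code in net.edges
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_points_geojson(
    points: Mapping[Hashable, Tuple[float, float]],
    properties: Mapping[Hashable, Mapping],
    path: PathLike,
) -> None:
    """Join per-point attributes (scores, levels, ...) onto point geometry."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": list(xy)},
            "properties": {"id": pid, **dict(properties.get(pid, {}))},
        }
        for pid, xy in points.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def validate_inputs(
    network_path: PathLike = None,
    facilities_path: PathLike = None,
    demand_path: PathLike = None,
) -> Dict[str, List[str]]:
    """Schema report per input file; never mutates inputs.

    Returns a map file-role -> list of human-readable problems (missing
    columns, non-numeric fields, duplicate ids, out-of-range values).  An
    empty list means the file is clean; a clean run returns all-empty lists.
    """
    report: Dict[str, List[str]] = {}

    def check_points(path, role, value_col, minimum_exclusive):
        problems: List[str] = []
        try:
            df = _read_point_records(path, [])
        except Exception as exc:  # unreadable or malformed
            report[role] = [f"unreadable: {exc}"]
            return
        for col in ["id", "x", "y", value_col]:
            if col not in df.columns:
                problems.append(f"missing column {col!r}")
        if "id" in df.columns and df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            problems.append(f"duplicate id(s): {dupes}")
        for col in ["x", "y", value_col]:
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="coerce")
                if vals.isna().any():
                    problems.append(f"non-numeric value(s) in {col!r}")
                elif col == value_col:
                    bad = vals <= 0 if minimum_exclusive else vals < 0
                    if bad.any():
                        problems.append(f"out-of-range {col!r} at row(s) {list(df.index[bad])}")
        report[role] = problems

    if facilities_path is not None:
        check_points(facilities_path, "facilities", "beds", minimum_exclusive=True)
    if demand_path is not None:
        check_points(demand_path, "demand", "pop_elderly", minimum_exclusive=False)
    if network_path is not None:
        try:
            read_network(network_path, allow_geographic=True)
            report["network"] = []
        except Exception as exc:
            report["network"] = [str(exc)]
    return report
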