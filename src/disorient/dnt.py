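"""Detour Navigation Test (DNT) scoring.

The DNT is an accompanied real-world walk in the participant's own
neighbourhood: a familiar **original route** from home to a landmark, then —
sprung on the participant at the first intersection of the way back — a
**detour route** home that must not overlap the original route. Disorientation
is observed as two event types:

* **wrong turn** — at an intersection, moving onto a path that is neither a
  marked viable alternative route nor an exempted overlap with the original
  route (e.g. a cul-de-sac exit where no alternative exists). After two
  consecutive wrong turns the participant is brought back to the location
  before the first wrong turn and tries again.
* **moment of hesitation** — slowing/stopping and looking around, or verbally
  admitting uncertainty (observer-recorded; not inferred by this package).

Event counts are normalized per route by the route's intersection count and
distance and summed into a route disorientation score. The composite score

    composite = (detour score + 1) / (original score + 1)

uses a +1 continuity correction so the ratio is defined when the original
route score is 0 (the typical case); composite = 1 means no differential
disorientation, > 1 more disorientation on the detour, < 1 more on the
original route. Patients are dichotomized as high risk when the composite
differs from 1.

The street network is a :class:`StreetGraph` over ``networkx``; intersections
are nodes of degree >= 3 (or explicitly flagged decision points). ``RESET``
in a taken path marks the experimenter escorting the participant back after a
double wrong turn — the jump back is not an edge traversal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "RESET",
    "StreetGraph",
    "NavEvent",
    "RouteWalk",
    "DntScore",
    "detect_wrong_turns",
    "route_disorientation_score",
    "composite_score",
    "classify_risk",
    "score_walk_pair",
    "write_graph_geojson",
    "read_graph_geojson",
    "write_routes_geojson",
    "read_routes_geojson",
    "read_events_csv",
]

#: Sentinel in a taken path marking a positional reset after a double wrong
#: turn: the following node is the position the participant was brought back
#: to, reached without traversing an edge.
RESET = "__RESET__"


class StreetGraph:
    """Street network: nodes with 2-D coordinates, edges with lengths in km.

    Edges can carry a ``viable`` flag marking them as part of a viable
    alternative (detour) route — the experimenter's map marking, set at
    analysis time, never inferred.
    """

    def __init__(self) -> None:
        self.g = nx.Graph()

    def add_node(self, node_id: str, x: float, y: float,
                 intersection: bool | None = None) -> None:
        self.g.add_node(node_id, x=float(x), y=float(y), intersection=intersection)

    def add_edge(self, u: str, v: str, length_km: float,
                 viable: bool = False) -> None:
        if length_km <= 0:
            raise ValueError(f"edge ({u}, {v}): length must be positive")
        self.g.add_edge(u, v, length_km=float(length_km), viable=bool(viable))

    def is_intersection(self, node_id: str) -> bool:
        """Degree >= 3, unless explicitly flagged either way."""
        flag = self.g.nodes[node_id].get("intersection")
        if flag is not None:
            return bool(flag)
        return self.g.degree[node_id] >= 3

    def viable_edges(self) -> frozenset[frozenset[str]]:
        return frozenset(
            frozenset((u, v)) for u, v, d in self.g.edges(data=True) if d["viable"]
        )

    def path_length_km(self, path: Sequence[str]) -> float:
        total = 0.0
        for u, v in zip(path, path[1:]):
            if not self.g.has_edge(u, v):
                raise ValueError(f"no street edge between {u!r} and {v!r}")
            total += self.g.edges[u, v]["length_km"]
        return total

    def count_intersections(self, path: Sequence[str]) -> int:
        return sum(self.is_intersection(n) for n in dict.fromkeys(path))

    def validate(self) -> None:
        if self.g.number_of_nodes() and not nx.is_connected(self.g):
            raise ValueError("street graph must be connected")


@dataclass(frozen=True)
class NavEvent:
    """One observed disorientation event."""

    kind: str  # "wrong_turn" | "hesitation"
    node_id: str
    consecutive_index: int | None = None  # 1 or 2, wrong turns only

    def __post_init__(self) -> None:
        if self.kind not in ("wrong_turn", "hesitation"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "wrong_turn" and self.consecutive_index not in (1, 2):
            raise ValueError("wrong_turn events need consecutive_index 1 or 2")


@dataclass
class RouteWalk:
    """One walked route: the planned node sequence, what was actually walked,
    and the observer's event log."""

    route_type: str  # "original" | "detour"
    planned_path: list[str]
    taken_path: list[str]
    events: list[NavEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.route_type not in ("original", "detour"):
            raise ValueError(f"route_type must be original|detour, got {self.route_type!r}")
        if len(self.planned_path) < 2:
            raise ValueError("planned_path needs at least two nodes")

    def hesitations(self) -> list[NavEvent]:
        return [e for e in self.events if e.kind == "hesitation"]


@dataclass(frozen=True)
class DntScore:
    """Per-participant DNT outcome."""

    original_wrong_turns_norm: float
    original_hesitations_norm: float
    original_score: float
    detour_wrong_turns_norm: float
    detour_hesitations_norm: float
    detour_score: float
    composite: float
    risk: str  # "high" | "low"


def detect_wrong_turns(
    walk: RouteWalk,
    graph: StreetGraph,
    original_path: Sequence[str] | None = None,
    allowed_overlap: Iterable[frozenset[str]] = (),
) -> list[NavEvent]:
    """Re-derive wrong-turn events from a taken path.

    A move from an intersection is a wrong turn when the edge taken is not on
    the walk's planned route, not marked viable on the map, and not an
    exempted overlap; for detour walks any edge of the original route is also
    wrong unless exempted. Retreating along the edge just walked is never
    flagged (turning back is recovery, not a new navigation choice). On the
    second consecutive wrong turn the participant is brought back to the node
    before the first wrong turn; the taken path marks this with ``RESET``
    followed by that node.
    """
    if walk.route_type == "detour" and original_path is None:
        raise ValueError("detour walks require the original route for overlap checks")

    allowed = frozenset(frozenset(e) for e in allowed_overlap)
    planned_edges = {frozenset(e) for e in zip(walk.planned_path, walk.planned_path[1:])}
    viable = graph.viable_edges() | planned_edges
    original_edges: set[frozenset[str]] = set()
    if original_path is not None and walk.route_type == "detour":
        original_edges = {frozenset(e) for e in zip(original_path, original_path[1:])}

    events: list[NavEvent] = []
    consecutive = 0
    anchor: str | None = None
    prev_edge: frozenset[str] | None = None
    path = walk.taken_path
    i = 0
    while i < len(path) - 1:
        u = path[i]
        if consecutive == 2 and path[i + 1] != RESET:
            raise ValueError(
                f"step {i}: expected a positional reset after two consecutive "
                f"wrong turns"
            )
        if path[i + 1] == RESET:
            if consecutive != 2:
                raise ValueError(f"step {i}: reset marker without a double wrong turn")
            if i + 2 >= len(path) or path[i + 2] != anchor:
                raise ValueError(
                    f"step {i}: reset must return to the pre-wrong-turn node {anchor!r}"
                )
            consecutive = 0
            anchor = None
            prev_edge = None
            i += 2  # land on the anchor without traversing an edge
            continue
        v = path[i + 1]
        if not graph.g.has_edge(u, v):
            raise ValueError(f"step {i}: no street edge between {u!r} and {v!r}")
        edge = frozenset((u, v))
        if graph.is_intersection(u) and edge != prev_edge:
            wrong = edge not in allowed and (
                edge in original_edges or edge not in viable
            )
            if wrong:
                consecutive += 1
                if consecutive == 1:
                    anchor = u
                events.append(NavEvent("wrong_turn", u, consecutive))
            else:
                consecutive = 0
                anchor = None
        prev_edge = edge
        i += 1
    return events


def route_disorientation_score(
    n_wrong_turns: int,
    n_hesitations: int,
    n_intersections: int,
    distance_km: float,
    normalization: str = "split",
) -> float:
    """Normalized disorientation score for one route.

    ``split`` (default): wrong turns per intersection (the opportunity set)
    plus hesitations per km (a rate) — the two components sum to the score.
    ``combined``: total events divided by intersections x distance.
    """
    if n_wrong_turns < 0 or n_hesitations < 0:
        raise ValueError("event counts must be non-negative")
    if n_intersections < 1:
        raise ValueError("route must contain at least one intersection")
    if distance_km <= 0:
        raise ValueError("route distance must be positive")
    if normalization == "split":
        return n_wrong_turns / n_intersections + n_hesitations / distance_km
    if normalization == "combined":
        return (n_wrong_turns + n_hesitations) / (n_intersections * distance_km)
    raise ValueError(f"unknown normalization {normalization!r}")


def composite_score(detour_score: float, original_score: float) -> float:
    """(detour + 1) / (original + 1), the continuity-corrected ratio."""
    if detour_score < 0 or original_score < 0:
        raise ValueError("route disorientation scores must be non-negative")
    return (detour_score + 1.0) / (original_score + 1.0)


def classify_risk(composite: float, tolerance: float = 1e-9) -> str:
    """``high`` if the composite differs from 1 beyond tolerance, else ``low``."""
    if composite <= 0:
        raise ValueError("composite score must be positive")
    return "high" if abs(composite - 1.0) > tolerance else "low"


def score_walk_pair(
    original: RouteWalk,
    detour: RouteWalk,
    graph: StreetGraph,
    allowed_overlap: Iterable[frozenset[str]] = (),
    normalization: str = "split",
    risk_tolerance: float = 1e-9,
) -> DntScore:
    """Full per-participant DNT pipeline: detect, normalize, compose, classify."""
    parts = {}
    for walk in (original, detour):
        wt = detect_wrong_turns(
            walk, graph,
            original_path=original.planned_path if walk.route_type == "detour" else None,
            allowed_overlap=allowed_overlap,
        )
        n_int = graph.count_intersections(walk.planned_path)
        dist = graph.path_length_km(walk.planned_path)
        wt_norm = route_disorientation_score(len(wt), 0, n_int, dist, normalization)
        hes_norm = route_disorientation_score(
            0, len(walk.hesitations()), n_int, dist, normalization)
        parts[walk.route_type] = (wt_norm, hes_norm, wt_norm + hes_norm)
    comp = composite_score(parts["detour"][2], parts["original"][2])
    return DntScore(
        original_wrong_turns_norm=parts["original"][0],
        original_hesitations_norm=parts["original"][1],
        original_score=parts["original"][2],
        detour_wrong_turns_norm=parts["detour"][0],
        detour_hesitations_norm=parts["detour"][1],
        detour_score=parts["detour"][2],
        composite=comp,
        risk=classify_risk(comp, risk_tolerance),
    )


# --------------------------------------------------------------------------
# GeoJSON / CSV interchange

def write_graph_geojson(graph: StreetGraph, path) -> None:
    features = []
    for n, d in sorted(graph.g.nodes(data=True)):
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [d["x"], d["y"]]},
            "properties": {"id": n, "intersection": graph.is_intersection(n)},
        })
    for u, v, d in sorted(graph.g.edges(data=True)):
        cu, cv = graph.g.nodes[u], graph.g.nodes[v]
        features.append({
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [[cu["x"], cu["y"]], [cv["x"], cv["y"]]],
            },
            "properties": {"u": u, "v": v, "length_km": d["length_km"],
                           "viable": d["viable"]},
        })
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_graph_geojson(path) -> StreetGraph:
    payload = json.loads(Path(path).read_text())
    graph = StreetGraph()
    edges = []
    for feat in payload["features"]:
        props, geom = feat["properties"], feat["geometry"]
        if geom["type"] == "Point":
            x, y = geom["coordinates"]
            graph.add_node(props["id"], x, y, intersection=props.get("intersection"))
        elif geom["type"] == "LineString":
            edges.append(props)
    for e in edges:
        graph.add_edge(e["u"], e["v"], e["length_km"], viable=e.get("viable", False))
    graph.validate()
    return graph


def write_routes_geojson(routes: dict[str, dict[str, list[str]]],
                         graph: StreetGraph, path) -> None:
    """``routes``: participant_id -> {route_type: planned node sequence}."""
    features = []
    for pid in sorted(routes):
        for rtype in sorted(routes[pid]):
            nodes = routes[pid][rtype]
            coords = [[graph.g.nodes[n]["x"], graph.g.nodes[n]["y"]] for n in nodes]
            features.append({
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": coords},
                "properties": {"participant_id": pid, "route_type": rtype,
                               "nodes": list(nodes)},
            })
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_routes_geojson(path) -> dict[str, dict[str, list[str]]]:
    payload = json.loads(Path(path).read_text())
    routes: dict[str, dict[str, list[str]]] = {}
    for feat in payload["features"]:
        p = feat["properties"]
        routes.setdefault(str(p["participant_id"]), {})[p["route_type"]] = list(p["nodes"])
    return routes


def read_events_csv(path) -> pd.DataFrame:
    """Observer event log: participant_id, route_type, kind, node_id, timestamp."""
    df = pd.read_csv(path, dtype={"participant_id": str, "node_id": str})
    required = ["participant_id", "route_type", "kind", "node_id", "timestamp"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df
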