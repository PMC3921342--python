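"""Areal adjacency structures for conditional-autoregressive models.

An :class:`AreaMap` holds area identifiers with planar polygon geometry;
an :class:`AdjacencyMatrix` is the symmetric neighbour structure (the CAR
graph) with a triplet encoding (``num``/``adj``/``sum_num_neigh``)
mirroring the GeoBUGS adjacency-file convention.  Indices are 0-based in
memory and 1-based only inside the GeoBUGS text files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import Polygon, shape, mapping


class DisconnectedGraphError(ValueError):
    """Raised when an adjacency graph is not connected (ICAR requires it)."""

    def __init__(self, components: list[list[int]]):
        self.components = components
        super().__init__(
            f"adjacency graph is disconnected: {len(components)} components "
            f"with sizes {[len(c) for c in components]}"
        )


@dataclass
class AreaMap:
    """Planar areal units: unique string ids and one polygon per area."""

    area_id: list[str]
    geometry: list[Polygon]

    def __post_init__(self) -> None:
        if len(self.area_id) != len(self.geometry):
            raise ValueError("area_id and geometry lengths differ")
        if len(set(self.area_id)) != len(self.area_id):
            raise ValueError("area ids are not unique")
        for aid, geom in zip(self.area_id, self.geometry):
            if geom is None or geom.is_empty:
                raise ValueError(f"empty geometry for area {aid!r}")

    @property
    def n(self) -> int:
        return len(self.area_id)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([[g.centroid.x, g.centroid.y] for g in self.geometry])


@dataclass
class AdjacencyMatrix:
    """Symmetric, irreflexive neighbour lists over ``n`` areas.

    ``neighbours[i]`` is the sorted list of 0-based neighbour indices of
    area ``i``.  The GeoBUGS triplet encoding is exposed via :attr:`num`,
    :attr:`adj` (0-based here; the writer converts) and
    :attr:`sum_num_neigh`.
    """

    n: int
    neighbours: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.neighbours) != self.n:
            raise ValueError(f"expected {self.n} neighbour lists, got {len(self.neighbours)}")
        self.neighbours = [sorted(set(ns)) for ns in self.neighbours]
        for i, ns in enumerate(self.neighbours):
            for j in ns:
                if j == i:
                    raise ValueError(f"area {i} lists itself as a neighbour")
                if not 0 <= j < self.n:
                    raise ValueError(f"neighbour index {j} of area {i} out of range")
                if i not in self.neighbours[j]:
                    raise ValueError(f"asymmetric adjacency: {i} lists {j} but not vice versa")

    @property
    def num(self) -> np.ndarray:
        return np.array([len(ns) for ns in self.neighbours], dtype=int)

    @property
    def adj(self) -> np.ndarray:
        return np.array([j for ns in self.neighbours for j in ns], dtype=int)

    @property
    def sum_num_neigh(self) -> int:
        return int(self.num.sum())

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (m, 2) array with i < j."""
        return np.array(
            [(i, j) for i, ns in enumerate(self.neighbours) for j in ns if i < j],
            dtype=int,
        ).reshape(-1, 2)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edges))
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_graph())

    def require_connected(self) -> None:
        g = self.to_graph()
        if not nx.is_connected(g):
            comps = [sorted(c) for c in nx.connected_components(g)]
            raise DisconnectedGraphError(comps)

    def dense(self) -> np.ndarray:
        """0/1 adjacency matrix W."""
        w = np.zeros((self.n, self.n))
        e = self.edges
        if len(e):
            w[e[:, 0], e[:, 1]] = 1.0
            w[e[:, 1], e[:, 0]] = 1.0
        return w


def _snap(coords: Iterable[tuple[float, float]], grid: float) -> set[tuple[int, int]]:
    return {(round(x / grid), round(y / grid)) for x, y in coords}


def _boundary_points(poly: Polygon, grid: float) -> set[tuple[int, int]]:
    pts: set[tuple[int, int]] = set()
    rings = [poly.exterior, *poly.interiors]
    for ring in rings:
        pts |= _snap(ring.coords, grid)
    return pts


def build_adjacency(
    area_map: AreaMap, rule: str = "queen", snap_grid: float = 1e-9
) -> AdjacencyMatrix:
    """Derive contiguity neighbours from polygon geometry.

    Two areas are neighbours iff their boundaries share at least one
    snapped vertex (``queen``) or a positive-length boundary segment
    (``rook``).  Coordinates are snapped to ``snap_grid`` before
    comparison to absorb floating-point jitter on shared borders.

    Raises
    ------
    DisconnectedGraphError
        If the resulting contiguity graph is not connected.
    """
    if rule not in ("queen", "rook"):
        raise ValueError(f"rule must be 'queen' or 'rook', got {rule!r}")
    n = area_map.n
    neighbours: list[list[int]] = [[] for _ in range(n)]
    if rule == "queen":
        pts = [_boundary_points(g, snap_grid) for g in area_map.geometry]
        for i in range(n):
            for j in range(i + 1, n):
                if pts[i] & pts[j]:
                    neighbours[i].append(j)
                    neighbours[j].append(i)
    else:
        # rook: shared boundary must have positive length
        for i in range(n):
            for j in range(i + 1, n):
                gi, gj = area_map.geometry[i], area_map.geometry[j]
                if not gi.envelope.buffer(10 * snap_grid).intersects(gj.envelope):
                    continue
                shared = gi.intersection(gj)
                if shared.length > 10 * snap_grid:
                    neighbours[i].append(j)
                    neighbours[j].append(i)
    adj = AdjacencyMatrix(n=n, neighbours=neighbours)
    adj.require_connected()
    return adj


def write_geobugs_adjacency(adj: AdjacencyMatrix, path) -> None:
    """Write the GeoBUGS ``list(num=..., adj=..., sumNumNeigh=...)`` file.

    Neighbour indices are converted to the 1-based WinBUGS convention.
    Areas with no neighbours are rejected: the ICAR conditional is
    undefined for islands.
    """
    num = adj.num
    if (num == 0).any():
        empty = np.flatnonzero(num == 0).tolist()
        raise ValueError(f"areas with no neighbours (ICAR undefined): {empty}")
    lines = ["list("]
    lines.append("num = c(" + ", ".join(str(k) for k in num) + "),")
    lines.append("adj = c(")
    for i, ns in enumerate(adj.neighbours):
        row = ", ".join(str(j + 1) for j in ns)
        lines.append(row + ("," if i < adj.n - 1 else ""))
    lines.append("),")
    lines.append(f"sumNumNeigh = {adj.sum_num_neigh}")
    lines.append(")")
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write adjacency file {path}: {exc}") from exc


def read_geobugs_adjacency(path) -> AdjacencyMatrix:
    """Parse a GeoBUGS adjacency file written by :func:`write_geobugs_adjacency`.

    Validates symmetry and the ``sumNumNeigh`` bookkeeping; returns the
    0-based :class:`AdjacencyMatrix`.
    """
    try:
        with open(path) as fh:
            text = fh.read()
    except OSError as exc:
        raise OSError(f"cannot read adjacency file {path}: {exc}") from exc

    def _extract_vector(name: str) -> list[int]:
        idx = text.find(name)
        if idx < 0:
            raise ValueError(f"{path}: missing '{name}' block")
        start = text.index("c(", idx) + 2
        depth = 1
        end = start
        while depth > 0:
            if end >= len(text):
                raise ValueError(f"{path}: unterminated '{name}' vector")
            if text[end] == "(":
                depth += 1
            elif text[end] == ")":
                depth -= 1
            end += 1
        body = text[start : end - 1]
        vals = [tok.strip() for tok in body.replace("\n", " ").split(",")]
        return [int(v) for v in vals if v]

    num = _extract_vector("num")
    adj_flat = _extract_vector("adj")
    idx = text.find("sumNumNeigh")
    if idx < 0:
        raise ValueError(f"{path}: missing 'sumNumNeigh'")
    tail = text[idx:].split("=", 1)[1]
    snn = int("".join(ch for ch in tail.split(")")[0].strip() if ch in "0123456789"))

    if snn != len(adj_flat):
        raise ValueError(
            f"{path}: sumNumNeigh = {snn} but adj has {len(adj_flat)} entries"
        )
    if snn != sum(num):
        raise ValueError(f"{path}: sumNumNeigh = {snn} but sum(num) = {sum(num)}")
    n = len(num)
    neighbours: list[list[int]] = []
    pos = 0
    for i, k in enumerate(num):
        chunk = adj_flat[pos : pos + k]
        pos += k
        for j in chunk:
            if not 1 <= j <= n:
                raise ValueError(f"{path}: neighbour index {j} of area {i + 1} out of 1..{n}")
        neighbours.append([j - 1 for j in chunk])
    for i, ns in enumerate(neighbours):
        for j in ns:
            if i not in neighbours[j]:
                raise ValueError(
                    f"{path}: asymmetric adjacency between areas {i + 1} and {j + 1}"
                )
    return AdjacencyMatrix(n=n, neighbours=neighbours)


def read_geojson_areas(path, id_property: str = "area_id") -> AreaMap:
    """Read an AreaMap from a GeoJSON FeatureCollection.

    ``id_property`` names the feature property carrying the area id; the
    feature ``id`` member is used as a fallback.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a FeatureCollection")
    ids, geoms = [], []
    for k, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        aid = props.get(id_property, feat.get("id"))
        if aid is None:
            raise ValueError(f"{path}: feature {k} has no '{id_property}' property or id")
        geom = shape(feat["geometry"])
        if geom.geom_type == "MultiPolygon":
            geom = max(geom.geoms, key=lambda g: g.area)
        if geom.geom_type != "Polygon":
            raise ValueError(f"{path}: feature {aid} is {geom.geom_type}, expected Polygon")
        ids.append(str(aid))
        geoms.append(geom)
    return AreaMap(area_id=ids, geometry=geoms)


def write_geojson_areas(
    area_map: AreaMap,
    path,
    properties: dict[str, Sequence] | None = None,
    id_property: str = "area_id",
) -> None:
    """Write an AreaMap (plus optional per-area properties) as GeoJSON."""
    properties = properties or {}
    for key, vals in properties.items():
        if len(vals) != area_map.n:
            raise ValueError(f"property {key!r} has length {len(vals)} != {area_map.n}")
    features = []
    for i, (aid, geom) in enumerate(zip(area_map.area_id, area_map.geometry)):
        props = {id_property: aid}
        for key, vals in properties.items():
            v = vals[i]
            props[key] = float(v) if isinstance(v, (np.floating, np.integer)) else v
        features.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
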