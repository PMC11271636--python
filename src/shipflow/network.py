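"""Directed weighted shipping networks built from port-to-port trip records.

A shipping network is a directed graph whose nodes are ports and whose edge
weights count the trips observed between ordered port pairs. The augmented
("fully connected") variant adds low-weight pseudo-edges for every missing
ordered pair so that downstream link screening can score all candidate
origin-destination connections.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .geo import GeoPoint, haversine, haversine_matrix

logger = logging.getLogger(__name__)

DEFAULT_PSEUDO_WEIGHT = 0.1


@dataclass(frozen=True)
class Port:
    """A port in the registry: identifier, display name, location and country.

    ``region`` may be None until region encoding has been applied.
    """

    port_id: str
    name: str
    location: GeoPoint
    country: str
    region: str | None = None

    def __post_init__(self) -> None:
        if not self.port_id:
            raise ValueError("port_id must be non-empty")
        if not self.country:
            raise ValueError(f"port {self.port_id!r}: country must be non-empty")


class ShippingNetwork:
    """Directed weighted port graph with an optional full-connection augmentation.

    Wraps a :class:`networkx.DiGraph`; edge attribute ``w`` is the weight
    (trip count, or the pseudo weight) and ``pseudo`` marks augmentation edges.
    """

    def __init__(self, graph: nx.DiGraph, ports: dict[str, Port], augmented: bool = False):
        for u, v in graph.edges():
            if u not in ports or v not in ports:
                raise ValueError(f"edge ({u!r}, {v!r}) references a port missing from the registry")
        self.graph = graph
        self.ports = ports
        self.augmented = augmented

    @property
    def port_ids(self) -> list[str]:
        return list(self.graph.nodes())

    def n_ports(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, source: str, dest: str) -> float:
        return float(self.graph.edges[source, dest]["w"])

    def real_edges(self) -> list[tuple[str, str]]:
        return [(u, v) for u, v, d in self.graph.edges(data=True) if not d.get("pseudo", False)]

    def pseudo_edges(self) -> list[tuple[str, str]]:
        return [(u, v) for u, v, d in self.graph.edges(data=True) if d.get("pseudo", False)]

    def distance(self, source: str, dest: str) -> float:
        """Great-circle distance in km between two ports of the network."""
        return haversine(self.ports[source].location, self.ports[dest].location)

    def distance_matrix(self) -> tuple[list[str], np.ndarray]:
        ids = self.port_ids
        lats = np.array([self.ports[p].location.lat for p in ids])
        lons = np.array([self.ports[p].location.lon for p in ids])
        return ids, haversine_matrix(lats, lons)

    def copy(self) -> "ShippingNetwork":
        return ShippingNetwork(self.graph.copy(), dict(self.ports), self.augmented)


def aggregate_trips(trips: pd.DataFrame) -> pd.DataFrame:
    """Aggregate raw trip rows into (source, dest, count).

    Accepts either event rows (one row per trip) or pre-aggregated rows with a
    ``count`` column; self-loop rows are dropped with a logged count.
    """
    df = trips.copy()
    if "count" not in df.columns:
        df["count"] = 1
    if (df["count"] < 0).any():
        raise ValueError("trip counts must be non-negative")
    self_loops = df["source"] == df["dest"]
    n_loops = int(self_loops.sum())
    if n_loops:
        logger.info("dropping %d self-loop trip rows", n_loops)
        df = df[~self_loops]
    agg = df.groupby(["source", "dest"], as_index=False)["count"].sum()
    return agg[agg["count"] > 0].reset_index(drop=True)


def build_network(trips: pd.DataFrame, registry: Sequence[Port]) -> ShippingNetwork:
    """Build the directed weighted shipping network from trip records.

    Edge weight w_ij is the total number of trips observed from port i to
    port j; ordered pairs with no trips get no edge. Every port of the
    registry becomes a node even if isolated.
    """
    ports = {p.port_id: p for p in registry}
    if len(ports) != len(registry):
        raise ValueError("duplicate port_id in registry")
    agg = aggregate_trips(trips)
    unknown = set(agg["source"]).union(agg["dest"]) - set(ports)
    if unknown:
        raise KeyError(f"trip rows reference unknown port ids: {sorted(unknown)}")
    g = nx.DiGraph()
    g.add_nodes_from(ports)
    for row in agg.itertuples(index=False):
        g.add_edge(row.source, row.dest, w=float(row.count), pseudo=False)
    return ShippingNetwork(g, ports, augmented=False)


def fully_connect(
    net: ShippingNetwork,
    pseudo_weight: float = DEFAULT_PSEUDO_WEIGHT,
    mode: str = "constant",
) -> ShippingNetwork:
    """Add pseudo-edges so every ordered port pair is connected.

    ``mode="constant"`` assigns the flat ``pseudo_weight`` to every added edge.
    ``mode="inverse_distance"`` assigns weights proportional to 1/d scaled so
    the closest pseudo pair receives ``pseudo_weight`` (an alternative reading
    of low-probability links being distance-discounted).
    """
    if net.augmented:
        raise ValueError("network is already fully connected")
    if pseudo_weight <= 0:
        raise ValueError("pseudo_weight must be positive")
    if mode not in ("constant", "inverse_distance"):
        raise ValueError(f"unknown pseudo-weight mode {mode!r}")
    if net.n_ports() < 2:
        warnings.warn("fully_connect on a network with fewer than 2 ports is a no-op")
        return net
    g = net.graph.copy()
    ids, dmat = net.distance_matrix()
    index = {p: k for k, p in enumerate(ids)}
    missing = [(u, v) for u in ids for v in ids if u != v and not g.has_edge(u, v)]
    if mode == "inverse_distance" and missing:
        dists = np.array([max(dmat[index[u], index[v]], 1.0) for u, v in missing])
        scale = pseudo_weight * dists.min()
        for (u, v), d in zip(missing, dists):
            g.add_edge(u, v, w=float(scale / d), pseudo=True)
    else:
        for u, v in missing:
            g.add_edge(u, v, w=pseudo_weight, pseudo=True)
    return ShippingNetwork(g, dict(net.ports), augmented=True)


def components(net: ShippingNetwork) -> tuple[list[set[str]], list[set[str]]]:
    """Weakly and strongly connected components, as lists of port-id sets."""
    weak = [set(c) for c in nx.weakly_connected_components(net.graph)]
    strong = [set(c) for c in nx.strongly_connected_components(net.graph)]
    return weak, strong


# ---------------------------------------------------------------------------
# External interfaces: CSV registry/trips, GraphML export
# ---------------------------------------------------------------------------

def load_registry(path) -> list[Port]:
    """Read a port registry CSV with header port_id,name,lat,lon,country[,region]."""
    df = pd.read_csv(path, dtype={"port_id": str, "country": str})
    required = {"port_id", "name", "lat", "lon", "country"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"registry missing columns: {sorted(missing)}")
    ports = []
    for row in df.itertuples(index=False):
        region = getattr(row, "region", None)
        if region is not None and (pd.isna(region) or region == ""):
            region = None
        ports.append(
            Port(str(row.port_id), str(row.name), GeoPoint(float(row.lat), float(row.lon)),
                 str(row.country), region)
        )
    return ports


def load_trips(path) -> pd.DataFrame:
    """Read a trips CSV with header source,dest[,count][,year]."""
    df = pd.read_csv(path, dtype={"source": str, "dest": str})
    missing = {"source", "dest"} - set(df.columns)
    if missing:
        raise ValueError(f"trip table missing columns: {sorted(missing)}")
    return df


def save_registry(ports: Iterable[Port], path) -> None:
    pd.DataFrame(
        [
            {
                "port_id": p.port_id,
                "name": p.name,
                "lat": p.location.lat,
                "lon": p.location.lon,
                "country": p.country,
                "region": p.region or "",
            }
            for p in ports
        ]
    ).to_csv(path, index=False)


def to_graphml(net: ShippingNetwork, path, metrics: pd.DataFrame | None = None) -> None:
    """Export the network to GraphML with weight/pseudo edge attributes.

    If a node-metrics table (indexed by port_id) is given, its columns are
    attached as node attributes.
    """
    g = net.graph.copy()
    for pid, port in net.ports.items():
        g.nodes[pid].update(
            name=port.name, lat=port.location.lat, lon=port.location.lon,
            country=port.country, region=port.region or "",
        )
    if metrics is not None:
        for col in metrics.columns:
            nx.set_node_attributes(g, metrics[col].to_dict(), name=col)
    nx.write_graphml(g, path)
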