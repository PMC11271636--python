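"""Shared fixtures: tiny hand-built networks and seeded synthetic worlds."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from shipflow import GeoPoint, Port, build_network
from shipflow.synthetic import WorldConfig, generate


def make_ports(coords: dict[str, tuple[float, float]], country: str = "X",
               countries: dict[str, str] | None = None) -> list[Port]:
    return [
        Port(pid, f"Port {pid}", GeoPoint(lat, lon),
             (countries or {}).get(pid, country))
        for pid, (lat, lon) in coords.items()
    ]


def make_network(edges: dict[tuple[str, str], int],
                 coords: dict[str, tuple[float, float]] | None = None,
                 extra_ports: list[str] = ()):
    """Build a ShippingNetwork from an edge->count dict; default geometry
    spreads ports along the equator two degrees apart."""
    names = sorted({p for e in edges for p in e} | set(extra_ports))
    if coords is None:
        coords = {p: (0.0, 2.0 * i) for i, p in enumerate(names)}
    ports = make_ports(coords)
    trips = pd.DataFrame(
        [{"source": u, "dest": v, "count": c} for (u, v), c in edges.items()],
        columns=["source", "dest", "count"],
    )
    return build_network(trips, ports)


@pytest.fixture(scope="session")
def small_world():
    """A 60-port, 8-region gravity world shared by the slower tests."""
    return generate(WorldConfig(n_ports=60, n_countries=20, n_regions=8, seed=11))


@pytest.fixture(scope="session")
def small_world_net(small_world):
    return build_network(small_world.trips, small_world.ports)


def random_digraph(rng: np.random.Generator, n: int, p: float = 0.3,
                   max_count: int = 5):
    """Random directed graph with integer trip counts; returns (nodes, edges)."""
    nodes = [f"n{i}" for i in range(n)]
    edges = {}
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < p:
                edges[(u, v)] = int(rng.integers(1, max_count + 1))
    return nodes, edges
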