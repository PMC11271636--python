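"""Seeded synthetic shipping worlds.

Real global port-visit data is proprietary, so every pipeline stage is
exercised on generated worlds that reproduce the statistical structure the
method assumes: ports clustered into countries and geographic regions,
heavy-tailed port "masses", origin-destination trip counts following a
gravity law (flow proportional to the mass product and decaying with a power
of distance, realised as Poisson counts so that unstable 1-2-trip links occur
naturally), bilateral trade volumes that track inter-country flows and vanish
within a country, and latitudinally graded temperature/salinity fields.

Defaults describe a mid-size world of 150 ports in 12 regions with gravity
exponent 2 and a flux scale putting a typical port at the order of a hundred
departures per period.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geo import GeoPoint, haversine_matrix
from .network import Port
from .regions import RegionTable, encode_regions
from .risk import EnvVector


@dataclass(frozen=True)
class WorldConfig:
    n_ports: int = 150
    n_countries: int = 40
    n_regions: int = 12
    gravity_exponent: float = 2.0      # gamma: distance-decay power
    flux_scale: float = 1e7            # kappa: overall traffic intensity
    mass_sigma: float = 1.0            # lognormal dispersion of port masses
    min_distance_km: float = 100.0     # distance floor in the gravity law
    trade_scale: float = 1e4           # USD per expected trip, order of magnitude
    trade_noise_sigma: float = 0.3     # multiplicative lognormal trade noise
    detour_factor: float = 1.15        # sea-route / great-circle ratio
    detour_noise: float = 0.05
    temp_gradient: float = 0.4         # degC lost per degree of |latitude|
    temp_noise: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ports < 2:
            raise ValueError("need at least 2 ports")
        if not 1 <= self.n_regions <= 17:
            raise ValueError("n_regions must be in [1, 17]")
        if self.n_countries < self.n_regions:
            raise ValueError("need at least one country per region")
        if self.gravity_exponent <= 0 or self.flux_scale < 0:
            raise ValueError("gravity exponent must be positive, flux scale non-negative")


@dataclass
class SyntheticWorld:
    """A generated world: registry, masses, flows, trade, environments, truth."""

    config: WorldConfig
    ports: list[Port]
    region_mapping: pd.DataFrame
    region_table: RegionTable
    masses: dict[str, float]
    env: dict[str, EnvVector]
    trips: pd.DataFrame | None = None
    expected_flows: np.ndarray | None = None  # lambda matrix, port order = ports
    true_links: set = field(default_factory=set)
    trade: pd.DataFrame | None = None

    @property
    def port_ids(self) -> list[str]:
        return [p.port_id for p in self.ports]

    def flow_lookup(self) -> dict[tuple[str, str], float]:
        """Observed trip counts keyed by (source, dest)."""
        if self.trips is None:
            raise ValueError("flows not generated yet")
        return {
            (r.source, r.dest): float(r.count) for r in self.trips.itertuples(index=False)
        }

    def route_provider(self, a: GeoPoint, b: GeoPoint) -> float:
        """Deterministic pseudo sea-route distance: great-circle times a detour
        factor with coordinate-hashed jitter (no route database involved)."""
        d = haversine_matrix(np.array([a.lat, b.lat]), np.array([a.lon, b.lon]))[0, 1]
        u = np.sin(a.lat * 12.9898 + a.lon * 78.233 + b.lat * 37.719 + b.lon * 4.581)
        jitter = abs(u * 43758.5453) % 1.0
        return d * (self.config.detour_factor + self.config.detour_noise * jitter)


def _wrap_lon(lon: np.ndarray) -> np.ndarray:
    out = (lon + 180.0) % 360.0 - 180.0
    return np.where(out <= -180.0, out + 360.0, out)


def generate_world(cfg: WorldConfig) -> SyntheticWorld:
    """Generate ports, countries, regions, masses and environmental fields."""
    root = np.random.SeedSequence(cfg.seed)
    rng_geo, rng_mass, rng_env = (np.random.default_rng(s) for s in root.spawn(3))

    regions = [f"R{i:02d}" for i in range(cfg.n_regions)]
    countries = [f"C{i:02d}" for i in range(cfg.n_countries)]
    country_region = {c: regions[i % cfg.n_regions] for i, c in enumerate(countries)}

    region_lat = rng_geo.uniform(-50.0, 50.0, cfg.n_regions)
    region_lon = rng_geo.uniform(-180.0, 180.0, cfg.n_regions)
    country_lat, country_lon = {}, {}
    for i, c in enumerate(countries):
        r = i % cfg.n_regions
        country_lat[c] = np.clip(region_lat[r] + rng_geo.normal(0.0, 8.0), -62.0, 62.0)
        country_lon[c] = _wrap_lon(np.array([region_lon[r] + rng_geo.normal(0.0, 10.0)]))[0]

    port_country = [countries[i % cfg.n_countries] for i in range(cfg.n_ports)]
    ports = []
    for i in range(cfg.n_ports):
        c = port_country[i]
        lat = float(np.clip(country_lat[c] + rng_geo.normal(0.0, 3.0), -65.0, 65.0))
        lon = float(_wrap_lon(np.array([country_lon[c] + rng_geo.normal(0.0, 4.0)]))[0])
        pid = f"P{i:03d}"
        ports.append(Port(pid, f"Port {pid}", GeoPoint(lat, lon), c, country_region[c]))

    masses = {p.port_id: float(m) for p, m in
              zip(ports, rng_mass.lognormal(0.0, cfg.mass_sigma, cfg.n_ports))}

    env = {}
    for p in ports:
        lat = abs(p.location.lat)
        t_annual = 28.0 - cfg.temp_gradient * lat + rng_env.normal(0.0, cfg.temp_noise)
        half = 4.0 + 0.08 * lat + abs(rng_env.normal(0.0, 1.0))
        s_annual = 35.0 - 0.02 * lat + rng_env.normal(0.0, 1.2)
        env[p.port_id] = EnvVector(t_annual - half, t_annual + half, t_annual, s_annual)

    mapping = pd.DataFrame(
        {"country": countries, "region": [country_region[c] for c in countries]}
    )
    table = encode_regions(ports, mapping)
    return SyntheticWorld(cfg, ports, mapping, table, masses, env)


def generate_flows(world: SyntheticWorld) -> SyntheticWorld:
    """Draw gravity-law trip counts: lambda_ij = kappa m_i m_j / d_ij^gamma,
    trips ~ Poisson(lambda), zero-count pairs are non-links."""
    cfg = world.config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(5)[3])
    ids = world.port_ids
    lats = np.array([p.location.lat for p in world.ports])
    lons = np.array([p.location.lon for p in world.ports])
    d = np.maximum(haversine_matrix(lats, lons), cfg.min_distance_km)
    m = np.array([world.masses[p] for p in ids])
    lam = cfg.flux_scale * np.outer(m, m) / d ** cfg.gravity_exponent
    np.fill_diagonal(lam, 0.0)
    counts = rng.poisson(lam)
    src, dst = np.nonzero(counts)
    trips = pd.DataFrame(
        {
            "source": [ids[i] for i in src],
            "dest": [ids[j] for j in dst],
            "count": counts[src, dst].astype(int),
        }
    )
    world = replace_fields(world, trips=trips, expected_flows=lam,
                           true_links={(ids[i], ids[j]) for i, j in zip(src, dst)})
    return world


def generate_trade(world: SyntheticWorld) -> SyntheticWorld:
    """Country-pair trade volumes proportional to aggregated expected flows with
    multiplicative lognormal noise; intra-country trade is exactly zero."""
    cfg = world.config
    if world.expected_flows is None:
        raise ValueError("generate flows before trade")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(5)[4])
    ids = world.port_ids
    country_of = {p.port_id: p.country for p in world.ports}
    countries = sorted({p.country for p in world.ports})
    cindex = {c: k for k, c in enumerate(countries)}
    agg = np.zeros((len(countries), len(countries)))
    for a, pa in enumerate(ids):
        for b, pb in enumerate(ids):
            agg[cindex[country_of[pa]], cindex[country_of[pb]]] += world.expected_flows[a, b]
    rows = []
    for a, ca in enumerate(countries):
        for b, cb in enumerate(countries):
            if a == b:
                continue
            usd = cfg.trade_scale * agg[a, b] * rng.lognormal(0.0, cfg.trade_noise_sigma)
            rows.append({"exporter": ca, "importer": cb, "usd": float(usd)})
    return replace_fields(
        world, trade=pd.DataFrame(rows, columns=["exporter", "importer", "usd"]))


def generate(cfg: WorldConfig) -> SyntheticWorld:
    """Full world: geography/environment, gravity flows and trade in one call."""
    return generate_trade(generate_flows(generate_world(cfg)))


def replace_fields(world: SyntheticWorld, **kw) -> SyntheticWorld:
    data = {f: getattr(world, f) for f in (
        "config", "ports", "region_mapping", "region_table", "masses", "env",
        "trips", "expected_flows", "true_links", "trade")}
    data.update(kw)
    return SyntheticWorld(**data)
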