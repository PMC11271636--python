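"""Destination-region encoding.

Ports are grouped into at most 17 geographical regions (by country), the
prediction classes of the flow model: ports within a region are assumed to
share broadly similar habitat, which is also what makes regions the natural
unit for ballast-water risk aggregation. A default country-to-region table
with 17 UN-style subregion tokens ships with the package and can be replaced
by any ``country,region`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence

import pandas as pd

from .geo import GeoPoint, spherical_centroid
from .network import Port

MAX_REGIONS = 17


def default_region_mapping() -> pd.DataFrame:
    """The bundled country-to-region table (17 region tokens)."""
    with resources.files("shipflow.data").joinpath("country_regions.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class RegionTable:
    """Region encoding: country->region map, member ports and region centroids."""

    country_to_region: dict[str, str]
    region_ports: dict[str, list[str]]
    centroids: dict[str, GeoPoint]

    @property
    def regions(self) -> list[str]:
        return sorted(self.region_ports)

    def region_of_port(self, port: Port) -> str:
        return self.country_to_region[port.country]

    def assign(self, registry: Sequence[Port]) -> list[Port]:
        """Return a copy of the registry with each port's region filled in."""
        return [replace(p, region=self.country_to_region[p.country]) for p in registry]


def encode_regions(
    registry: Sequence[Port],
    mapping: pd.DataFrame | None = None,
) -> RegionTable:
    """Build the region encoding for a port registry.

    ``mapping`` is a ``country,region`` table (default: the bundled one).
    Every country in the registry must be mapped; region centroids are
    computed from member-port locations on the unit sphere.
    """
    if mapping is None:
        mapping = default_region_mapping()
    if not {"country", "region"} <= set(mapping.columns):
        raise ValueError("region mapping needs 'country' and 'region' columns")
    c2r = dict(zip(mapping["country"].astype(str), mapping["region"].astype(str)))
    if len(set(c2r.values())) > MAX_REGIONS:
        raise ValueError(
            f"mapping defines {len(set(c2r.values()))} regions; at most {MAX_REGIONS} allowed"
        )
    unmapped = sorted({p.country for p in registry} - set(c2r))
    if unmapped:
        raise KeyError(f"countries missing from the region mapping: {unmapped}")
    region_ports: dict[str, list[str]] = {}
    region_locs: dict[str, list[GeoPoint]] = {}
    for p in registry:
        r = c2r[p.country]
        region_ports.setdefault(r, []).append(p.port_id)
        region_locs.setdefault(r, []).append(p.location)
    centroids = {r: spherical_centroid(locs) for r, locs in region_locs.items()}
    return RegionTable(c2r, region_ports, centroids)
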