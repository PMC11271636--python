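"""Assembly of gravity-model feature vectors.

Each training sample corresponds to one source port and its N candidate
destination regions (1 <= N <= 17). Every (source port, destination region)
pair carries a fixed-order 10-feature vector:

 1. origin port flux (total departures from the source port)
 2. destination region flux (total arrivals into the region's ports)
 3. great-circle distance from the source port to the region centroid (km)
 4. bilateral trade volume (USD) exported from the source country to the
    region's countries; zero for the source's own country
 5. origin betweenness centrality
 6. region median betweenness centrality
 7. origin closeness centrality
 8. region median closeness centrality
 9. origin PageRank
10. region median PageRank

The feature order is frozen: downstream model weights and golden tests depend
on it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geo import haversine
from .network import ShippingNetwork
from .regions import RegionTable

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "origin_flux",
    "dest_region_flux",
    "distance_km",
    "bilateral_trade_usd",
    "origin_betweenness",
    "region_median_betweenness",
    "origin_closeness",
    "region_median_closeness",
    "origin_pagerank",
    "region_median_pagerank",
)
N_FEATURES = len(FEATURE_NAMES)


@dataclass
class ODSample:
    """One source port with its candidate destination regions.

    ``X`` has one row per region in ``regions`` order; ``y`` holds the
    observed trips into each region and ``O_i`` the total departures from the
    source port.
    """

    source: str
    regions: list[str]
    X: np.ndarray
    O_i: float
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.regions)
        if not 1 <= n <= 17:
            raise ValueError(f"sample {self.source!r}: N={n} outside [1, 17]")
        if self.X.shape != (n, N_FEATURES):
            raise ValueError(f"sample {self.source!r}: X shape {self.X.shape} != ({n}, {N_FEATURES})")
        if self.y.shape != (n,) or (self.y < 0).any():
            raise ValueError(f"sample {self.source!r}: invalid y")
        if self.O_i <= 0:
            raise ValueError(f"sample {self.source!r}: O_i must be positive")
        if self.y.sum() > self.O_i + 1e-6:
            raise ValueError(f"sample {self.source!r}: sum(y) exceeds O_i")


def _trade_lookup(trade: pd.DataFrame) -> dict[tuple[str, str], float]:
    if not {"exporter", "importer", "usd"} <= set(trade.columns):
        raise ValueError("trade table needs exporter,importer,usd columns")
    return {
        (str(r.exporter), str(r.importer)): float(r.usd)
        for r in trade.itertuples(index=False)
    }


def assemble_samples(
    net: ShippingNetwork,
    metrics: pd.DataFrame,
    regions: RegionTable,
    trade: pd.DataFrame,
    retained_links: Iterable[tuple[str, str]],
) -> list[ODSample]:
    """Build one ODSample per source port with at least one retained destination.

    ``metrics`` must be the node-metrics table of the un-augmented network;
    ``retained_links`` is the set of port pairs that survived link screening.
    The candidate region list of a source is the distinct regions of its
    retained destination ports; observed flows count all real trips from the
    source into each candidate region.
    """
    missing_metric = set(net.port_ids) - set(metrics.index)
    if missing_metric:
        raise KeyError(f"metrics missing for ports: {sorted(missing_metric)}")
    trade_map = _trade_lookup(trade)
    missing_trade = 0

    out_flux: dict[str, float] = {p: 0.0 for p in net.port_ids}
    region_influx: dict[str, float] = {r: 0.0 for r in regions.regions}
    flows: dict[tuple[str, str], float] = {}
    port_region = {p: regions.region_of_port(net.ports[p]) for p in net.port_ids}
    for u, v in net.real_edges():
        w = net.weight(u, v)
        out_flux[u] += w
        region_influx[port_region[v]] += w
        flows[(u, v)] = w

    # Region medians over member ports present in the network.
    region_median = {}
    for r in regions.regions:
        members = [p for p in regions.region_ports[r] if p in metrics.index]
        sub = metrics.loc[members]
        region_median[r] = {
            col: float(sub[col].median()) if len(sub) else 0.0
            for col in ("betweenness", "closeness", "pagerank")
        }

    by_source: dict[str, set[str]] = {}
    for s, d in retained_links:
        if s == d:
            continue
        by_source.setdefault(s, set()).add(d)

    samples = []
    for s in sorted(by_source):
        dest_regions = sorted({port_region[d] for d in by_source[s]})
        O_i = out_flux[s]
        if O_i <= 0:
            continue
        src_port = net.ports[s]
        src_country = src_port.country
        X = np.zeros((len(dest_regions), N_FEATURES))
        y = np.zeros(len(dest_regions))
        for k, r in enumerate(dest_regions):
            trade_sum = 0.0
            for country in sorted({net.ports[p].country for p in regions.region_ports[r]}):
                if country == src_country:
                    continue  # intra-country trade is zero by definition
                if (src_country, country) in trade_map:
                    trade_sum += trade_map[(src_country, country)]
                else:
                    missing_trade += 1
            med = region_median[r]
            X[k] = (
                O_i,
                region_influx[r],
                haversine(src_port.location, regions.centroids[r]),
                trade_sum,
                float(metrics.at[s, "betweenness"]),
                med["betweenness"],
                float(metrics.at[s, "closeness"]),
                med["closeness"],
                float(metrics.at[s, "pagerank"]),
                med["pagerank"],
            )
            y[k] = sum(
                flows.get((s, p), 0.0) for p in regions.region_ports[r] if p in net.ports
            )
        samples.append(ODSample(s, dest_regions, X, float(O_i), y))
    if missing_trade:
        logger.info("%d country pairs missing from the trade table treated as 0", missing_trade)
    return samples


@dataclass
class FeatureScaler:
    """Per-feature z-scoring with statistics from the training split only."""

    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray = field(default=None)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.sd + self.mean


def fit_scaler(samples: Sequence[ODSample]) -> FeatureScaler:
    """Fit z-scoring statistics on the pooled feature rows of ``samples``.

    Constant features (zero spread) are passed through unscaled and flagged.
    """
    rows = np.vstack([s.X for s in samples])
    mean = rows.mean(axis=0)
    sd = rows.std(axis=0)
    constant = sd <= 0
    if constant.any():
        names = [FEATURE_NAMES[i] for i in np.flatnonzero(constant)]
        logger.warning("constant features passed through unscaled: %s", names)
        mean = np.where(constant, 0.0, mean)
        sd = np.where(constant, 1.0, sd)
    return FeatureScaler(mean, sd, constant)


def scale_features(
    samples: Sequence[ODSample], scaler: FeatureScaler | None = None
) -> tuple[list[ODSample], FeatureScaler]:
    """Z-score sample features; fits the scaler on ``samples`` when not given."""
    if scaler is None:
        scaler = fit_scaler(samples)
    scaled = [
        ODSample(s.source, list(s.regions), scaler.transform(s.X), s.O_i, s.y.copy())
        for s in samples
    ]
    return scaled, scaler


def samples_to_jsonl(samples: Sequence[ODSample], path) -> None:
    with open(path, "w") as fh:
        for s in samples:
            fh.write(json.dumps({
                "source": s.source, "regions": s.regions,
                "X": s.X.tolist(), "O_i": s.O_i, "y": s.y.tolist(),
            }) + "\n")


def samples_from_jsonl(path) -> list[ODSample]:
    samples = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            samples.append(ODSample(d["source"], d["regions"], np.array(d["X"]),
                                    d["O_i"], np.array(d["y"])))
    return samples
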