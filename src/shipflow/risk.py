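"""Ballast-water risk stage: environmental distances weighted by shipping flows.

Each port carries a 4-component environmental vector (annual minimum, maximum
and mean sea-surface temperature, and annual salinity). The environmental
distance of an origin-destination link is the Euclidean distance between the
two vectors; a small distance means similar habitats and hence a higher
chance that organisms carried in ballast water survive at the destination.
Weighting each link's distance by its trip count gives an empirical
distribution of shipping activity over risk levels, comparable between
observed and model-predicted flows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_BINS = 50


@dataclass(frozen=True)
class EnvVector:
    """Port environment: min/max/mean annual temperature (degC), salinity (PSU)."""

    t_min: float
    t_max: float
    t_annual: float
    s_annual: float

    def __post_init__(self) -> None:
        vals = (self.t_min, self.t_max, self.t_annual, self.s_annual)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("environmental components must be finite")
        if not self.t_min <= self.t_annual <= self.t_max:
            raise ValueError(
                f"temperature ordering violated: {self.t_min} <= {self.t_annual} <= {self.t_max}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.t_min, self.t_max, self.t_annual, self.s_annual])


def env_distance(a: EnvVector, b: EnvVector, scale: np.ndarray | None = None) -> float:
    """Euclidean distance between two environmental vectors.

    ``scale`` optionally divides each component (e.g. by per-component
    standard deviations) before the distance is taken, for the standardised
    variant; by default components enter in their native units.
    """
    diff = a.as_array() - b.as_array()
    if scale is not None:
        diff = diff / np.asarray(scale, dtype=float)
    return float(np.sqrt((diff ** 2).sum()))


def env_scale(env: dict[str, EnvVector]) -> np.ndarray:
    """Per-component standard deviations over a port environment table."""
    arr = np.vstack([v.as_array() for v in env.values()])
    sd = arr.std(axis=0)
    return np.where(sd > 0, sd, 1.0)


@dataclass
class RiskDistribution:
    """Trip-weighted empirical distribution of environmental distances.

    ``pairs`` holds one (source, dest, d_env, weight) row per OD link;
    ``hist`` is the total weight per bin of ``bin_edges``.
    """

    pairs: pd.DataFrame
    bin_edges: np.ndarray
    hist: np.ndarray

    @property
    def total_weight(self) -> float:
        return float(self.pairs["weight"].sum())


def weight_distribution(
    flows: dict[tuple[str, str], float],
    env: dict[str, EnvVector],
    bins: int = DEFAULT_BINS,
    bin_max: float | None = None,
    standardized: bool = False,
) -> RiskDistribution:
    """Build the trip-weighted environmental-distance distribution of a flow set.

    ``bin_max`` fixes the histogram span so compared distributions share a
    grid; it defaults to the maximum observed distance of these flows.
    ``standardized=True`` z-scales the components by their spread across the
    port table before distances are taken.
    """
    ports = {p for link in flows for p in link}
    missing = sorted(ports - set(env))
    if missing:
        raise KeyError(f"ports missing an environmental vector: {missing}")
    scale = env_scale(env) if standardized else None
    rows = [
        {"source": s, "dest": d, "d_env": env_distance(env[s], env[d], scale), "weight": float(w)}
        for (s, d), w in sorted(flows.items())
    ]
    pairs = pd.DataFrame(rows, columns=["source", "dest", "d_env", "weight"])
    if bin_max is None:
        bin_max = float(pairs["d_env"].max()) if len(pairs) else 1.0
    if bin_max <= 0:
        bin_max = 1.0
    edges = np.linspace(0.0, bin_max, bins + 1)
    hist, _ = np.histogram(
        np.clip(pairs["d_env"], 0.0, bin_max), bins=edges, weights=pairs["weight"]
    )
    return RiskDistribution(pairs, edges, hist)


def compare_distributions(
    pred: RiskDistribution, truth: RiskDistribution, method: str = "binned"
) -> dict:
    """Agreement between predicted and observed risk distributions.

    ``binned`` correlates the per-bin weights on the shared grid (and reports
    the total-variation distance between the normalised histograms);
    ``pairs`` correlates per-link weights over the union of OD links.
    """
    if method == "binned":
        if pred.bin_edges.shape != truth.bin_edges.shape or not np.allclose(
            pred.bin_edges, truth.bin_edges
        ):
            raise ValueError("distributions must share the same bin grid")
        a, b = pred.hist.astype(float), truth.hist.astype(float)
        if np.std(a) == 0 or np.std(b) == 0:
            return {"pearson": float("nan"), "total_variation": _tv(a, b),
                    "method": method, "degenerate": True}
        return {"pearson": _pearson(a, b), "total_variation": _tv(a, b),
                "method": method, "degenerate": False}
    if method == "pairs":
        key = ["source", "dest"]
        merged = pred.pairs.merge(truth.pairs, on=key, how="outer", suffixes=("_p", "_t"))
        a = merged["weight_p"].fillna(0.0).to_numpy()
        b = merged["weight_t"].fillna(0.0).to_numpy()
        if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
            return {"pearson": float("nan"), "total_variation": float("nan"),
                    "method": method, "degenerate": True}
        return {"pearson": _pearson(a, b), "total_variation": float("nan"),
                "method": method, "degenerate": False}
    raise ValueError(f"unknown method {method!r}")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    # identical inputs must correlate at exactly 1.0, not 1 - eps
    if np.array_equal(a, b):
        return 1.0
    return float(stats.pearsonr(a, b).statistic)


def _tv(a: np.ndarray, b: np.ndarray) -> float:
    pa = a / a.sum() if a.sum() > 0 else a
    pb = b / b.sum() if b.sum() > 0 else b
    return float(0.5 * np.abs(pa - pb).sum())


def load_env_table(path) -> dict[str, EnvVector]:
    """Read a port environment CSV: port_id,t_min,t_max,t_annual,s_annual."""
    df = pd.read_csv(path, dtype={"port_id": str})
    required = {"port_id", "t_min", "t_max", "t_annual", "s_annual"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"environment table missing columns: {sorted(missing)}")
    return {
        str(r.port_id): EnvVector(float(r.t_min), float(r.t_max), float(r.t_annual),
                                  float(r.s_annual))
        for r in df.itertuples(index=False)
    }


def save_env_table(env: dict[str, EnvVector], path) -> None:
    pd.DataFrame(
        [
            {"port_id": p, "t_min": v.t_min, "t_max": v.t_max,
             "t_annual": v.t_annual, "s_annual": v.s_annual}
            for p, v in env.items()
        ]
    ).to_csv(path, index=False)
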