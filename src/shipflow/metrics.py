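"""Node-level graph metrics of a shipping network.

Four metrics feed the gravity-model feature set: betweenness centrality
(unnormalised sum over ordered pairs), closeness centrality over outgoing
shortest paths, PageRank on the trip-weighted transition matrix, and
straightness centrality (mean ratio of great-circle to network shortest-path
distance).

``weight_mode`` selects how trip counts enter shortest-path lengths:

- ``"trips"`` (default): edge length = trip count, the weights used directly;
- ``"reciprocal"``: edge length = 1 / trip count, interpreting heavy routes
  as short (weights as distances);
- ``"unweighted"``: hop counts.

Centrality rankings on sparse heavy-tailed shipping networks are largely
insensitive to this choice; both conventions are provided.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .network import ShippingNetwork

WEIGHT_MODES = ("trips", "reciprocal", "unweighted")

_LENGTH_ATTR = "_len"


def _with_lengths(net: ShippingNetwork, weight_mode: str) -> nx.DiGraph:
    if weight_mode not in WEIGHT_MODES:
        raise ValueError(f"weight_mode must be one of {WEIGHT_MODES}, got {weight_mode!r}")
    g = net.graph.copy()
    if weight_mode == "unweighted":
        return g
    for _, _, data in g.edges(data=True):
        w = data["w"]
        data[_LENGTH_ATTR] = float(w) if weight_mode == "trips" else 1.0 / float(w)
    return g


def betweenness(net: ShippingNetwork, weight_mode: str = "trips") -> dict[str, float]:
    """Betweenness centrality: sum over ordered pairs (u, v), u != v != i, of the
    fraction of shortest u->v paths passing through i. Unnormalised; pairs with
    no path contribute zero."""
    if net.n_ports() == 0:
        raise ValueError("empty network")
    g = _with_lengths(net, weight_mode)
    attr = None if weight_mode == "unweighted" else _LENGTH_ATTR
    return {k: float(v) for k, v in
            nx.betweenness_centrality(g, normalized=False, weight=attr).items()}


def closeness(net: ShippingNetwork, weight_mode: str = "trips") -> dict[str, float]:
    """Closeness centrality over outgoing shortest-path distances.

    For node i with r reachable other nodes out of |V|-1, the value is
    ``(r / sum of distances) * (r / (|V|-1))``: the classical
    (|V|-1)/sum-of-distances form on strongly connected graphs, scaled by the
    reachable fraction otherwise. Nodes that reach nothing get 0.
    """
    if net.n_ports() == 0:
        raise ValueError("empty network")
    g = _with_lengths(net, weight_mode)
    attr = None if weight_mode == "unweighted" else _LENGTH_ATTR
    # networkx closeness uses incoming paths; reverse to measure outgoing.
    vals = nx.closeness_centrality(g.reverse(), distance=attr, wf_improved=True)
    return {k: float(v) for k, v in vals.items()}


def pagerank(
    net: ShippingNetwork,
    damping: float = 0.85,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> dict[str, float]:
    """Stationary distribution of the damped random walk with transition
    probabilities proportional to trip counts; dangling nodes redistribute
    uniformly. Values sum to 1.

    Reinterpreting weights as distances (the ``reciprocal`` mode of the
    shortest-path metrics) does not alter a walk's transition probabilities,
    so PageRank has no weight_mode: ships still follow traffic volumes.
    """
    if net.n_ports() == 0:
        raise ValueError("empty network")
    try:
        pr = nx.pagerank(net.graph, alpha=damping, tol=tol, max_iter=max_iter, weight="w")
    except nx.PowerIterationFailedConvergence as exc:
        raise RuntimeError(f"PageRank failed to converge within {max_iter} iterations") from exc
    return {k: float(v) for k, v in pr.items()}


def straightness(net: ShippingNetwork) -> dict[str, float]:
    """Straightness centrality: mean over reachable targets j of the ratio of
    the great-circle distance d^E_ij to the network shortest-path distance
    d^N_ij, divided by |V|-1. Edge lengths for d^N are great-circle km, so
    the ratio lies in (0, 1] and unreachable targets contribute 0."""
    ids = net.port_ids
    n = len(ids)
    if n == 0:
        raise ValueError("empty network")
    if n == 1:
        return {ids[0]: 0.0}
    index = {p: k for k, p in enumerate(ids)}
    _, dmat = net.distance_matrix()
    g = net.graph.copy()
    for u, v, data in g.edges(data=True):
        data["_km"] = max(dmat[index[u], index[v]], 0.0)
    out = {}
    for i in ids:
        lengths = nx.single_source_dijkstra_path_length(g, i, weight="_km")
        total = 0.0
        for j, dn in lengths.items():
            if j == i:
                continue
            de = dmat[index[i], index[j]]
            if dn <= 0.0:
                # Coincident ports: geodesic equals path length (both zero).
                total += 1.0 if de <= 0.0 else 0.0
            else:
                total += de / dn
        out[i] = total / (n - 1)
    return out


def node_metrics(net: ShippingNetwork, weight_mode: str = "trips") -> pd.DataFrame:
    """All four node metrics as a DataFrame indexed by port_id.

    Computed on the un-augmented network by convention: pseudo-edges would
    otherwise distort shortest paths and walk probabilities.
    """
    bt = betweenness(net, weight_mode)
    cl = closeness(net, weight_mode)
    pr = pagerank(net)
    st = straightness(net)
    df = pd.DataFrame({"betweenness": bt, "closeness": cl, "pagerank": pr, "straightness": st})
    df.index.name = "port_id"
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError("non-finite metric value computed")
    return df
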