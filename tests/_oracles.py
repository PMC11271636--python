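"""Independent brute-force oracles for graph metrics on tiny graphs.

Everything here enumerates simple paths or iterates dense matrices directly,
without networkx, so the production metric implementations can be checked
against an unrelated computation path. Only sensible for <= 8 nodes.
"""

from __future__ import annotations

import numpy as np

REL_TOL = 1e-12


def enumerate_shortest_paths(nodes, lengths):
    """All shortest simple paths per ordered pair.

    ``lengths`` maps (u, v) -> positive edge length. Returns a dict
    (u, v) -> (distance, list of node-tuples); unreachable pairs are absent.
    """
    adj = {u: [] for u in nodes}
    for (u, v), w in lengths.items():
        adj[u].append((v, w))
    result = {}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            all_paths = []
            stack = [(s, 0.0, (s,))]
            while stack:
                node, dist, path = stack.pop()
                if node == t:
                    all_paths.append((dist, path))
                    continue
                for nxt, w in adj[node]:
                    if nxt not in path:
                        stack.append((nxt, dist + w, path + (nxt,)))
            if all_paths:
                best = min(d for d, _ in all_paths)
                paths = [p for d, p in all_paths
                         if abs(d - best) <= REL_TOL * max(1.0, best)]
                result[(s, t)] = (best, paths)
    return result


def _plen(path, lengths):
    return sum(lengths[(path[i], path[i + 1])] for i in range(len(path) - 1))


def betweenness_oracle(nodes, lengths):
    sp = enumerate_shortest_paths(nodes, lengths)
    out = {n: 0.0 for n in nodes}
    for (u, v), (_, paths) in sp.items():
        sigma = len(paths)
        for i in nodes:
            if i in (u, v):
                continue
            through = sum(1 for p in paths if i in p)
            out[i] += through / sigma
    return out


def closeness_oracle(nodes, lengths):
    sp = enumerate_shortest_paths(nodes, lengths)
    n = len(nodes)
    out = {}
    for i in nodes:
        dists = [d for (u, v), (d, _) in sp.items() if u == i]
        r = len(dists)
        if r == 0 or sum(dists) == 0:
            out[i] = 0.0
        else:
            out[i] = (r / sum(dists)) * (r / (n - 1))
    return out


def straightness_oracle(nodes, lengths, geo_dist):
    """geo_dist maps (i, j) -> great-circle km; lengths are the km edge lengths."""
    sp = enumerate_shortest_paths(nodes, lengths)
    n = len(nodes)
    out = {}
    for i in nodes:
        total = 0.0
        for j in nodes:
            if j == i or (i, j) not in sp:
                continue
            dn = sp[(i, j)][0]
            de = geo_dist[(i, j)]
            total += (1.0 if de <= 0 else 0.0) if dn <= 0 else de / dn
        out[i] = total / (n - 1)
    return out


def pagerank_oracle(nodes, weights, damping=0.85, iters=10_000, tol=1e-13):
    """Dense power iteration on the damped trip-weighted transition matrix."""
    n = len(nodes)
    idx = {u: k for k, u in enumerate(nodes)}
    W = np.zeros((n, n))
    for (u, v), w in weights.items():
        W[idx[u], idx[v]] = w
    row = W.sum(axis=1)
    P = np.where(row[:, None] > 0, W / np.where(row[:, None] > 0, row[:, None], 1.0), 1.0 / n)
    pi = np.full(n, 1.0 / n)
    for _ in range(iters):
        new = damping * pi @ P + (1 - damping) / n
        if np.abs(new - pi).sum() < tol:
            pi = new
            break
        pi = new
    return {u: pi[idx[u]] for u in nodes}


def components_oracle(nodes, edges):
    """Weak/strong components from boolean reachability closure."""
    n = len(nodes)
    idx = {u: k for k, u in enumerate(nodes)}
    A = np.zeros((n, n), dtype=int)
    for u, v in edges:
        A[idx[u], idx[v]] = 1
    R = (A + np.eye(n, dtype=int) > 0).astype(int)
    for _ in range(n):
        R = (R + R @ R > 0).astype(int)
    strong_key = {u: tuple((R[idx[u]] * R[:, idx[u]]).tolist()) for u in nodes}
    U = (R + R.T > 0).astype(int)
    for _ in range(n):
        U = (U + U @ U > 0).astype(int)
    weak_key = {u: tuple(U[idx[u]].tolist()) for u in nodes}
    def group(keys):
        groups = {}
        for u, k in keys.items():
            groups.setdefault(k, set()).add(u)
        return sorted(groups.values(), key=lambda s: sorted(s))
    return group(weak_key), group(strong_key)
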