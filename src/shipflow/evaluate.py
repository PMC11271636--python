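"""Flow allocation and evaluation metrics.

A model scores the N candidate destination regions of a source port; the
predicted flows are the total outflow O_i multiplied by the softmax of the
scores, so predictions conserve flow by construction. Agreement with the
observed flows is measured by the Common Part of Commuters (CPC),

    CPC(yhat, y) = 2 sum_j min(yhat_j, y_j) / (sum_j yhat_j + sum_j y_j),

averaged over source ports, plus the normalised root-mean-square error
(NRMSE) and the Pearson correlation. NRMSE and correlation are pooled over
all (source, region) pairs by default; a per-source mean variant is
available since the per-source definitions leave the cross-source
aggregation open.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import stats


def allocate_flows(scores: np.ndarray, O_i: float) -> np.ndarray:
    """Distribute the total outflow over destinations: yhat = O_i * softmax(scores)."""
    if O_i <= 0:
        raise ValueError("O_i must be positive")
    s = np.asarray(scores, dtype=float)
    e = np.exp(s - s.max())
    return O_i * e / e.sum()


def cross_entropy(scores: np.ndarray, y: np.ndarray) -> float:
    """Cross-entropy between observed flows and the softmax of the scores,
    computed through a numerically stable log-softmax: -sum_j y_j log p_j."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    if (y < 0).any() or y.sum() <= 0:
        raise ValueError("observed flows must be non-negative with positive total")
    logp = s - s.max()
    logp = logp - np.log(np.exp(logp).sum())
    return float(-(y * logp).sum())


def cpc(yhat: np.ndarray, y: np.ndarray) -> float:
    """Common Part of Commuters for one source port; in [0, 1]."""
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    if yhat.shape != y.shape:
        raise ValueError("prediction and observation lengths differ")
    if (yhat < 0).any() or (y < 0).any():
        raise ValueError("flows must be non-negative")
    denom = yhat.sum() + y.sum()
    if denom <= 0:
        warnings.warn("CPC of two all-zero flow vectors defined as 1")
        return 1.0
    return float(2.0 * np.minimum(yhat, y).sum() / denom)


def mean_cpc(pairs: Sequence[tuple[np.ndarray, np.ndarray]]) -> float:
    """Per-source CPC summed over the M samples and divided by M."""
    if not pairs:
        raise ValueError("no samples")
    return float(np.mean([cpc(yh, y) for yh, y in pairs]))


def nrmse(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]], aggregate: str = "pooled"
) -> float:
    """Normalised RMSE of predicted vs observed flows.

    ``pooled`` concatenates all (source, region) pairs and normalises by the
    observed range; ``per_source`` averages the per-source NRMSE over sources
    with a non-degenerate observed range. NaN when no range is available.
    """
    if aggregate == "pooled":
        y = np.concatenate([np.asarray(p[1], dtype=float) for p in pairs])
        yh = np.concatenate([np.asarray(p[0], dtype=float) for p in pairs])
        span = y.max() - y.min()
        if span <= 0:
            return float("nan")
        return float(np.sqrt(np.mean((y - yh) ** 2)) / span)
    if aggregate == "per_source":
        vals = []
        for yh, y in pairs:
            y = np.asarray(y, dtype=float)
            yh = np.asarray(yh, dtype=float)
            span = y.max() - y.min()
            if span > 0:
                vals.append(np.sqrt(np.mean((y - yh) ** 2)) / span)
        return float(np.mean(vals)) if vals else float("nan")
    raise ValueError(f"unknown aggregate {aggregate!r}")


def corr(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]], aggregate: str = "pooled"
) -> float:
    """Pearson correlation of predicted vs observed flows (pooled or per-source
    mean); NaN when a variance is degenerate."""
    if aggregate == "pooled":
        y = np.concatenate([np.asarray(p[1], dtype=float) for p in pairs])
        yh = np.concatenate([np.asarray(p[0], dtype=float) for p in pairs])
        if len(y) < 2 or np.std(y) == 0 or np.std(yh) == 0:
            return float("nan")
        return float(stats.pearsonr(yh, y).statistic)
    if aggregate == "per_source":
        vals = []
        for yh, y in pairs:
            y = np.asarray(y, dtype=float)
            yh = np.asarray(yh, dtype=float)
            if len(y) >= 2 and np.std(y) > 0 and np.std(yh) > 0:
                vals.append(stats.pearsonr(yh, y).statistic)
        return float(np.mean(vals)) if vals else float("nan")
    raise ValueError(f"unknown aggregate {aggregate!r}")


def uniform_baseline(pairs_regions: Sequence[tuple[int, float]]) -> list[np.ndarray]:
    """The no-information allocation yhat_j = O_i / N for each (N, O_i)."""
    return [np.full(n, o / n) for n, o in pairs_regions]
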