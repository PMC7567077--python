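"""Independent brute-force oracles for the statistical machinery.

Everything here is written from first principles (explicit rank, margin and
pair-enumeration formulas) and never calls the package or scipy's test
functions, so it can serve as an independent cross-check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def midranks(x) -> np.ndarray:
    """Average ranks (1-based) with ties shared, by direct comparison."""
    x = np.asarray(x, dtype=float)
    ranks = np.empty(len(x))
    for i, v in enumerate(x):
        ranks[i] = 1 + np.sum(x < v) + (np.sum(x == v) - 1) / 2.0
    return ranks


def kruskal_wallis_oracle(samples: list[np.ndarray]) -> float:
    """Tie-corrected H from the textbook rank formula."""
    pooled = np.concatenate(samples)
    n = len(pooled)
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for s in samples:
        r = ranks[start : start + len(s)]
        h += len(s) * (r.mean() - (n + 1) / 2.0) ** 2
        start += len(s)
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


def chi_squared_oracle(table: np.ndarray) -> tuple[float, int]:
    """Pearson X^2 and df from explicit row/column margins."""
    T = np.asarray(table, dtype=float)
    total = T.sum()
    x2 = 0.0
    for i in range(T.shape[0]):
        for j in range(T.shape[1]):
            e = T[i].sum() * T[:, j].sum() / total
            x2 += (T[i, j] - e) ** 2 / e
    return x2, (T.shape[0] - 1) * (T.shape[1] - 1)


def kendall_tau_b_oracle(x, y) -> float:
    """Tau-b by enumerating every pair."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nc = nd = tx = ty = 0
    for i, j in combinations(range(len(x)), 2):
        dx = np.sign(x[i] - x[j])
        dy = np.sign(y[i] - y[j])
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx == dy:
            nc += 1
        else:
            nd += 1
    n0 = len(x) * (len(x) - 1) / 2.0
    return (nc - nd) / math.sqrt((n0 - tx) * (n0 - ty))


def dunn_z_oracle(samples: dict) -> dict:
    """Pairwise Dunn z statistics from explicit pooled midranks."""
    pooled = np.concatenate(list(samples.values()))
    n = len(pooled)
    ranks = midranks(pooled)
    mean_rank = {}
    start = 0
    for g, s in samples.items():
        mean_rank[g] = ranks[start : start + len(s)].mean()
        start += len(s)
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts**3 - counts) / (12.0 * (n - 1))
    out = {}
    for a, b in combinations(samples.keys(), 2):
        se = math.sqrt(
            (n * (n + 1) / 12.0 - tie) * (1.0 / len(samples[a]) + 1.0 / len(samples[b]))
        )
        out[(a, b)] = (mean_rank[a] - mean_rank[b]) / se
    return out


def bh_oracle(pvals) -> np.ndarray:
    """Step-up Benjamini–Hochberg by the definitional min-over-tail rule."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def great_circle_oracle(lon1, lat1, lon2, lat2, radius=6371.0) -> float:
    """Great-circle distance via the spherical law of cosines."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return radius * math.acos(min(1.0, max(-1.0, c)))


def rao_oracle(centroids, weights=None) -> float:
    """Rao Q by the explicit double sum over all centroid pairs."""
    centroids = np.atleast_2d(centroids)
    n = len(centroids)
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float)
    q = 0.0
    for i in range(n):
        for j in range(n):
            q += w[i] * w[j] * great_circle_oracle(*centroids[i], *centroids[j])
    return q
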