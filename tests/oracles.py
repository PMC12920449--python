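"""Independent brute-force oracles the tests check the package against.

Everything here is deliberately naive — direct summations, dictionary BFS,
exhaustive enumeration — and shares no code with the implementation.
"""

from collections import deque
from itertools import combinations
from math import log2

import numpy as np


def mi_bits_naive(p: np.ndarray) -> float:
    """Mutual information of a 2-D table by direct double loop."""
    p = np.asarray(p, float)
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    total = 0.0
    for a in range(p.shape[0]):
        for b in range(p.shape[1]):
            if p[a, b] > 0:
                total += p[a, b] * log2(p[a, b] / (pa[a] * pb[b]))
    return total


def pid_naive(joint: np.ndarray) -> dict:
    """MMI decomposition from a (2,2,2,2) joint, via naive marginals."""
    tdmi = mi_bits_naive(joint.reshape(4, 4))
    i_x = mi_bits_naive(joint.sum(axis=1).reshape(2, 4))
    i_y = mi_bits_naive(joint.sum(axis=0).reshape(2, 4))
    ri = min(i_x, i_y)
    return {
        "tdmi": tdmi,
        "ri": ri,
        "si": tdmi - max(i_x, i_y),
        "ui_x": i_x - ri,
        "ui_y": i_y - ri,
    }


def bfs_distances(n_nodes: int, edges: set) -> dict:
    """All-pairs hop distances by per-source BFS on an adjacency dict."""
    adj = {v: set() for v in range(n_nodes)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    out = {}
    for src in range(n_nodes):
        dist = {src: 0}
        queue = deque([src])
        while queue:
            v = queue.popleft()
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
        for dst in range(src + 1, n_nodes):
            out[(src, dst)] = float(dist.get(dst, np.inf))
    return out


def classify_naive(da: float, db: float, du: float) -> str:
    """Direct inequality checks on one pair's three distances."""
    if np.isinf(du):
        return "disconnected"
    if du < min(da, db):
        return "complementary"
    if du == max(da, db):
        return "shared"
    return "unique_a" if da < db else "unique_b"


def exhaustive_perm_p(a, b) -> float:
    """Two-sided exhaustive permutation p-value, direct enumeration."""
    pooled = list(a) + list(b)
    n_a = len(a)
    observed = abs(np.mean(a) - np.mean(b))
    count = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        sel = set(idx)
        ga = [pooled[i] for i in sel]
        gb = [pooled[i] for i in range(len(pooled)) if i not in sel]
        if abs(np.mean(ga) - np.mean(gb)) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


def hedges_g_naive(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    j = 1 - 3 / (4 * (na + nb) - 9)
    return j * (a.mean() - b.mean()) / sp


def lambda_eff_quadrature(c0, c_inf, lam, d0, dmax, n_steps=200_001) -> float:
    """Normalized area under the decay curve by fine trapezoidal sums."""
    d = np.linspace(d0, dmax, n_steps)
    c = c_inf + (c0 - c_inf) * np.exp(-d / lam)
    return float(np.trapezoid(c, d) / c0)
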