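"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the package (KD-trees, sparse
graph components, vectorized kernels): components come from networkx on an
exhaustive all-pairs edge list or from a hand-rolled union-find, and kernel
densities from scipy.stats.norm summation.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.stats import norm


def brute_force_components(points: np.ndarray, radius: float) -> list[frozenset[int]]:
    """Connected components of the ≤radius threshold graph, exhaustively."""
    n = len(points)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if float(np.linalg.norm(points[i] - points[j])) <= radius:
                g.add_edge(i, j)
    return [frozenset(c) for c in nx.connected_components(g)]


def union_find_components(points: np.ndarray, radius: float, block: int = 512) -> np.ndarray:
    """Component labels via blockwise all-pairs distances + union-find."""
    n = len(points)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for start in range(0, n, block):
        stop = min(start + block, n)
        d = np.linalg.norm(points[start:stop, None, :] - points[None, :, :], axis=2)
        ii, jj = np.nonzero(d <= radius)
        for i, j in zip(ii + start, jj):
            if i < j:
                union(int(i), int(j))
    return np.array([find(i) for i in range(n)])


def gaussian_kernel_sum(x: float, values: np.ndarray, h: float) -> float:
    """Direct kernel summation: (1/n) Σ N(x; v, h)."""
    return float(np.mean(norm.pdf(x, loc=values, scale=h)))
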