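"""Proximity-graph connected components shared by cluster detection and the
apical-fragmentation diagnostic."""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree


def radius_components(points: np.ndarray, radius: float) -> np.ndarray:
    """Label connected components of the graph linking points within ``radius``.

    An edge joins two points whose Euclidean distance is <= ``radius``
    (inclusive, matching the cluster definition). Returns an integer label per
    point; labels are arbitrary but consistent within a call.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array of coordinates")
    n = len(points)
    if n == 0:
        return np.empty(0, dtype=int)
    tree = cKDTree(points)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if len(pairs) == 0:
        return np.arange(n)
    graph = sparse.csr_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    return labels
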