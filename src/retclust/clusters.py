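"""Cluster detection among Otx2-positive cells.

A retinal cluster is operationally a group of two or more Otx2-positive cells
in close vicinity. "Close vicinity" is rendered as a proximity graph: an edge
joins two Otx2-positive cells whose 3-D Euclidean center-to-center distance is
at most the linkage radius, and each connected component of size >= 2 is one
cluster. Singletons are discarded, components are disjoint by construction,
and output order is deterministic (lexicographic by centroid), giving stable
cluster ids across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from ._graph import radius_components
from .io import OrganoidTable


@dataclass(frozen=True)
class Cluster:
    """A connected group of >= 2 Otx2-positive cells.

    ``centroid`` is the arithmetic mean of member positions (μm). Composition
    counts satisfy ``n_pr + n_bp == n_cells`` (photoreceptors are Otx2+Rx2+,
    bipolar precursors Otx2+Rx2−); cone/rod are photoreceptor sub-counts.
    """

    cluster_id: str
    organoid_id: str
    member_ids: tuple[str, ...]
    centroid: np.ndarray
    n_cells: int
    n_pr: int
    n_bp: int
    n_cone: int
    n_rod: int

    def __post_init__(self) -> None:
        if self.n_cells != self.n_pr + self.n_bp:
            raise ValueError(
                f"cluster {self.cluster_id}: n_pr + n_bp must equal n_cells"
            )


def cluster_centroid(positions: np.ndarray) -> np.ndarray:
    """Arithmetic mean position of >= 2 member coordinates (per axis)."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[0] < 2:
        raise ValueError("cluster centroid requires >= 2 positions")
    return positions.mean(axis=0)


def detect_clusters(
    table: OrganoidTable, linkage_radius_um: float
) -> list[Cluster]:
    """Detect Otx2+ clusters as proximity-graph connected components.

    Returns clusters sorted lexicographically by centroid; ids are assigned as
    ``<organoid_id>-c<k>`` in that order. A table with no Otx2+ cells yields
    an empty list (not an error).
    """
    if linkage_radius_um <= 0:
        raise ValueError("linkage_radius_um must be > 0")
    cells = table.cells
    sub = cells[cells["otx2"]]
    if len(sub) == 0:
        return []
    pts = sub[["x", "y", "z"]].to_numpy(dtype=float)
    labels = radius_components(pts, linkage_radius_um)

    clusters: list[Cluster] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < 2:
            continue
        members = sub.iloc[idx]
        n = int(idx.size)
        n_pr = int(members["rx2"].sum())
        clusters.append(
            Cluster(
                cluster_id="",
                organoid_id=table.organoid_id,
                member_ids=tuple(members["cell_id"]),
                centroid=cluster_centroid(pts[idx]),
                n_cells=n,
                n_pr=n_pr,
                n_bp=n - n_pr,
                n_cone=int(members["zpr1"].sum()),
                n_rod=int(members["rhodopsin"].sum()),
            )
        )
    clusters.sort(key=lambda c: tuple(c.centroid))
    return [
        replace(c, cluster_id=f"{table.organoid_id}-c{k}")
        for k, c in enumerate(clusters)
    ]


@dataclass(frozen=True)
class SizeDistribution:
    """Summary of cluster sizes: count, mean, range and per-size frequencies."""

    n: int
    mean: float
    min: int
    max: int
    frequencies: dict[int, int]

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "min": self.min,
            "max": self.max,
            "frequencies": {str(k): v for k, v in sorted(self.frequencies.items())},
        }


def size_distribution(clusters: Iterable[Cluster]) -> SizeDistribution:
    """Distribution of cells-per-cluster. Empty input gives a zero-count summary."""
    sizes = [c.n_cells for c in clusters]
    if not sizes:
        return SizeDistribution(n=0, mean=math.nan, min=0, max=0, frequencies={})
    freq: dict[int, int] = {}
    for s in sizes:
        freq[s] = freq.get(s, 0) + 1
    return SizeDistribution(
        n=len(sizes),
        mean=float(np.mean(sizes)),
        min=int(min(sizes)),
        max=int(max(sizes)),
        frequencies=freq,
    )
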