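"""Nearest-neighbor cluster spacing: sub-stacks, the ±3·SD minimum-distance
band filter, pooled summaries, kernel density estimation and mode counting.

The measurement procedure mirrors how spacing is scored on confocal stacks:
each organoid is partitioned into axial slabs ("sub-stacks", capped at 30
clusters each); within a sub-stack, all unordered pairwise centroid distances
(vector lengths) are computed; per cluster, the minimum of those distances is
its nearest-neighbor distance; the band mean(minima) ± 3·sd(minima) (sample
SD, clamped at 0) is applied to the all-pairs set to discard distances between
non-adjacent clusters; the retained distances are pooled across sub-stacks and
organoids and summarized by their mean and a Gaussian KDE. Because the band is
wider than the minima themselves, first neighbors and some second neighbors
survive the filter, which is why the retained count exceeds the cluster count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial.distance import pdist, squareform

from .clusters import Cluster
from .config import AnalysisConfig


@dataclass(frozen=True)
class SubStack:
    """An axial slab of one organoid holding the clusters whose centroid z
    falls in [z_lo, z_hi)."""

    organoid_id: str
    z_lo: float
    z_hi: float
    cluster_ids: tuple[str, ...]
    degenerate: bool = False

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)


@dataclass(frozen=True)
class DistanceSet:
    """Distances of one sub-stack.

    ``all_pairs`` holds each unordered centroid pair once; ``minima`` the
    per-cluster nearest-neighbor distance; after filtering, ``filtered`` holds
    the retained distances and ``lo``/``hi`` the band bounds (NaN before
    filtering or for degenerate sets).
    """

    substack: SubStack | None
    all_pairs: np.ndarray
    minima: np.ndarray
    filtered: np.ndarray | None = None
    lo: float = math.nan
    hi: float = math.nan
    degenerate: bool = False

    @property
    def n_clusters(self) -> int:
        return len(self.minima)


def partition_substacks(
    clusters: Sequence[Cluster], cfg: AnalysisConfig
) -> list[SubStack]:
    """Partition one organoid's clusters into contiguous z slabs.

    Initial slabs have depth ``substack_depth_um``; a slab over the
    ``max_clusters_per_substack`` cap is split at its median z, and adjacent
    slabs are merged while their joint count stays within the cap. Every
    cluster is assigned to exactly one slab by centroid z. An organoid with
    fewer than two clusters yields a single slab flagged degenerate.
    """
    if not clusters:
        return []
    organoids = {c.organoid_id for c in clusters}
    if len(organoids) != 1:
        raise ValueError("partition_substacks expects clusters of one organoid")
    organoid_id = organoids.pop()
    zs = np.array([c.centroid[2] for c in clusters])
    ids = [c.cluster_id for c in clusters]
    z_lo, z_hi = float(zs.min()), float(zs.max())

    if len(clusters) < 2:
        return [
            SubStack(
                organoid_id=organoid_id,
                z_lo=z_lo,
                z_hi=z_hi + cfg.substack_depth_um,
                cluster_ids=tuple(ids),
                degenerate=True,
            )
        ]

    depth = cfg.substack_depth_um
    n_slabs = max(1, math.ceil((z_hi - z_lo) / depth))
    edges = [z_lo + k * depth for k in range(n_slabs)] + [z_lo + n_slabs * depth]

    # interval list as (lo, hi, member row-indices); half-open [lo, hi)
    slabs: list[tuple[float, float, np.ndarray]] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        idx = np.flatnonzero((zs >= lo) & (zs < hi))
        slabs.append((lo, hi, idx))

    cap = cfg.max_clusters_per_substack

    def split(slab):
        lo, hi, idx = slab
        if len(idx) <= cap or hi - lo < 1e-9:
            if len(idx) > cap:
                warnings.warn(
                    f"{organoid_id}: {len(idx)} clusters share z in "
                    f"[{lo:.3f},{hi:.3f}); cannot split below the cap"
                )
            return [slab]
        mid = float(np.median(zs[idx]))
        if not (lo < mid < hi):
            mid = (lo + hi) / 2
        left = idx[zs[idx] < mid]
        right = idx[zs[idx] >= mid]
        if len(left) == 0 or len(right) == 0:
            return [slab]
        return split((lo, mid, left)) + split((mid, hi, right))

    slabs = [s for slab in slabs for s in split(slab)]

    # greedy left-to-right merge of adjacent slabs under the cap; empty slabs
    # vanish into their neighbor
    merged: list[tuple[float, float, np.ndarray]] = []
    for slab in slabs:
        if merged and len(merged[-1][2]) + len(slab[2]) <= cap:
            lo, _, idx = merged[-1]
            merged[-1] = (lo, slab[1], np.concatenate([idx, slab[2]]))
        else:
            merged.append(slab)

    out = []
    for lo, hi, idx in merged:
        if len(idx) == 0:
            continue
        out.append(
            SubStack(
                organoid_id=organoid_id,
                z_lo=lo,
                z_hi=hi,
                cluster_ids=tuple(ids[i] for i in sorted(idx)),
                degenerate=len(idx) < 2,
            )
        )
    return out


def pairwise_distances(
    centroids: np.ndarray, substack: SubStack | None = None
) -> DistanceSet:
    """All unordered pairwise Euclidean distances plus per-cluster minima.

    Fewer than two centroids yields an empty set flagged degenerate.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    k = len(centroids)
    if k < 2:
        return DistanceSet(
            substack=substack,
            all_pairs=np.empty(0),
            minima=np.empty(0),
            degenerate=True,
        )
    condensed = pdist(centroids)
    full = squareform(condensed)
    np.fill_diagonal(full, np.inf)
    minima = full.min(axis=1)
    return DistanceSet(substack=substack, all_pairs=condensed, minima=minima)


def neighbor_filter(ds: DistanceSet, sd_multiplier: float = 3.0) -> DistanceSet:
    """Band-filter the all-pairs distances by the minima statistics.

    ``lo = mean(minima) − m·sd(minima)`` clamped at 0 and
    ``hi = mean(minima) + m·sd(minima)`` with the sample (n−1) SD and the
    default multiplier m = 3; retained are the unordered pairs with
    ``lo <= d <= hi``. All minima lie inside the band when sd > 0; when
    sd == 0 the band collapses onto the common minimum and only distances
    exactly equal to it survive. Degenerate sets pass through with an empty
    filtered multiset and a warning.
    """
    if ds.degenerate or len(ds.minima) < 2:
        warnings.warn("degenerate distance set: no neighbor distances to filter")
        return replace(ds, filtered=np.empty(0), lo=math.nan, hi=math.nan)
    sd = float(ds.minima.std(ddof=1))
    if sd == 0.0:
        lo = hi = float(ds.minima[0])
    else:
        mean = float(ds.minima.mean())
        lo = max(0.0, mean - sd_multiplier * sd)
        hi = mean + sd_multiplier * sd
    keep = ds.all_pairs[(ds.all_pairs >= lo) & (ds.all_pairs <= hi)]
    return replace(ds, filtered=keep, lo=lo, hi=hi)


@dataclass(frozen=True)
class SpacingSummary:
    """Pooled spacing over the filtered distances of many sub-stacks."""

    mean_um: float
    n_distances: int
    n_clusters: int
    n_organoids: int

    def as_dict(self) -> dict:
        return {
            "mean_um": self.mean_um,
            "n_distances": self.n_distances,
            "n_clusters": self.n_clusters,
            "n_organoids": self.n_organoids,
        }


def pooled_spacing_summary(distance_sets: Iterable[DistanceSet]) -> SpacingSummary:
    """Mean over the union of filtered multisets, with counts.

    All-degenerate (or empty) input yields an n=0 summary with NaN mean.
    """
    pooled: list[np.ndarray] = []
    n_clusters = 0
    organoids: set[str] = set()
    for ds in distance_sets:
        n_clusters += ds.n_clusters
        if ds.substack is not None:
            organoids.add(ds.substack.organoid_id)
        if ds.filtered is not None and len(ds.filtered):
            pooled.append(ds.filtered)
    values = np.concatenate(pooled) if pooled else np.empty(0)
    return SpacingSummary(
        mean_um=float(values.mean()) if len(values) else math.nan,
        n_distances=int(len(values)),
        n_clusters=n_clusters,
        n_organoids=len(organoids),
    )


@dataclass(frozen=True)
class DensityEstimate:
    """Gaussian-kernel density on a regular grid over [0, max + 4·bandwidth]."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_samples: int

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def scott_bandwidth(values: np.ndarray) -> float:
    """Scott's rule for a 1-D Gaussian KDE: sd(values) · n^(−1/5)."""
    values = np.asarray(values, dtype=float)
    return float(values.std(ddof=1) * len(values) ** (-1 / 5))


def kde(
    values: Sequence[float],
    bandwidth: float | str = "scott",
    grid_size: int = 512,
) -> DensityEstimate:
    """Gaussian kernel density estimate of a multiset of lengths (μm).

    ``bandwidth`` is "scott" or a positive number. Requires >= 2 values; with
    zero spread Scott's rule degenerates and a numeric bandwidth is required.
    The grid spans [0, max + 4·bandwidth], so for strictly positive length
    data the density integrates to 1 within numerical tolerance.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("kde requires at least 2 values")
    if bandwidth == "scott":
        h = scott_bandwidth(values)
        if h <= 0:
            raise ValueError(
                "zero-variance data: Scott's rule gives no bandwidth; "
                "pass a numeric bandwidth"
            )
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be > 0")
    grid = np.linspace(0.0, float(values.max()) + 4 * h, grid_size)
    z = (grid[:, None] - values[None, :]) / h
    density = np.exp(-0.5 * z * z).sum(axis=1) / (len(values) * h * math.sqrt(2 * math.pi))
    return DensityEstimate(grid=grid, density=density, bandwidth=h, n_samples=len(values))


def count_modes(de: DensityEstimate, prominence: float) -> int:
    """Number of density modes above ``prominence`` × the global maximum.

    A mode is a strict local maximum of the gridded density (plateaus collapse
    to one peak; grid endpoints never count). A flat zero density has none.
    """
    if not 0 < prominence < 1:
        raise ValueError("prominence must be in (0, 1)")
    peak = float(de.density.max())
    if peak <= 0:
        return 0
    peaks, _ = find_peaks(de.density)
    return int(np.sum(de.density[peaks] > prominence * peak))


def plot_density(de: DensityEstimate, ax=None, **kwargs):
    """Plot a density estimate (KDE-style curve); returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(de.grid, de.density, **kwargs)
    ax.set_xlabel("distance (μm)")
    ax.set_ylabel("density")
    return ax
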