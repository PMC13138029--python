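"""Cell-type scoring and per-cluster composition ratios.

The marker logic is Otx2-anchored: Otx2+Rx2+ cells are photoreceptors (PR),
Otx2+Rx2− cells are bipolar precursors (BP); Zpr1 marks cone PRs and Rhodopsin
rod PRs as sub-labels; Prox1 marks horizontal cells and the Ath5::GFP reporter
marks (a labeled subset of) retinal ganglion cells. Per-cluster ratios use the
Otx2+ member count as denominator, and summaries report the median of the
per-cluster ratios rather than a ratio of pooled counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .clusters import Cluster
from .errors import ConsistencyError
from .io import OrganoidTable

logger = logging.getLogger(__name__)

ROLE_LABELS = ("PR", "BP", "HC", "RGC", "other")


def classify_cell(cell: Mapping) -> str:
    """Assign a role label from the boolean marker flags of one cell.

    Precedence for conflicting flags is Otx2-first (the counting procedure is
    Otx2-anchored): an Otx2+ cell is PR or BP regardless of Prox1/Ath5 flags;
    such conflicts are logged. Pure function: same flags, same label.
    """
    if cell["otx2"]:
        if cell["prox1"] or cell["ath5_gfp"]:
            logger.warning(
                "cell %s: Otx2 conflicts with Prox1/Ath5 flags; Otx2 role wins",
                cell.get("cell_id", "<unknown>"),
            )
        return "PR" if cell["rx2"] else "BP"
    if cell["prox1"]:
        return "HC"
    if cell["ath5_gfp"]:
        return "RGC"
    return "other"


def photoreceptor_subtype(cell: Mapping) -> str | None:
    """Cone/rod sub-label for Otx2+ cells; None otherwise.

    Cone and rod are counted disjointly; a doubly labeled cell counts as cone
    and the overlap is logged.
    """
    if not cell["otx2"]:
        return None
    if cell["zpr1"]:
        if cell["rhodopsin"]:
            logger.warning(
                "cell %s: Zpr1 and Rhodopsin co-labeled; counted as cone",
                cell.get("cell_id", "<unknown>"),
            )
        return "cone"
    if cell["rhodopsin"]:
        return "rod"
    return None


@dataclass(frozen=True)
class CompositionRatios:
    """Per-cluster ratios over the Otx2+ denominator.

    ``bp_ratio`` is defined as ``1 - pr_ratio`` so the pair sums to 1 exactly
    in floating point (the counts satisfy n_pr + n_bp == n by construction).
    """

    cluster_id: str
    pr_ratio: float
    bp_ratio: float
    cone_ratio: float


def cluster_composition(cluster: Cluster, table: OrganoidTable) -> CompositionRatios:
    """Compute PR/BP/cone ratios for one cluster, members resolved in ``table``."""
    cells = table.cells.set_index("cell_id")
    missing = [m for m in cluster.member_ids if m not in cells.index]
    if missing:
        raise ConsistencyError(
            f"cluster {cluster.cluster_id}: member id(s) not in table: "
            f"{', '.join(missing[:5])}"
        )
    members = cells.loc[list(cluster.member_ids)]
    n = len(members)
    n_pr = int(members["rx2"].sum())
    n_cone = int((members["zpr1"] & members["otx2"]).sum())
    pr_ratio = n_pr / n
    return CompositionRatios(
        cluster_id=cluster.cluster_id,
        pr_ratio=pr_ratio,
        bp_ratio=1.0 - pr_ratio,
        cone_ratio=n_cone / n,
    )


@dataclass(frozen=True)
class CompositionSummary:
    """Medians of per-cluster ratios over all clusters of a collection."""

    ratios: tuple[CompositionRatios, ...]
    median_pr_ratio: float
    median_bp_ratio: float
    median_cone_ratio: float
    n_clusters: int
    n_organoids: int

    def as_dict(self) -> dict:
        return {
            "median_pr_ratio": self.median_pr_ratio,
            "median_bp_ratio": self.median_bp_ratio,
            "median_cone_ratio": self.median_cone_ratio,
            "n_clusters": self.n_clusters,
            "n_organoids": self.n_organoids,
        }


def summarize_compositions(
    clusters: Sequence[Cluster], tables: Sequence[OrganoidTable]
) -> CompositionSummary:
    """Median per-cluster composition over clusters from one or more organoids.

    Medians are taken over the per-cluster ratio distributions (matching
    boxplot-style summaries), not over pooled cell counts. Empty input yields
    an n=0 summary with NaN medians.
    """
    by_id = {t.organoid_id: t for t in tables}
    ratios: list[CompositionRatios] = []
    for c in clusters:
        if c.organoid_id not in by_id:
            raise ConsistencyError(
                f"cluster {c.cluster_id}: no table for organoid {c.organoid_id!r}"
            )
        ratios.append(cluster_composition(c, by_id[c.organoid_id]))
    if not ratios:
        return CompositionSummary(
            ratios=(),
            median_pr_ratio=math.nan,
            median_bp_ratio=math.nan,
            median_cone_ratio=math.nan,
            n_clusters=0,
            n_organoids=0,
        )
    return CompositionSummary(
        ratios=tuple(ratios),
        median_pr_ratio=float(np.median([r.pr_ratio for r in ratios])),
        median_bp_ratio=float(np.median([r.bp_ratio for r in ratios])),
        median_cone_ratio=float(np.median([r.cone_ratio for r in ratios])),
        n_clusters=len(ratios),
        n_organoids=len({c.organoid_id for c in clusters}),
    )


def rgc_adjacency(
    clusters: Sequence[Cluster],
    table: OrganoidTable,
    adjacency_radius_um: float = 25.0,
) -> tuple[float, list[bool]]:
    """Fraction of clusters with >= 1 Ath5::GFP+ cell within the radius.

    Returns ``(fraction, per_cluster_flags)``. The default radius is twice the
    nominal cluster radius — juxtaposition without an explicit distance.
    """
    if adjacency_radius_um <= 0:
        raise ValueError("adjacency_radius_um must be > 0")
    if not clusters:
        return 0.0, []
    rgc = table.cells[table.cells["ath5_gfp"]]
    if len(rgc) == 0:
        return 0.0, [False] * len(clusters)
    tree = cKDTree(rgc[["x", "y", "z"]].to_numpy(dtype=float))
    flags = []
    for c in clusters:
        neighbors = tree.query_ball_point(c.centroid, adjacency_radius_um)
        flags.append(len(neighbors) > 0)
    return float(np.mean(flags)), flags
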