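"""Laminated-vs-clustered architecture call with quantitative diagnostics.

Three diagnostics render the qualitative tissue-polarization phenotype
computable:

* **apical fragmentation** — 1 − (largest PKC-ζ+ connected component /
  all PKC-ζ+ cells) under the linkage radius. A single continuous apical
  surface gives 0; many isolated apical foci (one per cluster) push it
  toward 1.
* **radial order index** — a rank statistic in [−1, 1] comparing radial
  positions of Ath5::GFP+ RGCs against Otx2+ cells around the organoid
  centroid (2·AUC − 1 of the Mann-Whitney comparison). Positive values mean
  RGCs sit outside the Otx2+ cells — the laminated orientation.
* **clustered fraction** — fraction of Otx2+ cells inside detected clusters.

The call is rule-based: laminated iff fragmentation < f AND radial order > r;
clustered iff fragmentation >= f AND clustered fraction >= c; anything else
(including degenerate inputs) is indeterminate. The thresholds are
calibration parameters exposed in the config, not measured facts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from ._graph import radius_components
from .clusters import detect_clusters
from .config import AnalysisConfig
from .io import OrganoidTable

logger = logging.getLogger(__name__)


def apical_fragmentation(
    table: OrganoidTable, linkage_radius_um: float
) -> float | None:
    """Fragmentation of the apical (PKC-ζ+) point set in [0, 1].

    0 iff all apical points form one connected component under the linkage
    radius. Returns None (indeterminate, logged) when no apical cells exist.
    """
    apical = table.cells[table.cells["pkc_zeta"]]
    if len(apical) == 0:
        logger.warning("%s: no PKC-zeta+ cells; apical signal indeterminate",
                       table.organoid_id)
        return None
    pts = apical[["x", "y", "z"]].to_numpy(dtype=float)
    labels = radius_components(pts, linkage_radius_um)
    largest = int(np.bincount(labels).max())
    return 1.0 - largest / len(pts)


def radial_order_index(table: OrganoidTable) -> float | None:
    """Rank statistic of RGC-outside-Otx2 radial ordering, in [−1, 1].

    The organoid center is the centroid of all cells (robust for
    near-spherical aggregates, no sphere fit). Cells flagged both Otx2+ and
    Ath5+ are excluded as conflicts. Returns None when either class is absent.
    """
    cells = table.cells
    center = table.positions.mean(axis=0)
    radii = np.linalg.norm(table.positions - center, axis=1)
    otx2 = cells["otx2"].to_numpy()
    ath5 = cells["ath5_gfp"].to_numpy()
    conflict = otx2 & ath5
    if conflict.any():
        logger.warning(
            "%s: %d cells flagged both Otx2+ and Ath5+; excluded from the "
            "radial order index", table.organoid_id, int(conflict.sum()),
        )
    r_otx2 = radii[otx2 & ~conflict]
    r_rgc = radii[ath5 & ~conflict]
    if len(r_otx2) == 0 or len(r_rgc) == 0:
        logger.warning("%s: missing Otx2+ or Ath5+ cells; radial order "
                       "indeterminate", table.organoid_id)
        return None
    u = mannwhitneyu(r_rgc, r_otx2, alternative="two-sided").statistic
    auc = u / (len(r_rgc) * len(r_otx2))
    return float(2 * auc - 1)


@dataclass(frozen=True)
class ArchitectureCall:
    """Per-organoid architecture label plus the diagnostics behind it."""

    organoid_id: str
    label: str  # laminated | clustered | indeterminate
    apical_fragmentation: float | None
    radial_order_index: float | None
    clustered_fraction: float | None
    thresholds: dict

    def as_dict(self) -> dict:
        return {
            "organoid_id": self.organoid_id,
            "label": self.label,
            "apical_fragmentation": self.apical_fragmentation,
            "radial_order_index": self.radial_order_index,
            "clustered_fraction": self.clustered_fraction,
            "thresholds": dict(self.thresholds),
        }


def classify_architecture(
    table: OrganoidTable, cfg: AnalysisConfig
) -> ArchitectureCall:
    """Deterministic laminated/clustered/indeterminate call for one organoid."""
    frag = apical_fragmentation(table, cfg.linkage_radius_um)
    roi = radial_order_index(table)

    n_otx2 = int(table.cells["otx2"].sum())
    clustered_fraction: float | None = None
    if n_otx2 > 0:
        clusters = detect_clusters(table, cfg.linkage_radius_um)
        in_clusters = sum(c.n_cells for c in clusters)
        clustered_fraction = in_clusters / n_otx2

    f = cfg.fragmentation_threshold
    c = cfg.clustered_fraction_threshold
    r = cfg.radial_order_threshold

    label = "indeterminate"
    if frag is not None:
        if frag < f and roi is not None and roi > r:
            label = "laminated"
        elif frag >= f and clustered_fraction is not None and clustered_fraction >= c:
            label = "clustered"

    return ArchitectureCall(
        organoid_id=table.organoid_id,
        label=label,
        apical_fragmentation=frag,
        radial_order_index=roi,
        clustered_fraction=clustered_fraction,
        thresholds={
            "fragmentation_threshold": f,
            "clustered_fraction_threshold": c,
            "radial_order_threshold": r,
        },
    )
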