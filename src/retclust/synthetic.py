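"""Synthetic organoid generator for clustered and laminated retinal tissue.

The generator emulates the endpoint statistics of day-7 medaka retinal
organoids as 3-D cell tables with known ground truth, in two modes:

* **clustered** — discrete multicellular Otx2+ clusters on the mid-cortex
  spherical shell. Cluster centers follow a hard-core (inhibition) point
  process realized as a jittered Fibonacci spherical lattice with a rejection
  floor: the lattice reproduces the even spacing and the first/second-neighbor
  structure of the observed pattern, and the hard-core floor guarantees a
  minimum center-to-center distance. Cluster sizes are a shifted, truncated
  Poisson law (mean 8, range 2–22); members carry the Otx2-anchored marker
  logic (67% photoreceptors of which cones make up 44% of all Otx2+ cells);
  one PKC-ζ+ apical point sits at each cluster center; retinal ganglion cells
  surround each cluster, a configurable fraction carrying the Ath5::GFP label.

* **laminated** — a contiguous Otx2+ band at the inner cortex radius, RGCs in
  an adjacent band toward the outer rim, and a single continuous apical
  surface sampled as a dense PKC-ζ+ point lattice at the inner radius.

Both modes are byte-reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
import pydantic
from scipy.spatial.distance import pdist, squareform

from .errors import PackingError
from .io import CELL_COLUMNS, MARKER_COLUMNS, OrganoidTable

#: Empirical nearest-neighbor coefficient of the Fibonacci spherical lattice:
#: mean NN distance ≈ LATTICE_NN_COEF · R / sqrt(n) for n points on a sphere
#: of radius R (measured once on unjittered lattices, n ≈ 90–130).
LATTICE_NN_COEF = 3.196


class GeneratorParams(pydantic.BaseModel):
    """Parameters of the synthetic organoid generator (lengths in μm)."""

    model_config = pydantic.ConfigDict(frozen=True)

    mode: Literal["clustered", "laminated"] = "clustered"
    cortex_outer_radius_um: float = pydantic.Field(default=150.0, gt=0)
    cortex_thickness_um: float = pydantic.Field(default=30.0, gt=0)
    target_nn_spacing_um: float = pydantic.Field(default=45.0, gt=0)
    #: hard-core floor between cluster centers; None = 0.8 × target spacing
    inhibition_radius_um: Optional[float] = pydantic.Field(default=None, gt=0)
    #: number of clusters; None = derived from target spacing and shell area
    n_clusters: Optional[int] = pydantic.Field(default=None, ge=0)
    cluster_size_mean: float = pydantic.Field(default=8.0, gt=0)
    cluster_size_range: tuple[int, int] = (2, 22)
    cluster_radius_um: float = pydantic.Field(default=12.5, gt=0)
    #: center-to-center spacing of adjacent nuclei within a cluster
    cell_spacing_um: float = pydantic.Field(default=7.0, gt=0)
    p_pr_given_otx2: float = pydantic.Field(default=0.67, ge=0, le=1)
    p_cone_given_otx2: float = pydantic.Field(default=0.44, ge=0, le=1)
    rgc_per_cluster_mean: float = pydantic.Field(default=12.0, ge=0)
    p_ath5_label: float = pydantic.Field(default=0.20, ge=0, le=1)
    hc_per_cluster_mean: float = pydantic.Field(default=1.0, ge=0)
    n_core_cells: int = pydantic.Field(default=300, ge=0)
    noise_sd_um: float = pydantic.Field(default=1.0, ge=0)
    center_jitter_um: float = pydantic.Field(default=2.0, ge=0)
    lamina_thickness_um: float = pydantic.Field(default=10.0, gt=0)
    apical_spacing_um: float = pydantic.Field(default=7.0, gt=0)
    seed: int = 0

    @pydantic.model_validator(mode="after")
    def _check(self):
        if self.cortex_thickness_um >= self.cortex_outer_radius_um:
            raise ValueError("cortex_thickness_um must be < outer radius")
        lo, hi = self.cluster_size_range
        if lo < 2 or hi < lo:
            raise ValueError("cluster_size_range must be within [2, inf)")
        if not lo <= self.cluster_size_mean <= hi:
            raise ValueError("cluster_size_mean must lie in cluster_size_range")
        if self.p_cone_given_otx2 > self.p_pr_given_otx2:
            raise ValueError("p_cone_given_otx2 must be <= p_pr_given_otx2")
        return self

    @property
    def inner_radius_um(self) -> float:
        return self.cortex_outer_radius_um - self.cortex_thickness_um

    @property
    def mid_radius_um(self) -> float:
        return self.cortex_outer_radius_um - self.cortex_thickness_um / 2

    def resolved_inhibition_radius(self) -> float:
        if self.inhibition_radius_um is not None:
            return self.inhibition_radius_um
        return 0.8 * self.target_nn_spacing_um

    def resolved_n_clusters(self) -> int:
        """Cluster count hosting the target NN spacing on the mid shell."""
        if self.n_clusters is not None:
            return self.n_clusters
        return int(
            round((LATTICE_NN_COEF * self.mid_radius_um / self.target_nn_spacing_um) ** 2)
        )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually realized, for parameter-recovery tests."""

    mode: str
    centers: np.ndarray
    member_ids: tuple[tuple[str, ...], ...]
    roles: dict[str, str]
    center_nn_um: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.member_ids)

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "centers": self.centers.tolist(),
            "member_ids": [list(m) for m in self.member_ids],
            "roles": self.roles,
            "center_nn_um": self.center_nn_um.tolist(),
        }


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-evenly spread unit vectors (golden-angle spiral lattice)."""
    if n <= 0:
        return np.empty((0, 3))
    i = np.arange(n)
    golden = (1 + math.sqrt(5)) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * math.pi * i / golden
    r = np.sqrt(np.clip(1 - z * z, 0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _place_centers(params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    """Jittered-lattice hard-core placement of cluster centers on the mid shell."""
    n = params.resolved_n_clusters()
    if n == 0:
        return np.empty((0, 3))
    radius = params.mid_radius_um
    r_inh = params.resolved_inhibition_radius()
    # hexagonal-packing feasibility bound on the shell
    if n * (math.sqrt(3) / 2) * r_inh**2 > 4 * math.pi * radius**2:
        raise PackingError(
            f"cannot place {n} centers at inhibition radius {r_inh:.1f} μm "
            f"on a {radius:.0f} μm shell (packing bound exceeded)"
        )
    base = fibonacci_sphere(n) * radius
    placed: list[np.ndarray] = []
    for k in range(n):
        ok = False
        for _ in range(200):
            cand = base[k] + rng.normal(0.0, params.center_jitter_um, 3)
            cand *= radius / np.linalg.norm(cand)
            if not placed:
                ok = True
                break
            d = np.linalg.norm(np.asarray(placed) - cand, axis=1)
            if d.min() >= r_inh:
                ok = True
                break
        if not ok:
            raise PackingError(
                f"center {k}: no admissible position at inhibition radius "
                f"{r_inh:.1f} μm after bounded retries"
            )
        placed.append(cand)
    return np.asarray(placed)


def _uniform_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    r = radius * rng.uniform(size=n) ** (1 / 3)
    return v * r[:, None]


def _uniform_shell(
    rng: np.random.Generator, n: int, r_lo: float, r_hi: float
) -> np.ndarray:
    """Volume-uniform points in the spherical shell [r_lo, r_hi]."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    u = rng.uniform(size=n)
    r = (r_lo**3 + (r_hi**3 - r_lo**3) * u) ** (1 / 3)
    return v * r[:, None]


def _cluster_member_offsets(
    params: GeneratorParams, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Offsets of one cluster's cells: a contact-packed blob.

    Cells in a cluster touch their neighbors, so members are grown one by one,
    each at roughly one nuclear spacing from a previously placed member and
    confined to the cluster ball. This keeps every cluster a single connected
    component at linkage radii above the nuclear spacing while the blob extent
    grows with size (≈ 2× cluster radius for the mean size).
    """
    offsets = [np.zeros(3)]
    for _ in range(size - 1):
        for _ in range(50):
            anchor = offsets[rng.integers(0, len(offsets))]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            step = params.cell_spacing_um + rng.normal(0.0, 0.8)
            step = float(np.clip(step, 0.7 * params.cell_spacing_um,
                                 1.3 * params.cell_spacing_um))
            cand = anchor + step * direction
            if np.linalg.norm(cand) <= params.cluster_radius_um:
                break
        offsets.append(cand)
    return np.asarray(offsets)


def _draw_sizes(params: GeneratorParams, rng: np.random.Generator, n: int) -> np.ndarray:
    """Shifted Poisson cluster sizes, truncated to the configured range."""
    lo, hi = params.cluster_size_range
    lam = params.cluster_size_mean - lo
    sizes = lo + rng.poisson(lam, size=n)
    while np.any(sizes > hi):
        redo = sizes > hi
        sizes[redo] = lo + rng.poisson(lam, size=int(redo.sum()))
    return sizes


class _TableBuilder:
    """Accumulates cell rows with sequential ids and a role registry."""

    def __init__(self, organoid_id: str):
        self.organoid_id = organoid_id
        self.rows: list[dict] = []
        self.roles: dict[str, str] = {}

    def add(self, pos: np.ndarray, role: str, **flags: bool) -> str:
        cell_id = f"{self.organoid_id}-{len(self.rows):05d}"
        row = {
            "cell_id": cell_id,
            "x": float(pos[0]),
            "y": float(pos[1]),
            "z": float(pos[2]),
            "organoid_id": self.organoid_id,
        }
        for m in MARKER_COLUMNS:
            row[m] = bool(flags.get(m, False))
        self.rows.append(row)
        self.roles[cell_id] = role
        return cell_id

    def table(self, provenance: str) -> OrganoidTable:
        frame = pd.DataFrame(self.rows, columns=list(CELL_COLUMNS))
        for m in MARKER_COLUMNS:
            frame[m] = frame[m].astype(bool)
        return OrganoidTable(
            organoid_id=self.organoid_id, cells=frame, provenance=provenance
        )


def _add_otx2_cell(
    b: _TableBuilder, pos: np.ndarray, params: GeneratorParams, rng: np.random.Generator
) -> str:
    """One Otx2+ cell with the PR/BP + cone/rod marker logic."""
    is_pr = rng.uniform() < params.p_pr_given_otx2
    flags = {"otx2": True, "rx2": is_pr}
    role = "bp"
    if is_pr:
        p_cone = (
            params.p_cone_given_otx2 / params.p_pr_given_otx2
            if params.p_pr_given_otx2 > 0
            else 0.0
        )
        if rng.uniform() < p_cone:
            flags["zpr1"] = True
            role = "cone_pr"
        else:
            flags["rhodopsin"] = True
            role = "rod_pr"
    return b.add(pos, role, **flags)


def _add_rgcs(
    b: _TableBuilder,
    positions: np.ndarray,
    params: GeneratorParams,
    rng: np.random.Generator,
) -> None:
    labels = rng.uniform(size=len(positions)) < params.p_ath5_label
    for pos, labeled in zip(positions, labels):
        if labeled:
            b.add(pos, "rgc", ath5_gfp=True)
        else:
            b.add(pos, "rgc_unlabeled")


def _center_nn(centers: np.ndarray) -> np.ndarray:
    if len(centers) < 2:
        return np.empty(0)
    d = squareform(pdist(centers))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def generate_clustered_organoid(
    params: GeneratorParams,
    organoid_id: str = "sim-clustered-0",
    rng: np.random.Generator | None = None,
) -> tuple[OrganoidTable, GroundTruth]:
    """Generate one clustered-mode organoid table plus ground truth."""
    if params.mode != "clustered":
        raise ValueError("params.mode must be 'clustered'")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    b = _TableBuilder(organoid_id)

    centers = _place_centers(params, rng)
    sizes = _draw_sizes(params, rng, len(centers))
    members: list[tuple[str, ...]] = []
    member_centroids: list[np.ndarray] = []
    cone_positions: list[np.ndarray] = []

    for center, size in zip(centers, sizes):
        ids = []
        positions = []
        # blob offsets are final member positions: bounded steps (< linkage)
        # keep each cluster one connected component, and the cluster-radius
        # bound plus the inhibition floor forbids cross-cluster contacts
        for offset in _cluster_member_offsets(params, rng, int(size)):
            pos = center + offset
            cid = _add_otx2_cell(b, pos, params, rng)
            ids.append(cid)
            positions.append(pos)
            if b.roles[cid] == "cone_pr":
                cone_positions.append(pos)
        members.append(tuple(ids))
        member_centroids.append(np.mean(positions, axis=0))
        # apical polarity focus at the cluster center
        b.add(
            center + rng.normal(0.0, params.noise_sd_um, 3),
            "apical",
            pkc_zeta=True,
        )

    # RGCs juxtaposed to each cluster: directly apposed to the cluster
    # surface (within about one nuclear spacing of it, well inside
    # 2 × cluster_radius of the realized cluster centroid), radially
    # confined to the cortex
    for center in member_centroids:
        n_rgc = int(rng.poisson(params.rgc_per_cluster_mean))
        if n_rgc == 0:
            continue
        offsets = _uniform_shell(
            rng,
            n_rgc,
            params.cluster_radius_um,
            params.cluster_radius_um + params.cell_spacing_um,
        )
        pos = center + offsets + rng.normal(0.0, params.noise_sd_um, (n_rgc, 3))
        norms = np.linalg.norm(pos, axis=1)
        lo = params.inner_radius_um + 2.0
        hi = params.cortex_outer_radius_um - 2.0
        scale = np.clip(norms, lo, hi) / norms
        _add_rgcs(b, pos * scale[:, None], params, rng)

    # horizontal cells next to cone photoreceptors
    n_hc = int(rng.poisson(params.hc_per_cluster_mean * max(len(centers), 1)))
    if cone_positions and n_hc:
        anchors = rng.integers(0, len(cone_positions), size=n_hc)
        for a in anchors:
            b.add(
                cone_positions[a] + rng.normal(0.0, 2.0, 3),
                "hc",
                prox1=True,
            )

    for pos in _uniform_ball(rng, params.n_core_cells, params.inner_radius_um - 5.0):
        b.add(pos, "core")

    truth = GroundTruth(
        mode="clustered",
        centers=centers,
        member_ids=tuple(members),
        roles=dict(b.roles),
        center_nn_um=_center_nn(centers),
    )
    table = b.table(provenance=f"synthetic clustered organoid, seed={params.seed}")
    return table, truth


def generate_laminated_organoid(
    params: GeneratorParams,
    organoid_id: str = "sim-laminated-0",
    rng: np.random.Generator | None = None,
) -> tuple[OrganoidTable, GroundTruth]:
    """Generate one laminated-mode organoid table plus ground truth.

    Cell budgets match the clustered mode (same notional cluster count times
    per-cluster means) so the two modes are comparable in size; the apical
    surface is a dense point lattice at the inner cortex radius whose spacing
    keeps it one connected component under the default linkage radius.
    """
    if params.mode != "laminated":
        raise ValueError("params.mode must be 'laminated'")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    b = _TableBuilder(organoid_id)

    n_units = params.resolved_n_clusters()
    inner = params.inner_radius_um
    outer = params.cortex_outer_radius_um

    # Otx2+ band, apical-in
    n_otx2 = int(round(n_units * params.cluster_size_mean))
    cone_positions: list[np.ndarray] = []
    for pos in _uniform_shell(rng, n_otx2, inner, inner + params.lamina_thickness_um):
        pos = pos + rng.normal(0.0, params.noise_sd_um, 3)
        cid = _add_otx2_cell(b, pos, params, rng)
        if b.roles[cid] == "cone_pr":
            cone_positions.append(pos)

    # single continuous apical surface sampled as a point lattice
    area = 4 * math.pi * inner**2
    n_apical = int(round(area * 2 / (math.sqrt(3) * params.apical_spacing_um**2)))
    apical = fibonacci_sphere(n_apical) * inner
    apical = apical + rng.normal(0.0, 0.5, apical.shape)
    for pos in apical:
        b.add(pos, "apical", pkc_zeta=True)

    # RGC band toward the outer rim
    n_rgc = int(round(n_units * params.rgc_per_cluster_mean))
    rgc_pos = _uniform_shell(rng, n_rgc, outer - params.lamina_thickness_um - 2.0, outer - 2.0)
    _add_rgcs(b, rgc_pos + rng.normal(0.0, params.noise_sd_um, rgc_pos.shape), params, rng)

    n_hc = int(rng.poisson(params.hc_per_cluster_mean * n_units))
    if cone_positions and n_hc:
        anchors = rng.integers(0, len(cone_positions), size=n_hc)
        for a in anchors:
            b.add(cone_positions[a] + rng.normal(0.0, 2.0, 3), "hc", prox1=True)

    for pos in _uniform_ball(rng, params.n_core_cells, inner - 5.0):
        b.add(pos, "core")

    truth = GroundTruth(
        mode="laminated",
        centers=np.empty((0, 3)),
        member_ids=(),
        roles=dict(b.roles),
        center_nn_um=np.empty(0),
    )
    table = b.table(provenance=f"synthetic laminated organoid, seed={params.seed}")
    return table, truth


def generate_organoid(
    params: GeneratorParams,
    organoid_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[OrganoidTable, GroundTruth]:
    """Dispatch on ``params.mode``."""
    if params.mode == "clustered":
        return generate_clustered_organoid(
            params, organoid_id or "sim-clustered-0", rng
        )
    return generate_laminated_organoid(
        params, organoid_id or "sim-laminated-0", rng
    )


def generate_cohort(
    params: GeneratorParams, n_organoids: int, id_prefix: str | None = None
) -> list[tuple[OrganoidTable, GroundTruth]]:
    """Generate ``n_organoids`` independent organoids.

    Per-organoid RNG streams are spawned deterministically from the seed, so a
    cohort is byte-reproducible and any single organoid can be regenerated.
    """
    prefix = id_prefix or f"sim-{params.mode}"
    seeds = np.random.SeedSequence(params.seed).spawn(n_organoids)
    out = []
    for k in range(n_organoids):
        rng = np.random.default_rng(seeds[k])
        out.append(generate_organoid(params, f"{prefix}-{k}", rng))
    return out
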