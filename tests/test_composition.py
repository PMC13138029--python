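"""Marker logic, per-cluster ratios and their summaries."""

from __future__ import annotations

import math

import numpy as np
import pytest

from retclust import (
    classify_cell,
    cluster_composition,
    detect_clusters,
    photoreceptor_subtype,
    rgc_adjacency,
    summarize_compositions,
)
from retclust.composition import CompositionRatios
from retclust.errors import ConsistencyError

from conftest import make_table, points_table


@pytest.mark.parametrize(
    "flags,label",
    [
        ({"otx2": True, "rx2": True}, "PR"),
        ({"otx2": True, "rx2": False}, "BP"),
        ({"prox1": True}, "HC"),
        ({"ath5_gfp": True}, "RGC"),
        ({}, "other"),
        # Otx2-anchored precedence on conflicting flags
        ({"otx2": True, "rx2": True, "prox1": True}, "PR"),
        ({"otx2": True, "ath5_gfp": True}, "BP"),
    ],
)
def test_classify_cell_marker_logic(flags, label):
    cell = make_table([flags]).cells.iloc[0]
    assert classify_cell(cell) == label
    assert classify_cell(cell) == classify_cell(cell)  # pure


@pytest.mark.parametrize(
    "flags,subtype",
    [
        ({"otx2": True, "zpr1": True}, "cone"),
        ({"otx2": True, "rhodopsin": True}, "rod"),
        ({"otx2": True}, None),
        ({"zpr1": True}, None),  # no Otx2 anchor
    ],
)
def test_photoreceptor_subtype(flags, subtype):
    cell = make_table([flags]).cells.iloc[0]
    assert photoreceptor_subtype(cell) == subtype


def cluster_of(table, radius=10.0):
    (cluster,) = detect_clusters(table, radius)
    return cluster


def test_cluster_composition_forced_arithmetic():
    """6 Otx2+ members of which 4 Rx2+ → PR 2/3, BP 1/3 (cluster-level)."""
    rows = [{"x": i * 2.0, "otx2": True, "rx2": i < 4} for i in range(6)]
    table = make_table(rows)
    ratios = cluster_composition(cluster_of(table), table)
    assert ratios.pr_ratio == pytest.approx(2 / 3)
    assert ratios.bp_ratio == pytest.approx(1 / 3)
    assert ratios.pr_ratio + ratios.bp_ratio == 1.0


def test_all_pr_cluster():
    rows = [{"x": i * 2.0, "otx2": True, "rx2": True} for i in range(4)]
    table = make_table(rows)
    ratios = cluster_composition(cluster_of(table), table)
    assert (ratios.pr_ratio, ratios.bp_ratio) == (1.0, 0.0)


def test_missing_member_raises_consistency_error():
    rows = [{"x": i * 2.0, "otx2": True} for i in range(3)]
    table = make_table(rows)
    cluster = cluster_of(table)
    broken = make_table([{"x": 99.0, "cell_id": "unrelated"}], organoid_id="org-A")
    with pytest.raises(ConsistencyError, match=cluster.member_ids[0]):
        cluster_composition(cluster, broken)


@pytest.mark.parametrize("seed", range(5))
def test_random_flags_match_counting_oracle(seed):
    """Ratios equal exhaustive per-member counting on random marker draws."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(int(rng.integers(4, 20))):
        pr = bool(rng.integers(0, 2))
        rows.append(
            {
                "x": i * 3.0,
                "otx2": True,
                "rx2": pr,
                "zpr1": pr and bool(rng.integers(0, 2)),
            }
        )
    table = make_table(rows)
    cluster = cluster_of(table)
    ratios = cluster_composition(cluster, table)
    n = len(rows)
    n_pr = sum(r["rx2"] for r in rows)
    n_cone = sum(r["zpr1"] for r in rows)
    assert ratios.pr_ratio == n_pr / n
    assert ratios.cone_ratio == n_cone / n
    assert ratios.pr_ratio + ratios.bp_ratio == 1.0


def test_summarize_medians():
    def r(pr, cone=0.0):
        return CompositionRatios("c", pr, 1.0 - pr, cone)

    # median is taken over per-cluster ratios, robust to order
    from retclust.composition import CompositionSummary  # noqa: F401

    table = make_table([{"x": 0.0, "otx2": True}, {"x": 2.0, "otx2": True}])
    clusters = detect_clusters(table, 10.0)
    single = summarize_compositions(clusters, [table])
    assert single.median_pr_ratio == single.ratios[0].pr_ratio

    empty = summarize_compositions([], [])
    assert empty.n_clusters == 0 and math.isnan(empty.median_pr_ratio)


def test_median_of_three_ratio_values():
    rows_a = [{"x": i * 2.0, "otx2": True, "rx2": i < 1} for i in range(2)]   # pr 0.5
    rows_b = [{"x": 50 + i * 2.0, "otx2": True, "rx2": i < 3} for i in range(5)]  # 0.6
    rows_c = [{"x": 100 + i * 2.0, "otx2": True, "rx2": i < 9} for i in range(10)]  # 0.9
    table = make_table(rows_a + rows_b + rows_c)
    clusters = detect_clusters(table, 10.0)
    assert len(clusters) == 3
    summary = summarize_compositions(clusters, [table])
    assert summary.median_pr_ratio == pytest.approx(0.6)
    assert summary.n_clusters == 3 and summary.n_organoids == 1


def test_rgc_adjacency_trivial_cases():
    rows = [{"x": i * 2.0, "otx2": True} for i in range(4)]
    table = make_table(rows)
    clusters = detect_clusters(table, 10.0)
    fraction, flags = rgc_adjacency(clusters, table, 25.0)
    assert fraction == 0.0 and flags == [False]

    rows.append({"x": 3.0, "ath5_gfp": True})
    table2 = make_table(rows)
    clusters2 = detect_clusters(table2, 10.0)
    fraction2, flags2 = rgc_adjacency(clusters2, table2, 25.0)
    assert fraction2 == 1.0 and flags2 == [True]


def test_rgc_adjacency_on_generated_cohort(clustered_cohort):
    """RGCs are juxtaposed by construction.

    Every cluster has placed RGCs within the adjacency radius (ground truth,
    label-blind). The Ath5::GFP-visible adjacency is Bernoulli-thinned: with
    12 RGCs/cluster and a 20% label rate, the population fraction is
    1 − exp(−2.4) ≈ 0.91; the pooled observation must match that closed form
    within its 99% binomial sampling interval.
    """
    hits = 0
    total = 0
    for table, truth in clustered_cohort:
        clusters = detect_clusters(table, 10.0)
        _, flags = rgc_adjacency(clusters, table, 25.0)
        hits += sum(flags)
        total += len(flags)
        # construction-level check on all placed RGCs, labeled or not
        cells = table.cells.set_index("cell_id")
        rgc_ids = [i for i, role in truth.roles.items() if role.startswith("rgc")]
        rgc_pos = cells.loc[rgc_ids, ["x", "y", "z"]].to_numpy()
        for c in clusters:
            d = np.linalg.norm(rgc_pos - c.centroid, axis=1)
            assert (d <= 25.0).any()
    assert total > 500
    expected = 1.0 - math.exp(-12.0 * 0.2)
    assert expected >= 0.9
    half_width = 2.576 * math.sqrt(expected * (1 - expected) / total)
    assert abs(hits / total - expected) <= half_width
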