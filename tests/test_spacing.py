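"""Sub-stack partition, distance filter, pooled summary, KDE and modes."""

from __future__ import annotations

import math
import statistics

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from retclust import (
    AnalysisConfig,
    count_modes,
    kde,
    neighbor_filter,
    pairwise_distances,
    partition_substacks,
    pooled_spacing_summary,
)
from retclust.clusters import Cluster
from retclust.spacing import DensityEstimate, DistanceSet

from _oracles import gaussian_kernel_sum


def fake_clusters(zs, organoid_id="org-A"):
    out = []
    for k, z in enumerate(zs):
        out.append(
            Cluster(
                cluster_id=f"{organoid_id}-c{k}",
                organoid_id=organoid_id,
                member_ids=("a", "b"),
                centroid=np.array([0.0, 0.0, float(z)]),
                n_cells=2, n_pr=2, n_bp=0, n_cone=0, n_rod=0,
            )
        )
    return out


class TestPartition:
    def test_few_clusters_single_substack(self):
        cfg = AnalysisConfig(substack_depth_um=60.0)
        subs = partition_substacks(fake_clusters([0, 10, 20, 30, 40]), cfg)
        assert len(subs) == 1
        assert subs[0].n_clusters == 5 and not subs[0].degenerate

    def test_cap_respected_by_pigeonhole(self):
        cfg = AnalysisConfig(substack_depth_um=60.0, max_clusters_per_substack=30)
        zs = np.linspace(0, 300, 65)
        subs = partition_substacks(fake_clusters(zs), cfg)
        assert len(subs) >= 3
        assert all(s.n_clusters <= 30 for s in subs)

    def test_single_cluster_flagged_degenerate(self):
        subs = partition_substacks(fake_clusters([5.0]), AnalysisConfig())
        assert len(subs) == 1 and subs[0].degenerate

    @pytest.mark.parametrize("seed", range(10))
    def test_every_cluster_assigned_exactly_once(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 120))
        zs = rng.uniform(-150, 150, n)
        cfg = AnalysisConfig(
            substack_depth_um=float(rng.uniform(20, 100)),
            max_clusters_per_substack=int(rng.integers(2, 40)),
        )
        clusters = fake_clusters(zs)
        subs = partition_substacks(clusters, cfg)
        assigned = [cid for s in subs for cid in s.cluster_ids]
        assert sorted(assigned) == sorted(c.cluster_id for c in clusters)
        # intervals disjoint
        intervals = sorted((s.z_lo, s.z_hi) for s in subs)
        for (lo1, hi1), (lo2, _) in zip(intervals, intervals[1:]):
            assert hi1 <= lo2 + 1e-9


class TestPairwise:
    def test_three_four_five_triangle(self):
        ds = pairwise_distances(np.array([[0, 0, 0], [3, 4, 0]]))
        assert ds.all_pairs.tolist() == [5.0]
        assert ds.minima.tolist() == [5.0, 5.0]

    def test_random_centroids_match_direct_summation(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, size=(5, 3))
        ds = pairwise_distances(pts)
        assert len(ds.all_pairs) == 10
        oracle = sorted(
            math.sqrt(sum((pts[i][a] - pts[j][a]) ** 2 for a in range(3)))
            for i in range(5)
            for j in range(i + 1, 5)
        )
        assert np.allclose(sorted(ds.all_pairs), oracle)
        for i in range(5):
            expected = min(
                float(np.linalg.norm(pts[i] - pts[j])) for j in range(5) if j != i
            )
            assert ds.minima[i] == pytest.approx(expected)
        # symmetry/positivity and triangle inequality spot-check
        assert (ds.all_pairs > 0).all()
        d = lambda i, j: float(np.linalg.norm(pts[i] - pts[j]))
        for i, j, k in [(0, 1, 2), (1, 3, 4), (0, 2, 4)]:
            assert d(i, j) <= d(i, k) + d(k, j) + 1e-12

    def test_single_centroid_degenerate(self):
        ds = pairwise_distances(np.array([[1.0, 2.0, 3.0]]))
        assert ds.degenerate and len(ds.all_pairs) == 0


class TestNeighborFilter:
    def test_zero_sd_band_collapses_to_common_minimum(self):
        d = 7.0
        ds = DistanceSet(
            substack=None,
            all_pairs=np.array([d, d, 3 * d]),
            minima=np.array([d, d, d]),
        )
        out = neighbor_filter(ds)
        assert out.lo == out.hi == d
        assert out.filtered.tolist() == [d, d]

    def test_constructed_substack_matches_mean_sd_oracle(self):
        minima = [10.0, 12.0, 14.0, 40.0]
        all_pairs = np.array([10.0, 12.0, 14.0, 40.0, 100.0, 100.0, 55.0])
        ds = DistanceSet(substack=None, all_pairs=all_pairs, minima=np.array(minima))
        out = neighbor_filter(ds)
        mean = statistics.mean(minima)
        sd = statistics.stdev(minima)  # independent recomputation
        assert out.lo == pytest.approx(max(0.0, mean - 3 * sd))
        assert out.hi == pytest.approx(mean + 3 * sd)
        expected = [d for d in all_pairs if out.lo <= d <= out.hi]
        assert sorted(out.filtered) == sorted(expected)
        # the minima themselves are always retained
        assert all(out.lo <= m <= out.hi for m in minima)

    def test_degenerate_passthrough_warns(self):
        ds = pairwise_distances(np.array([[0.0, 0.0, 0.0]]))
        with pytest.warns(UserWarning, match="degenerate"):
            out = neighbor_filter(ds)
        assert len(out.filtered) == 0 and math.isnan(out.lo)

    @given(st.integers(0, 10_000))
    def test_filtered_subset_and_band_monotonicity(self, seed):
        """filtered ⊆ all_pairs; widening the band never shrinks it."""
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 120, size=(int(rng.integers(3, 12)), 3))
        ds = pairwise_distances(pts)
        all_pairs = set(np.round(ds.all_pairs, 9))
        previous: set = set()
        for mult in (1.0, 2.0, 3.0, 5.0):
            out = neighbor_filter(ds, sd_multiplier=mult)
            current = set(np.round(out.filtered, 9))
            assert current <= all_pairs
            assert previous <= current
            previous = current


class TestPooled:
    def test_mean_of_single_filtered_set(self):
        ds = DistanceSet(
            substack=None,
            all_pairs=np.array([40.0, 50.0]),
            minima=np.array([40.0, 40.0]),
            filtered=np.array([40.0, 50.0]),
            lo=0.0,
            hi=100.0,
        )
        summary = pooled_spacing_summary([ds])
        assert summary.mean_um == pytest.approx(45.0)
        assert summary.n_distances == 2

    def test_empty_input(self):
        summary = pooled_spacing_summary([])
        assert summary.n_distances == 0 and math.isnan(summary.mean_um)


class TestKDE:
    def test_point_mass_peaks_at_value_and_normalizes(self):
        de = kde([45.0, 45.0, 45.0], bandwidth=1.0)
        assert de.grid[np.argmax(de.density)] == pytest.approx(45.0, abs=de.grid[1])
        assert de.integral() == pytest.approx(1.0, abs=1e-3)

    def test_density_matches_direct_kernel_summation(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(20, 90, size=40)
        de = kde(values, bandwidth=3.0)
        for idx in np.linspace(0, len(de.grid) - 1, 10).astype(int):
            x = de.grid[idx]
            assert de.density[idx] == pytest.approx(
                gaussian_kernel_sum(x, values, 3.0), abs=1e-9
            )

    def test_requires_two_values_and_positive_bandwidth(self):
        with pytest.raises(ValueError):
            kde([45.0], bandwidth=1.0)
        with pytest.raises(ValueError):
            kde([1.0, 2.0], bandwidth=0.0)
        with pytest.raises(ValueError, match="[Zz]ero-variance"):
            kde([5.0, 5.0, 5.0], bandwidth="scott")

    def test_location_equivariance_of_modes(self):
        rng = np.random.default_rng(9)
        values = np.concatenate([rng.normal(45, 2, 200), rng.normal(90, 2, 200)])
        de = kde(values, bandwidth=2.0, grid_size=2048)
        shifted = kde(values + 30.0, bandwidth=2.0, grid_size=2048)
        step = de.grid[1] - de.grid[0]

        def mode_locs(d):
            from scipy.signal import find_peaks

            peaks, _ = find_peaks(d.density)
            big = peaks[d.density[peaks] > 0.2 * d.density.max()]
            return d.grid[big]

        for a, b in zip(mode_locs(de), mode_locs(shifted)):
            assert b - a == pytest.approx(30.0, abs=3 * step)


class TestModes:
    def test_unimodal_sample(self):
        rng = np.random.default_rng(4)
        de = kde(rng.normal(45, 5, 300), bandwidth="scott")
        assert count_modes(de, 0.2) == 1

    def test_well_separated_mixture_is_bimodal(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.normal(45, 3, 300), rng.normal(90, 3, 300)])
        de = kde(values, bandwidth=3.0)
        assert count_modes(de, 0.2) == 2

    def test_flat_zero_density(self):
        de = DensityEstimate(
            grid=np.linspace(0, 1, 50),
            density=np.zeros(50),
            bandwidth=1.0,
            n_samples=2,
        )
        assert count_modes(de, 0.2) == 0
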