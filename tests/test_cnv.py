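"""Empirical binning, normalization, CBS segmentation, ploidy, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from bagseq.cnv import (
    BinScheme,
    SegmentationParams,
    build_empirical_bins,
    cluster_profiles,
    count_bins,
    estimate_ploidy,
    linkage_to_newick,
    normalize_profile,
    segment_profile,
)


# --------------------------------------------------------------------------
# oracles


def exhaustive_one_breakpoint(x):
    """Least-squares single change point by full enumeration."""
    n = len(x)
    best, best_b = np.inf, None
    for b in range(1, n):
        sse = np.var(x[:b]) * b + np.var(x[b:]) * (n - b)
        if sse < best:
            best, best_b = sse, b
    return best_b


def exhaustive_two_breakpoints(x, min_width=3):
    """Least-squares two change points by full enumeration."""
    n = len(x)
    best, best_pair = np.inf, None
    for b1 in range(min_width, n - 2 * min_width + 1):
        for b2 in range(b1 + min_width, n - min_width + 1):
            sse = (
                np.var(x[:b1]) * b1
                + np.var(x[b1:b2]) * (b2 - b1)
                + np.var(x[b2:]) * (n - b2)
            )
            if sse < best:
                best, best_pair = sse, (b1, b2)
    return best_pair


# --------------------------------------------------------------------------
# bins


class TestEmpiricalBins:
    def test_uniform_positions_give_equal_width_bins(self):
        pos = {"chr1": np.arange(0, 100_000, 1)}
        scheme = build_empirical_bins(pos, 5, chrom_lengths={"chr1": 100_000})
        widths = (scheme.bins["end"] - scheme.bins["start"]).to_numpy()
        assert len(scheme) == 5
        assert np.all(widths == 20_000)

    def test_density_gradient_narrows_bins(self):
        # doubled density on the first half: bins there should be half as wide
        first = np.arange(0, 50_000, 1)
        second = np.arange(50_000, 100_000, 2)
        pos = {"chr1": np.concatenate([first, second])}
        scheme = build_empirical_bins(pos, 10, chrom_lengths={"chr1": 100_000})
        counts = count_bins(pos, scheme)
        assert counts.max() - counts.min() <= 1
        widths = (scheme.bins["end"] - scheme.bins["start"]).to_numpy()
        assert widths[:4].mean() < widths[6:].mean()

    @pytest.mark.parametrize("n_bins", [7, 100])
    def test_self_consistency_single_chromosome(self, n_bins, rng):
        pos = {"chr1": np.sort(rng.choice(500_000, size=20_000, replace=False))}
        scheme = build_empirical_bins(pos, n_bins, chrom_lengths={"chr1": 500_000})
        counts = count_bins(pos, scheme)
        assert len(counts) == n_bins
        assert counts.max() - counts.min() <= 1

    def test_self_consistency_per_chromosome(self, rng):
        # whole bins cannot cross chromosome ends, so the equal-count
        # guarantee is exact within each chromosome
        pos = {
            "chr1": np.sort(rng.choice(500_000, size=20_000, replace=False)),
            "chr2": np.sort(rng.choice(300_000, size=9_000, replace=False)),
        }
        scheme = build_empirical_bins(
            pos, 100, chrom_lengths={"chr1": 500_000, "chr2": 300_000}
        )
        counts = count_bins(pos, scheme)
        for _, grp in scheme.bins.groupby("chrom"):
            c = counts[grp.index]
            assert c.max() - c.min() <= 1

    def test_too_many_bins_rejected(self):
        with pytest.raises(ValueError):
            build_empirical_bins({"chr1": np.arange(10)}, 50)

    def test_gc_computed_from_genome(self):
        genome = {"chr1": "GGGG" + "AAAA" + "GGCC" + "ATAT"}
        pos = {"chr1": np.array([3, 7, 11, 15])}
        scheme = build_empirical_bins(pos, 4, genome=genome)
        # boundaries fall between consecutive positions: bins of 4 bases each
        assert list(scheme.bins["start"]) == [0, 4, 8, 12]
        assert scheme.bins["gc"].tolist() == pytest.approx([1.0, 0.0, 1.0, 0.0])


# --------------------------------------------------------------------------
# normalization


class TestNormalize:
    def test_constant_input_gives_all_ones(self):
        v = normalize_profile(np.full(200, 37), np.full(200, 0.45))
        assert np.allclose(v, 1.0)

    def test_mean_is_exactly_one(self, rng):
        counts = rng.poisson(60, 500)
        gc = rng.uniform(0.3, 0.6, 500)
        v = normalize_profile(counts, gc)
        assert v.mean() == pytest.approx(1.0, abs=1e-9)

    def test_planted_gc_bias_removed(self, rng):
        """A smooth multiplicative GC bias on flat counts is flattened out."""
        n = 2000
        gc = np.sort(rng.uniform(0.30, 0.60, n))
        rng.shuffle(gc)
        bias = np.exp(1.5 * (gc - gc.mean()))
        counts = np.round(400 * bias).astype(int)
        v = normalize_profile(counts, gc)
        assert np.max(np.abs(v - 1)) < 0.05

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_profile(np.zeros(100), np.full(100, 0.4))


# --------------------------------------------------------------------------
# segmentation


class TestSegmentation:
    def test_flat_profile_one_segment(self):
        seg, bps = segment_profile(np.ones(300), SegmentationParams(seed=1))
        assert bps == []
        assert np.allclose(seg, 1.0)

    def test_single_step_found_within_two_bins(self, rng):
        x = np.concatenate([np.ones(500), np.full(500, 1.5)])
        x += rng.normal(0, 0.05, 1000)
        seg, bps = segment_profile(x, SegmentationParams(seed=1))
        assert len(bps) == 1
        assert abs(bps[0] - 500) <= 2
        assert abs(bps[0] - exhaustive_one_breakpoint(x)) <= 2

    def test_two_steps_match_exhaustive_oracle(self, rng):
        x = np.concatenate([np.ones(70), np.full(60, 1.6), np.ones(70)])
        x += rng.normal(0, 0.05, 200)
        seg, bps = segment_profile(x, SegmentationParams(seed=1))
        oracle = exhaustive_two_breakpoints(x)
        assert len(bps) == 2
        assert abs(bps[0] - oracle[0]) <= 2 and abs(bps[1] - oracle[1]) <= 2

    def test_nan_rejected(self):
        x = np.ones(100)
        x[10] = np.nan
        with pytest.raises(ValueError):
            segment_profile(x, SegmentationParams(seed=1))

    def test_deterministic_under_fixed_seed(self, rng):
        x = np.concatenate([np.ones(100), np.full(100, 1.4)]) + rng.normal(0, 0.05, 200)
        a = segment_profile(x, SegmentationParams(seed=9))
        b = segment_profile(x, SegmentationParams(seed=9))
        assert a[1] == b[1]
        assert np.array_equal(a[0], b[0])

    def test_segment_means_equal_member_bin_means(self, rng):
        x = np.concatenate([np.ones(80), np.full(120, 1.5)]) + rng.normal(0, 0.05, 200)
        seg, bps = segment_profile(x, SegmentationParams(seed=1))
        bounds = [0] + bps + [len(x)]
        for a, b in zip(bounds, bounds[1:]):
            assert seg[a] == pytest.approx(x[a:b].mean())
            assert np.allclose(seg[a:b], seg[a])

    def test_weak_noise_splits_are_undone(self, rng):
        """Pure noise around a constant level yields a single segment."""
        x = 1.0 + rng.normal(0, 0.05, 400)
        _, bps = segment_profile(x, SegmentationParams(seed=2))
        assert bps == []


# --------------------------------------------------------------------------
# ploidy


class TestPloidy:
    def test_zero_error_construction(self):
        s = np.array([0.5] * 50 + [1.0] * 100 + [1.5] * 50)
        ploidy, scaled = estimate_ploidy(s)
        assert ploidy == 2.0
        assert set(np.round(scaled, 9)) == {1.0, 2.0, 3.0}

    def test_flat_profile_tie_breaks_to_lowest_multiplier(self):
        ploidy, _ = estimate_ploidy(np.ones(100))
        assert ploidy == 2.0

    def test_weights_shift_the_optimum(self):
        # two candidate states; the heavily weighted one dominates the SSE
        s = np.array([1.0, 1.26])
        heavy_first, _ = estimate_ploidy(s, weights=np.array([100.0, 1.0]))
        heavy_second, _ = estimate_ploidy(s, weights=np.array([1.0, 100.0]))
        assert heavy_first != heavy_second

    def test_scaling_preserves_boundaries(self, rng):
        x = np.concatenate([np.ones(100), np.full(100, 1.5)]) + rng.normal(0, 0.04, 200)
        seg, bps = segment_profile(x, SegmentationParams(seed=1))
        _, scaled = estimate_ploidy(seg)
        bounds = np.nonzero(np.diff(scaled))[0] + 1
        assert set(bounds) <= set(bps)


# --------------------------------------------------------------------------
# clustering


class TestClustering:
    def test_manhattan_distance_arithmetic(self):
        d = pdist(np.array([[1.0, 1.0], [2.0, 2.0]]), metric="cityblock")
        assert d[0] == 2.0

    def test_identical_profiles_merge_first(self):
        m = pd.DataFrame(
            [[1.0, 1.0, 2.0], [1.0, 1.0, 2.0], [4.0, 4.0, 4.0]],
            index=["a", "b", "c"],
        )
        Z, order = cluster_profiles(m)
        assert Z[0, 2] == 0.0  # first merge at distance zero
        assert {order.index("a"), order.index("b")} == {0, 1} or order[-2:] == ["a", "b"]

    def test_three_planted_clones_recovered(self, rng):
        from scipy.cluster.hierarchy import fcluster
        from sklearn.metrics import adjusted_rand_score

        states = {
            0: np.array([2.0] * 50 + [3.0] * 50),
            1: np.array([1.0] * 50 + [2.0] * 50),
            2: np.array([2.0] * 100),
        }
        rows, labels = [], []
        for clone, base in states.items():
            for _ in range(20):
                rows.append(base + rng.normal(0, 0.05, 100))
                labels.append(clone)
        m = pd.DataFrame(rows, index=[f"c{i}" for i in range(60)])
        Z, _ = cluster_profiles(m)
        found = fcluster(Z, t=3, criterion="maxclust")
        assert adjusted_rand_score(labels, found) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cluster_profiles(pd.DataFrame([[1.0, 2.0]]))

    def test_newick_serialization(self):
        m = pd.DataFrame([[1.0, 1.0], [2.0, 2.0], [9.0, 9.0]], index=["a", "b", "c"])
        Z, _ = cluster_profiles(m)
        tree = linkage_to_newick(Z, list(m.index))
        assert tree.endswith(";")
        for label in "abc":
            assert label in tree
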