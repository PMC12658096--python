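"""Leave-one-out ranks, match summaries and rank-matrix clustering."""

import numpy as np
import pytest
from scipy.stats import chisquare

from facegestalt import (
    Cohort,
    DistanceMatrix,
    Gallery,
    GalleryError,
    ImageEncoding,
    cluster_rank_matrix,
    match_summary,
    pairwise_rank_matrix,
    rank_of_match,
)
from facegestalt.ranking import RankMatrix
from _oracles import average_linkage_naive, rank_by_full_sort


def dmatrix_from_probe_row(probe_distances, ids):
    """Symmetric matrix whose first row/column holds the probe's distances."""
    n = len(ids)
    v = np.full((n, n), 1.0)
    v[0, 1:] = probe_distances
    v[1:, 0] = probe_distances
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(ids, v)


class TestRankOfMatch:
    def test_closest_target_ranks_first(self):
        ids = ("p", "t", "x", "y")
        d = dmatrix_from_probe_row([0.1, 0.5, 0.9], ids)
        assert rank_of_match("p", "t", ["t", "x", "y"], d) == 1

    def test_interleaved_competitors(self):
        ids = ("p", "t", "a", "b", "c")
        d = dmatrix_from_probe_row([0.15, 0.10, 0.20, 0.30], ids)
        assert rank_of_match("p", "t", ["t", "a", "b", "c"], d) == 2

    def test_ties_take_worst_rank(self):
        ids = ("p", "t", "a", "b")
        d = dmatrix_from_probe_row([0.5, 0.5, 0.9], ids)
        # target tied with one equal competitor -> rank 2, not 1
        assert rank_of_match("p", "t", ["t", "a", "b"], d) == 2

    def test_target_must_be_competitor(self):
        ids = ("p", "t", "a")
        d = dmatrix_from_probe_row([0.5, 0.6], ids)
        with pytest.raises(GalleryError, match="missing"):
            rank_of_match("p", "t", ["a"], d)
        with pytest.raises(GalleryError, match="probe"):
            rank_of_match("p", "t", ["p", "t"], d)

    def test_matches_full_sort_oracle_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n_comp = int(rng.integers(2, 40))
            ids = ("p",) + tuple(f"c{i}" for i in range(n_comp))
            probe_d = rng.choice([0.2, 0.4, 0.6, 0.8], size=n_comp)  # force ties
            d = dmatrix_from_probe_row(probe_d, ids)
            target_pos = int(rng.integers(0, n_comp))
            got = rank_of_match("p", ids[1 + target_pos], list(ids[1:]), d)
            assert got == rank_by_full_sort(probe_d, target_pos)


def random_background_and_cohort(n_bg, k, seed, cohort_spread=1.0):
    """Random unit-vector background plus a cohort clustered by `cohort_spread`."""
    rng = np.random.default_rng(seed)

    def enc(name, base=None, spread=1.0):
        raw = rng.standard_normal((2, 24)) if base is None else \
            base + spread * rng.standard_normal((2, 24))
        return ImageEncoding(name, name, "s", raw)

    background = Gallery([enc(f"bg{i:04d}") for i in range(n_bg)])
    center = rng.standard_normal((2, 24))
    cohort_gallery = Gallery([enc(f"co{i:02d}", center, cohort_spread) for i in range(k)])
    cohort = Cohort(tuple(cohort_gallery.image_ids))
    return background, cohort_gallery, cohort


class TestPairwiseRankMatrix:
    def test_empty_background_forces_rank_range(self):
        background, cohort_gallery, cohort = random_background_and_cohort(0, 3, 1)
        from facegestalt import pairwise_distance_matrix
        d = pairwise_distance_matrix(cohort_gallery)
        rm = pairwise_rank_matrix(cohort, Gallery([]), d)
        for i in range(3):
            row = np.delete(rm.ranks[i], i)
            assert sorted(row) == [1, 2]

    def test_tight_cohort_beats_null_background(self):
        from facegestalt import pairwise_distance_matrix
        background, cohort_gallery, cohort = random_background_and_cohort(
            300, 8, 2, cohort_spread=0.05)
        d = pairwise_distance_matrix(background.merged_with(cohort_gallery))
        rm = pairwise_rank_matrix(cohort, background, d)
        off = rm.ranks[~np.eye(8, dtype=bool)]
        assert np.median(off) < 50
        assert rm.gallery_size == 300

    def test_null_cohort_ranks_uniform(self):
        """Random cohorts among a random background: ranks ~ uniform on [1, G+k-1]."""
        from facegestalt import pairwise_distance_matrix
        all_ranks = []
        G, k = 60, 4
        for seed in range(8):
            background, cohort_gallery, cohort = random_background_and_cohort(
                G, k, seed + 10, cohort_spread=50.0)
            d = pairwise_distance_matrix(background.merged_with(cohort_gallery))
            rm = pairwise_rank_matrix(cohort, background, d)
            all_ranks.extend(rm.ranks[~np.eye(k, dtype=bool)])
        all_ranks = np.asarray(all_ranks)
        hi = G + k - 1
        assert all_ranks.min() >= 1 and all_ranks.max() <= hi
        counts, _ = np.histogram(all_ranks, bins=7, range=(0.5, hi + 0.5))
        assert chisquare(counts).pvalue > 0.01
        assert abs(all_ranks.mean() - (hi + 1) / 2) / ((hi + 1) / 2) < 0.15


class TestMatchSummary:
    def _rm(self, ranks, gallery_size=100):
        k = len(ranks)
        return RankMatrix(tuple(f"s{i}" for i in range(k)), np.asarray(ranks),
                          gallery_size)

    def test_strong_and_matched_flags(self):
        rm = self._rm([[0, 9, 80], [70, 0, 60], [55, 90, 0]])
        ms = match_summary(rm, cutoff=50, strong_cutoff=10)
        # s0-s1 best directed rank 9: both matched, strong pair
        assert set(ms.matched_ids) == {"s0", "s1"}
        assert ms.matched_count == 2
        assert ms.strong_pairs == (("s0", "s1"),)

    def test_boundary_rank_is_not_matched(self):
        rm = self._rm([[0, 50], [50, 0]])
        assert match_summary(rm, cutoff=50).matched_count == 0

    def test_no_matches_when_all_ranks_high(self):
        rm = self._rm([[0, 99], [98, 0]])
        ms = match_summary(rm, cutoff=50, strong_cutoff=10)
        assert ms.matched_count == 0 and ms.strong_pairs == ()

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(20)
        ranks = rng.integers(1, 100, size=(6, 6))
        np.fill_diagonal(ranks, 0)
        rm = self._rm(ranks)
        m10 = set(match_summary(rm, cutoff=10).matched_ids)
        m50 = set(match_summary(rm, cutoff=50).matched_ids)
        assert m10 <= m50


class TestClustering:
    def test_two_leaves_single_merge(self):
        rm = RankMatrix(("a", "b"), np.array([[0, 7], [3, 0]]), 50)
        res = cluster_rank_matrix(rm)
        assert len(res.merges) == 1
        assert res.merges[0][2] == 3.0  # min-symmetrized height
        assert set(res.leaf_order) == {"a", "b"}
        assert res.newick.endswith(";") and "a" in res.newick and "b" in res.newick

    def test_identical_rows_merge_at_equal_heights_id_order(self):
        k = 4
        ranks = np.full((k, k), 5)
        np.fill_diagonal(ranks, 0)
        rm = RankMatrix(("d", "b", "a", "c"), ranks, 50)
        res = cluster_rank_matrix(rm)
        heights = [m[2] for m in res.merges]
        assert heights == pytest.approx([5.0] * (k - 1))
        assert res.leaf_order[0] == "a"  # id-sorted tie-break

    def test_separated_groups_merge_last(self):
        # two tight groups: within-ranks small, across-ranks large
        k = 6
        ranks = np.full((k, k), 200)
        for grp in ([0, 1, 2], [3, 4, 5]):
            for i in grp:
                for j in grp:
                    if i != j:
                        ranks[i, j] = 2
        np.fill_diagonal(ranks, 0)
        rm = RankMatrix(tuple(f"s{i}" for i in range(k)), ranks, 500)
        res = cluster_rank_matrix(rm)
        # the first k-2 merges never join the two groups: only the last
        # merge happens at the across-group height
        assert [m[2] for m in res.merges[:-1]] == pytest.approx([2.0] * (k - 2))
        assert res.merges[-1][2] == pytest.approx(200.0)

    def test_matches_naive_average_linkage_oracle(self):
        rng = np.random.default_rng(30)
        for trial in range(10):
            k = int(rng.integers(3, 7))
            s = rng.integers(1, 400, size=(k, k))
            s = np.minimum(s, s.T).astype(float)
            np.fill_diagonal(s, 0)
            ranks = s.astype(np.int64)
            np.fill_diagonal(ranks, 0)
            rm = RankMatrix(tuple(f"s{i}" for i in range(k)),
                            np.maximum(ranks, 1 - np.eye(k, dtype=np.int64)), 500)
            rm_s = rm.min_symmetric().astype(float)
            got_heights = sorted(m[2] for m in cluster_rank_matrix(rm).merges)
            oracle = average_linkage_naive(rm_s[np.ix_(np.argsort(rm.subject_ids),
                                                       np.argsort(rm.subject_ids))])
            expected = sorted(h for _, _, h in oracle)
            assert got_heights == pytest.approx(expected, abs=1e-9)

    def test_needs_two_subjects(self):
        rm = RankMatrix(("a",), np.zeros((1, 1), dtype=int), 10)
        with pytest.raises(GalleryError):
            cluster_rank_matrix(rm)
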