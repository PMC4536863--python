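"""Group-average clustering and SIMPROF node significance."""

import numpy as np
import pytest

from msapop import (
    ResemblanceMatrix,
    agglomerative_cluster,
    annotate_dendrogram,
    build_marker_matrix,
    resemblance_matrix,
    simprof_test,
)
from msapop.scoring import MarkerMatrix


def resemblance_of(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{j}" for j in range(values.shape[0])]
    return ResemblanceMatrix(sample_ids=ids, values=values,
                             measure="BRAY_CURTIS")


def brute_force_average_linkage(d):
    """Naive O(n^3) group-average agglomeration.

    Returns the merge sequence as (frozenset_left, frozenset_right, height).
    """
    n = d.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = clusters[keys[ai]], clusters[keys[bi]]
                h = np.mean([d[i, j] for i in a for j in b])
                if best is None or h < best[0]:
                    best = (h, keys[ai], keys[bi])
        h, ka, kb = best
        merges.append((clusters[ka], clusters[kb], h))
        clusters[min(ka, kb)] = clusters[ka] | clusters[kb]
        del clusters[max(ka, kb)]
    return merges


def merge_partitions(dend):
    out = []
    for k, (left, right, h) in enumerate(dend.merges):
        la = frozenset(dend.leaves_under(left))
        rb = frozenset(dend.leaves_under(right))
        out.append((la, rb, h))
    return out


class TestAgglomerativeCluster:
    def test_unique_merge_order(self):
        s = np.array([
            [1.0, 0.9, 0.1],
            [0.9, 1.0, 0.1],
            [0.1, 0.1, 1.0],
        ])
        dend = agglomerative_cluster(resemblance_of(s))
        (l1, r1, h1), (l2, r2, h2) = merge_partitions(dend)
        assert {l1, r1} == {frozenset([0]), frozenset([1])}
        assert h1 == pytest.approx(0.1)
        assert h2 == pytest.approx(0.9)

    def test_identical_samples_merge_at_zero_height(self):
        s = np.array([[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]])
        dend = agglomerative_cluster(resemblance_of(s))
        assert dend.merges[0][2] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        d = rng.random((n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dend = agglomerative_cluster(resemblance_of(1.0 - d))
        expected = brute_force_average_linkage(d)
        got = merge_partitions(dend)
        for (ea, eb, eh), (ga, gb, gh) in zip(expected, got):
            assert {ea, eb} == {ga, gb}
            assert gh == pytest.approx(eh)

    def test_heights_non_decreasing(self, rng):
        d = rng.random((12, 12))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dend = agglomerative_cluster(resemblance_of(1.0 - d))
        heights = [h for _, _, h in dend.merges]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_non_finite_entries_rejected(self):
        s = np.array([[1.0, np.nan], [np.nan, 1.0]])
        with pytest.raises(ValueError):
            agglomerative_cluster(resemblance_of(s))


class TestSimprof:
    def test_two_sample_node_untestable(self, rng):
        markers = rng.integers(0, 2, size=(30, 2)).astype(float)
        ann = simprof_test(markers, n_perm_mean=9, n_perm_test=9)
        assert not ann.testable and not ann.significant
        assert ann.p is None

    def test_pi_nonnegative_and_p_in_unit_interval(self, rng):
        markers = rng.integers(0, 2, size=(40, 10)).astype(float)
        ann = simprof_test(markers, n_perm_mean=99, n_perm_test=99, rng=3)
        assert ann.pi >= 0.0
        assert 0.0 < ann.p <= 1.0

    def test_pi_is_relabeling_invariant(self, rng):
        markers = rng.integers(0, 2, size=(40, 10)).astype(float)
        perm = rng.permutation(10)
        a = simprof_test(markers, 99, 99, rng=5)
        b = simprof_test(markers[:, perm], 99, 99, rng=5)
        # the observed profile is sorted, hence exactly invariant; the
        # permutation-estimated mean profile (and so pi and p) agrees to
        # Monte-Carlo accuracy
        assert a.pi == pytest.approx(b.pi, abs=0.5)
        assert a.p == pytest.approx(b.p, abs=0.25)

    def test_planted_clusters_detected(self, rng):
        # two groups with disjoint high-frequency marker sets
        g1 = (rng.random((40, 6)) < 0.9).astype(float)
        g2 = (rng.random((40, 6)) < 0.05).astype(float)
        markers = np.hstack([
            np.vstack([g1, g2]), np.vstack([g2, g1]),
        ])
        ann = simprof_test(markers, n_perm_mean=199, n_perm_test=199, rng=7)
        assert ann.significant
        assert ann.p < 0.05


class TestAnnotateDendrogram:
    def _markers_and_dend(self, values):
        mk = MarkerMatrix(
            marker_ids=[f"m{i}" for i in range(values.shape[0])],
            sample_ids=[f"s{j}" for j in range(values.shape[1])],
            values=values.astype(float),
        )
        r = resemblance_matrix(mk, "BRAY_CURTIS")
        return mk, agglomerative_cluster(r)

    def test_homogeneous_data_stops_at_root(self, rng):
        values = rng.integers(0, 2, size=(50, 12))
        mk, dend = self._markers_and_dend(values)
        annotate_dendrogram(dend, mk, rng_seed=2, n_perm_mean=99,
                            n_perm_test=99, alpha=0.01)
        root_ann = dend.simprof[dend.root]
        if not root_ann.significant:
            below = [dend.simprof[n] for n in dend.simprof if n != dend.root]
            assert not any(a.tested for a in below)

    def test_planted_partition_found_and_within_groups_homogeneous(self, small_dataset):
        bands, meta, truth = small_dataset
        mk = build_marker_matrix(bands)
        r = resemblance_matrix(mk, "BRAY_CURTIS")
        dend = agglomerative_cluster(r)
        annotate_dendrogram(dend, mk, rng_seed=4, n_perm_mean=199,
                            n_perm_test=199)
        assert dend.simprof[dend.root].significant
        # at least one node separating planted populations is significant
        n_sig = sum(a.significant for a in dend.simprof.values())
        assert n_sig >= 2

    def test_alpha_zero_means_nothing_significant(self, rng):
        values = rng.integers(0, 2, size=(30, 8))
        mk, dend = self._markers_and_dend(values)
        annotate_dendrogram(dend, mk, alpha=1e-12, rng_seed=0,
                            n_perm_mean=49, n_perm_test=49)
        assert not any(a.significant for a in dend.simprof.values())

    def test_every_node_carries_a_flag(self, rng):
        values = rng.integers(0, 2, size=(30, 9))
        mk, dend = self._markers_and_dend(values)
        annotate_dendrogram(dend, mk, rng_seed=1, n_perm_mean=49,
                            n_perm_test=49)
        internal = set(range(dend.n_leaves, dend.n_leaves + len(dend.merges)))
        assert set(dend.simprof) == internal
        for ann in dend.simprof.values():
            if ann.significant:
                assert ann.testable and ann.tested

    def test_sample_mismatch_is_an_error(self, rng):
        values = rng.integers(0, 2, size=(30, 6))
        mk, dend = self._markers_and_dend(values)
        mk.sample_ids = mk.sample_ids[::-1]
        with pytest.raises(ValueError):
            annotate_dendrogram(dend, mk)
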