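"""Microstate pipeline: GFP, signed-correlation K-means, GEV,
alignment, back-fitting and durations, with brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msconn import microstate as ms
from msconn import synthetic
from msconn.microstate import MicrostateTemplateSet


def _orthogonal_templates(n_channels: int, k: int) -> np.ndarray:
    """Exactly orthogonal average-referenced unit-GFP maps."""
    rng = np.random.default_rng(0)
    raw = rng.normal(size=(n_channels, k + 1))
    raw[:, 0] = 1.0  # force the mean direction into the basis
    q, _ = np.linalg.qr(raw)
    maps = q[:, 1 : k + 1]  # orthogonal to the constant vector -> zero mean
    return maps / np.sqrt((maps**2).mean(axis=0))


class TestGfp:
    def test_two_channel_example(self):
        assert ms.compute_gfp(np.array([[1.0], [-1.0]]))[0] == pytest.approx(1.0)

    def test_flat_map_is_zero(self):
        assert ms.compute_gfp(np.full((8, 3), 2.5)).max() == 0.0

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            ms.compute_gfp(np.ones((1, 10)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(-50, 50))
    def test_reference_shift_invariance(self, seed, offset):
        data = np.random.default_rng(seed).normal(size=(8, 5))
        g1 = ms.compute_gfp(data)
        g2 = ms.compute_gfp(data + offset)
        np.testing.assert_allclose(g1, g2, atol=1e-10)
        assert (g1 >= 0).all()


class TestSpatialCorrelation:
    def test_self_negation_orthogonal(self):
        maps = _orthogonal_templates(16, 2)
        a, b = maps[:, 0], maps[:, 1]
        assert ms.spatial_correlation(a, a) == pytest.approx(1.0)
        assert ms.spatial_correlation(a, -a) == pytest.approx(-1.0)
        assert ms.spatial_correlation(a, b) == pytest.approx(0.0, abs=1e-12)


class TestKmeans:
    def test_two_orthogonal_clusters(self):
        maps = _orthogonal_templates(16, 2)
        samples = np.repeat(maps.T, 20, axis=0) * np.random.default_rng(1).uniform(
            0.5, 2.0, size=(40, 1)
        )
        tset = ms.kmeans_microstates(samples, 2, n_restarts=5, seed=0)
        corr = np.abs(tset.maps.T @ maps / 16)
        # each centroid matches one template perfectly (up to order)
        assert np.allclose(np.sort(corr.max(axis=1)), 1.0, atol=1e-9)
        assert tset.gev == pytest.approx(1.0)

    def test_noiseless_erp_recovery(self, noiseless_epochs):
        epochs, truth, templates = noiseless_epochs
        maps = epochs.data[0].T
        tset = ms.kmeans_microstates(maps, 4, n_restarts=10, seed=0)
        from scipy.optimize import linear_sum_assignment

        corr = templates.T @ tset.maps / templates.shape[0]
        row, col = linear_sum_assignment(-corr)
        np.testing.assert_allclose(corr[row, col], 1.0, atol=1e-6)

    def test_gev_trace_monotone(self, tiny_cohort):
        cohort, _, _ = tiny_cohort
        maps = cohort[0].data.mean(axis=0).T
        _, trace = ms.kmeans_microstates(maps, 4, n_restarts=1, seed=2, return_trace=True)
        diffs = np.diff(trace)
        assert (diffs >= -1e-12).all()

    def test_k_exceeding_samples_rejected(self):
        with pytest.raises(ValueError):
            ms.kmeans_microstates(np.zeros((3, 8)), 5)


class TestGev:
    def test_perfect_fit(self):
        maps = _orthogonal_templates(16, 3)
        data = np.repeat(maps.T, 5, axis=0)
        labels = np.repeat(np.arange(3), 5)
        assert ms.compute_gev(data, maps, labels) == pytest.approx(1.0)

    def test_orthogonal_assignment_is_zero(self):
        maps = _orthogonal_templates(16, 2)
        data = np.tile(maps[:, 0], (4, 1))
        labels = np.full(4, 1)  # assigned to the orthogonal template
        assert ms.compute_gev(data, maps, labels) == pytest.approx(0.0, abs=1e-20)

    def test_nested_template_sets_monotone(self, noiseless_epochs):
        epochs, _, templates = noiseless_epochs
        rng = np.random.default_rng(0)
        extra = np.column_stack([templates, rng.normal(size=(templates.shape[0], 2))])
        data = epochs.data[0].T + rng.normal(scale=0.2, size=epochs.data[0].T.shape)
        gevs = []
        for k in (4, 6):
            sub = extra[:, :k]
            seg = ms.backfit(sub, data.T, times=epochs.times, sampling_rate=250.0)
            gevs.append(ms.compute_gev(data, sub, seg.labels))
        assert gevs[1] >= gevs[0] - 1e-12


class TestCrossValidation:
    def test_bookkeeping_and_determinism(self, tiny_erps):
        erp_lists = {pid: list(d.values()) for pid, d in tiny_erps.items()}
        k1, t1 = ms.cross_validate_k(erp_lists, k_range=(3, 5), n_repeats=2,
                                     n_restarts=2, seed=9)
        k2, t2 = ms.cross_validate_k(erp_lists, k_range=(3, 5), n_repeats=2,
                                     n_restarts=2, seed=9)
        assert k1 == k2
        assert len(t1) == 3 * 2
        np.testing.assert_allclose(t1["test_gev"], t2["test_gev"])
        assert set(t1.columns) == {"repeat", "k", "test_gev", "cv_crit", "silhouette"}

    def test_too_few_participants_rejected(self, tiny_erps):
        some = {k: list(v.values()) for k, v in list(tiny_erps.items())[:3]}
        with pytest.raises(ValueError):
            ms.cross_validate_k(some)

    def test_selects_true_k_on_small_cohort(self, tiny_erps):
        """Per-repeat silhouette votes concentrate on the generator's
        four classes even on a small cohort."""
        erp_lists = {pid: list(d.values()) for pid, d in tiny_erps.items()}
        k, table = ms.cross_validate_k(erp_lists, k_range=(3, 6), n_repeats=10,
                                       n_restarts=3, seed=0)
        votes = (
            table.loc[table.groupby("repeat")["silhouette"].idxmax(), "k"]
            .value_counts()
        )
        assert k == 4
        assert votes.get(4, 0) >= 8  # >= 80% of repeats


class TestAlignment:
    def test_scrambled_identical_sets(self):
        maps = _orthogonal_templates(16, 4)
        perm_in = [np.array([2, 0, 3, 1]), np.array([1, 3, 0, 2]), np.arange(4)]
        sets = [
            MicrostateTemplateSet(maps=maps[:, p], labels=list("ABCD")) for p in perm_in
        ]
        global_set, perms = ms.align_templates(sets)
        # the global mean must equal the common set up to class order
        corr = np.abs(global_set.maps.T @ maps / 16)
        assert np.allclose(np.sort(corr.max(axis=1)), 1.0, atol=1e-9)
        for s, p in zip(sets, perms):
            np.testing.assert_allclose(
                np.abs(np.sum(s.maps[:, p] * global_set.maps, axis=0) / 16), 1.0, atol=1e-9
            )

    def test_polarity_respected(self):
        """A sign-flipped copy of a map must not be matched as the same
        class: |corr| = 1 for the flip, but the SIGNED assignment
        prefers an upright near-copy (r ~ 0.995) over it."""
        maps = _orthogonal_templates(16, 2)
        a0, a1 = maps[:, 0], maps[:, 1]
        ref = MicrostateTemplateSet(maps=maps, labels=["A", "B"])
        near = a0 + 0.1 * a1
        near /= np.sqrt((near**2).mean())
        other = MicrostateTemplateSet(
            maps=np.column_stack([-a0, near]), labels=["A", "B"]
        )
        _, perms = ms.align_templates([ref, ref, other])
        # other's class matched to global class 0 (= a0) must be the
        # upright near-copy (index 1), never the exact flip (index 0)
        assert perms[2][0] == 1

    def test_heterogeneous_k_rejected(self):
        a = MicrostateTemplateSet(maps=_orthogonal_templates(16, 2), labels=["A", "B"])
        b = MicrostateTemplateSet(maps=_orthogonal_templates(16, 3), labels=["A", "B", "C"])
        with pytest.raises(ValueError):
            ms.align_templates([a, b])

    def test_cohort_convergence(self, tiny_cohort):
        cohort, _, _ = tiny_cohort
        sets = [
            ms.kmeans_microstates(ep.data.mean(axis=0).T, 4, n_restarts=3, seed=1)
            for ep in cohort
        ]
        global_set, perms = ms.align_templates(sets, max_iter=100)
        assert global_set.k == 4
        assert len(perms) == len(sets)


class TestBackfit:
    def test_constant_template_epoch(self):
        maps = _orthogonal_templates(16, 3)
        data = np.tile(maps[:, 2][:, None], (1, 40))
        seg = ms.backfit(maps, data, times=np.arange(40) * 4.0, sampling_rate=250.0)
        assert (seg.labels == 2).all()
        np.testing.assert_allclose(seg.correlation, 1.0)

    def test_matches_bruteforce_argmax(self, noiseless_epochs):
        epochs, _, templates = noiseless_epochs
        rng = np.random.default_rng(1)
        data = epochs.data[0] + rng.normal(scale=0.5, size=epochs.data[0].shape)
        seg = ms.backfit(templates, data, times=epochs.times, sampling_rate=250.0)
        # oracle: per-sample loop over classes with np.corrcoef
        for t in range(0, data.shape[1], 7):
            cors = [np.corrcoef(data[:, t], templates[:, j])[0, 1]
                    for j in range(templates.shape[1])]
            assert seg.labels[t] == int(np.argmax(cors))
            assert seg.correlation[t] == pytest.approx(max(cors), abs=1e-12)


class TestDurations:
    def test_single_class_full_epoch(self):
        seg = ms.Segmentation(
            labels=np.zeros(1300, dtype=int), correlation=np.ones(1300),
            times=np.arange(1300) * 4.0, sampling_rate=250.0, class_labels=["A"],
        )
        assert seg.durations_ms()[0] == pytest.approx(5200.0)

    def test_absent_class_and_partition(self):
        labels = np.array([0, 0, 1, 1, 1, 0])
        seg = ms.Segmentation(
            labels=labels, correlation=np.ones(6), times=np.arange(6) * 4.0,
            sampling_rate=250.0, class_labels=["A", "B", "C"],
        )
        d = seg.durations_ms()
        assert d[2] == 0.0
        assert sum(d.values()) == pytest.approx(6 * 4.0)
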