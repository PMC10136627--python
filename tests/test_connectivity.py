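"""PLV estimation, microstate gating and graph metrics, each checked
against closed forms or exhaustive enumeration."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msconn import connectivity as conn
from msconn.microstate import Segmentation


def _segmentation(labels, k):
    labels = np.asarray(labels)
    return Segmentation(
        labels=labels, correlation=np.ones(len(labels)),
        times=np.arange(len(labels)) * 4.0, sampling_rate=250.0,
        class_labels=[chr(65 + i) for i in range(k)],
    )


class TestInstantaneousPhase:
    def test_pure_tone_phase_slope(self):
        sfreq, f = 250.0, 10.0
        t = np.arange(1000) / sfreq
        sig = np.cos(2 * np.pi * f * t)[None, None, :]
        pt = conn.instantaneous_phase(sig, edge_trim=0.1, sampling_rate=sfreq)
        unwrapped = np.unwrap(pt.phase[0, 0])
        slope = np.polyfit(t[pt.valid], unwrapped[pt.valid], 1)[0]
        assert abs(slope - 2 * np.pi * f) / (2 * np.pi * f) < 0.01

    def test_quadrature_pair(self):
        sfreq, f = 250.0, 10.0
        t = np.arange(1000) / sfreq
        sig = np.stack([np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t)])[None]
        pt = conn.instantaneous_phase(sig, edge_trim=0.1, sampling_rate=sfreq)
        diff = np.angle(np.exp(1j * (pt.phase[0, 0] - pt.phase[0, 1])))
        assert np.allclose(diff[pt.valid], np.pi / 2, atol=0.02)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            conn.instantaneous_phase(np.zeros((1, 2, 100)), sampling_rate=250.0)


class TestPlv:
    def test_identical_phases_give_one(self):
        rng = np.random.default_rng(0)
        phases = rng.uniform(-np.pi, np.pi, size=(100, 1, 30))
        p = np.concatenate([phases, phases], axis=1)
        plv = conn.plv_timecourse(p, (0, 1))
        np.testing.assert_array_equal(plv, np.ones(30))

    def test_opposite_phasors_cancel(self):
        p = np.zeros((2, 2, 1))
        p[1, 0, 0] = np.pi  # phase differences 0 and pi
        plv = conn.plv_timecourse(p, (0, 1))
        assert plv[0] == pytest.approx(0.0, abs=1e-15)

    def test_single_trial_is_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(-np.pi, np.pi, size=(1, 2, 20))
        np.testing.assert_allclose(conn.plv_timecourse(p, (0, 1)), 1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(-np.pi, np.pi))
    def test_bounds_and_common_offset_invariance(self, seed, offset):
        rng = np.random.default_rng(seed)
        p = rng.uniform(-np.pi, np.pi, size=(5, 2, 8))
        plv = conn.plv_timecourse(p, (0, 1))
        assert ((plv >= 0) & (plv <= 1 + 1e-12)).all()
        shifted = p + offset  # same offset on both channels
        np.testing.assert_allclose(conn.plv_timecourse(shifted, (0, 1)), plv, atol=1e-12)

    def test_matrix_matches_pairwise(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(-np.pi, np.pi, size=(6, 4, 10))
        cube = conn.plv_matrix_timecourse(p)
        for a, b in itertools.combinations(range(4), 2):
            np.testing.assert_allclose(cube[a, b], conn.plv_timecourse(p, (a, b)), atol=1e-12)


class TestGatedPlv:
    def test_single_class_equals_time_mean(self):
        rng = np.random.default_rng(3)
        plv = rng.uniform(0, 1, size=(3, 3, 8))
        plv = (plv + plv.transpose(1, 0, 2)) / 2
        nets = conn.microstate_gated_plv(plv, _segmentation([0] * 8, 1), n_trials=5)
        expected = plv.mean(axis=2)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(nets[0].adjacency, expected, atol=1e-12)

    def test_constant_plv_identical_across_classes(self):
        plv = np.full((3, 3, 6), 0.4)
        nets = conn.microstate_gated_plv(plv, _segmentation([0, 1, 0, 1, 2, 2], 3))
        for a, b in itertools.combinations(nets.values(), 2):
            np.testing.assert_allclose(a.adjacency, b.adjacency)

    def test_hand_computed_case(self):
        # 3 channels, 4 samples, labels [0, 1, 0, 1]
        plv = np.zeros((3, 3, 4))
        vals = {(0, 1): [0.1, 0.2, 0.3, 0.4], (0, 2): [0.5, 0.6, 0.7, 0.8],
                (1, 2): [0.9, 0.8, 0.7, 0.6]}
        for (a, b), v in vals.items():
            plv[a, b] = plv[b, a] = v
        nets = conn.microstate_gated_plv(plv, _segmentation([0, 1, 0, 1], 2))
        assert nets[0].adjacency[0, 1] == pytest.approx(0.2)  # mean(0.1, 0.3)
        assert nets[1].adjacency[0, 2] == pytest.approx(0.7)  # mean(0.6, 0.8)
        assert nets[1].adjacency[1, 2] == pytest.approx(0.7)  # mean(0.8, 0.6)

    def test_empty_class_marker(self):
        plv = np.full((2, 2, 4), 0.5)
        nets = conn.microstate_gated_plv(plv, _segmentation([0, 0, 0, 0], 2))
        assert not nets[0].empty and nets[1].empty

    def test_time_axis_mismatch_rejected(self):
        with pytest.raises(ValueError):
            conn.microstate_gated_plv(np.zeros((2, 2, 5)), _segmentation([0] * 4, 1))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_gated_value_within_sample_range(self, seed):
        rng = np.random.default_rng(seed)
        plv = rng.uniform(0, 1, size=(3, 3, 10))
        plv = (plv + plv.transpose(1, 0, 2)) / 2
        labels = rng.integers(0, 2, size=10)
        nets = conn.microstate_gated_plv(plv, _segmentation(labels, 2))
        for cls, net in nets.items():
            if net.empty:
                continue
            sub = plv[:, :, labels == cls]
            for a in range(3):
                for b in range(3):
                    if a == b:
                        continue
                    assert sub[a, b].min() - 1e-12 <= net.adjacency[a, b] <= sub[a, b].max() + 1e-12


def _cp_oracle(adj):
    """Exhaustive Onnela weighted clustering: geometric-mean triangle
    intensity over all node triples, weights scaled by the max."""
    n = adj.shape[0]
    w = adj / adj.max()
    cp = np.zeros(n)
    for u in range(n):
        deg = np.count_nonzero(adj[u])
        if deg < 2:
            continue
        s = 0.0
        for v in range(n):
            for x in range(n):
                if len({u, v, x}) == 3:
                    s += (w[u, v] * w[u, x] * w[v, x]) ** (1 / 3)
        cp[u] = s / (deg * (deg - 1))
    return cp


def _lp_oracle(adj):
    """Shortest paths by exhaustive enumeration of simple paths with
    distances 1/weight."""
    n = adj.shape[0]
    best = np.full((n, n), np.inf)
    nodes = list(range(n))
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            for r in range(0, n - 1):
                for mid in itertools.permutations([x for x in nodes if x not in (a, b)], r):
                    path = [a, *mid, b]
                    d = 0.0
                    ok = True
                    for u, v in zip(path, path[1:]):
                        if adj[u, v] == 0:
                            ok = False
                            break
                        d += 1.0 / adj[u, v]
                    if ok:
                        best[a, b] = min(best[a, b], d)
    finite = np.isfinite(best)
    return best[finite].mean(), int(finite.sum())


class TestGraphMetrics:
    def test_binary_triangle_and_star(self):
        tri = np.ones((3, 3)) - np.eye(3)
        per_node, cp = conn.clustering_coefficient(tri, mode="binary", sparsity=1.0)
        np.testing.assert_allclose(per_node, 1.0)
        star = np.zeros((4, 4))
        star[0, 1:] = star[1:, 0] = 1.0
        per_node, cp = conn.clustering_coefficient(star, mode="binary", sparsity=1.0)
        assert cp == 0.0

    def test_binary_complete_and_path_lp(self):
        complete = np.ones((5, 5)) - np.eye(5)
        lp, n = conn.characteristic_path_length(complete, mode="binary", sparsity=1.0)
        assert lp == pytest.approx(1.0)
        path = np.zeros((3, 3))
        path[0, 1] = path[1, 0] = path[1, 2] = path[2, 1] = 1.0
        lp, n = conn.characteristic_path_length(path, mode="binary", sparsity=1.0)
        assert lp == pytest.approx(4.0 / 3.0)

    def test_weighted_cp_against_enumeration(self):
        rng = np.random.default_rng(4)
        adj = rng.uniform(0.1, 1.0, size=(4, 4))
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 0.0)
        per_node, cp = conn.clustering_coefficient(adj, mode="weighted")
        np.testing.assert_allclose(per_node, _cp_oracle(adj), atol=1e-12)

    def test_weighted_lp_against_enumeration(self):
        rng = np.random.default_rng(5)
        adj = rng.uniform(0.1, 1.0, size=(5, 5))
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 0.0)
        lp, n = conn.characteristic_path_length(adj, mode="weighted")
        lp_oracle, n_oracle = _lp_oracle(adj)
        assert lp == pytest.approx(lp_oracle, abs=1e-12)
        assert n == n_oracle

    def test_adding_edges_never_increases_binary_lp(self):
        rng = np.random.default_rng(6)
        adj = np.zeros((6, 6))
        # spanning chain, then add edges one by one
        for i in range(5):
            adj[i, i + 1] = adj[i + 1, i] = 1.0
        lp_prev, _ = conn.characteristic_path_length(adj, mode="binary", sparsity=1.0)
        candidates = [(a, b) for a in range(6) for b in range(a + 1, 6) if adj[a, b] == 0]
        rng.shuffle(candidates)
        for a, b in candidates[:5]:
            adj[a, b] = adj[b, a] = 1.0
            lp, _ = conn.characteristic_path_length(adj, mode="binary", sparsity=1.0)
            assert lp <= lp_prev + 1e-12
            lp_prev = lp

    def test_negative_weights_rejected(self):
        adj = -np.ones((3, 3)) + np.eye(3)
        with pytest.raises(ValueError):
            conn.clustering_coefficient(adj)

    def test_tiny_graph_rejected(self):
        with pytest.raises(ValueError):
            conn.characteristic_path_length(np.zeros((1, 1)))
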