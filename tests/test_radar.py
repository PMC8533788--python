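"""Star projection, layout optimization and position gates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radarcyto import radar
from radarcyto.fcs_io import EventMatrix
from radarcyto.radar import (
    OptimizerConfig,
    PercentileScaler,
    RadarAxis,
    RadarLayout,
    assign_position,
    default_layout,
    define_position_gates,
    optimize_layout,
    project_star,
    separation_score,
)

from conftest import make_matrix

MARKERS3 = ["CD19", "CD10", "CD45"]


def project_oracle(S, layout):
    """Brute-force term-by-term star summation."""
    out = np.zeros((len(S), 2))
    for i in range(len(S)):
        for j, axis in enumerate(layout.axes):
            out[i, 0] += axis.weight * S[i, j] * math.cos(axis.angle)
            out[i, 1] += axis.weight * S[i, j] * math.sin(axis.angle)
    return out


class TestProjection:
    def test_zero_intensities_project_to_origin(self):
        m = make_matrix(np.zeros((5, 3)), MARKERS3)
        layout = default_layout(MARKERS3)
        np.testing.assert_allclose(project_star(m, layout), 0.0)

    def test_single_axis_unit(self):
        layout = RadarLayout((
            RadarAxis("CD19", 0.0, 1.0),
            RadarAxis("CD10", 0.0, 0.0),
            RadarAxis("CD45", 0.0, 0.0),
        ))
        m = make_matrix([[1.0, 7.0, 7.0]], MARKERS3)
        np.testing.assert_allclose(project_star(m, layout), [[1.0, 0.0]],
                                   atol=1e-12)

    def test_three_axes_against_summation_oracle(self):
        layout = RadarLayout(tuple(
            RadarAxis(mk, math.radians(deg), 1.0)
            for mk, deg in zip(MARKERS3, (0, 120, 240))
        ))
        m = make_matrix([[0.5, 0.5, 1.0]], MARKERS3)
        np.testing.assert_allclose(
            project_star(m, layout), project_oracle(m.values, layout),
            atol=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_random_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_axes = int(rng.integers(3, 8))
        markers = [f"M{j}" for j in range(n_axes)]
        layout = RadarLayout(tuple(
            RadarAxis(mk, float(rng.uniform(0, 2 * math.pi - 1e-9)),
                      float(rng.uniform(0, 3)))
            for mk in markers
        ))
        S = rng.uniform(0, 1, size=(int(rng.integers(1, 20)), n_axes))
        m = make_matrix(S, markers)
        np.testing.assert_allclose(
            project_star(m, layout), project_oracle(S, layout), atol=1e-12)

    def test_linear_in_intensities(self):
        rng = np.random.default_rng(1)
        S = rng.uniform(0, 1, (10, 3))
        layout = default_layout(MARKERS3)
        a = 2.75
        p1 = project_star(make_matrix(S, MARKERS3), layout)
        p2 = project_star(make_matrix(a * S, MARKERS3), layout)
        np.testing.assert_allclose(p2, a * p1, atol=1e-12)

    def test_missing_marker_named_in_error(self):
        m = make_matrix(np.zeros((2, 2)), ["CD19", "CD10"])
        with pytest.raises(KeyError, match="CD45"):
            project_star(m, default_layout(MARKERS3))


class TestSeparationScore:
    def test_zero_when_centroids_coincide(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0]] * 4)
        labels = np.array(["a", "a", "b", "b"] * 2, dtype=object)
        assert separation_score(pts, labels, ["a"], ["b"]) == 0.0

    def test_scale_invariant(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal(0, 1, (50, 2)),
                         rng.normal(4, 1, (50, 2))])
        labels = np.array(["a"] * 50 + ["b"] * 50, dtype=object)
        s1 = separation_score(pts, labels, ["a"], ["b"])
        s2 = separation_score(17.0 * pts, labels, ["a"], ["b"])
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_rotation_invariant(self):
        # invariance justifies fixing one axis angle in exhaustive search
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 1, (40, 2)),
                         rng.normal(3, 1, (40, 2))])
        labels = np.array(["a"] * 40 + ["b"] * 40, dtype=object)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        s1 = separation_score(pts, labels, ["a"], ["b"])
        s2 = separation_score(pts @ R.T, labels, ["a"], ["b"])
        assert s1 == pytest.approx(s2, rel=1e-9)


def toy_instance(seed=0, delta=3.0):
    """Two populations that differ in exactly one of three markers."""
    rng = np.random.default_rng(seed)
    n = 60
    norm = np.column_stack([
        rng.normal(0.0, 0.3, n), rng.normal(1.0, 0.3, n),
        rng.normal(1.0, 0.3, n)])
    path = np.column_stack([
        rng.normal(delta, 0.3, n), rng.normal(1.0, 0.3, n),
        rng.normal(1.0, 0.3, n)])
    values = np.vstack([norm, path])
    labels = np.array(["norm"] * n + ["path"] * n, dtype=object)
    return make_matrix(values, MARKERS3, labels=labels)


def hand_scale(X):
    lo = np.percentile(X, 1, axis=0)
    hi = np.percentile(X, 99, axis=0)
    return np.clip((X - lo) / (hi - lo), 0.0, 1.0)


def hand_score(P, labels):
    a = P[labels == "norm"]
    b = P[labels == "path"]
    d = np.hypot(*(a.mean(0) - b.mean(0)))
    spread = math.sqrt(0.5 * (a.var(0).sum() + b.var(0).sum()))
    return d / spread


def exhaustive_toy_optimum(m, config=OptimizerConfig()):
    """Exhaustive search over the discrete layout space of a 3-marker
    toy. The objective is rotation-invariant, so the first marker's
    angle is fixed at zero without loss of optimality."""
    S = hand_scale(m.values)
    labels = np.asarray(m.labels, dtype=object)
    angles = 2 * math.pi * np.arange(config.n_angles) / config.n_angles
    best = -math.inf
    for w0 in config.weights:
        v0 = np.array([w0, 0.0])
        for a1 in angles:
            for w1 in config.weights:
                v1 = w1 * np.array([math.cos(a1), math.sin(a1)])
                for a2 in angles:
                    for w2 in config.weights:
                        v2 = w2 * np.array([math.cos(a2), math.sin(a2)])
                        P = np.outer(S[:, 0], v0) + np.outer(S[:, 1], v1) \
                            + np.outer(S[:, 2], v2)
                        best = max(best, hand_score(P, labels))
    return best


class TestOptimizer:
    def test_differing_marker_gets_maximal_weight(self):
        m = toy_instance()
        layout = optimize_layout(
            m, ["norm"], ["path"],
            config=OptimizerConfig(seed=0, pooled_weight=0.0))
        by_marker = {a.marker: a.weight for a in layout.axes}
        assert by_marker["CD19"] == max(by_marker.values())

    def test_never_below_default_layout(self):
        m = toy_instance(seed=5)
        layout = optimize_layout(m, ["norm"], ["path"],
                                 config=OptimizerConfig(seed=3))
        scaler = PercentileScaler.fit(m, MARKERS3)
        pts = project_star(m, default_layout(MARKERS3), scaler)
        d_score = separation_score(pts, m.labels, ["norm"], ["path"])
        assert layout.score >= d_score - 1e-12

    def test_requires_two_labelled_populations(self):
        m = toy_instance()
        with pytest.raises(ValueError):
            optimize_layout(m, [], ["path"])
        with pytest.raises(ValueError):
            optimize_layout(m, ["norm"], ["absent"],
                            config=OptimizerConfig())


def _cluster_gateset(tube=1, k=6):
    rng = np.random.default_rng(0)
    centers = np.array([
        [2.0 * math.cos(2 * math.pi * j / k),
         2.0 * math.sin(2 * math.pi * j / k)] for j in range(k)
    ])
    centroids = np.vstack([
        c + rng.normal(0, 0.02, (5, 2)) for c in centers
    ])
    gates = define_position_gates(centroids, tube, ((0.0, 0.0), 0.5), seed=0)
    return gates, centers


class TestPositionGates:
    def test_gate_counts_per_tube(self):
        g1, _ = _cluster_gateset(tube=1, k=6)
        g2, _ = _cluster_gateset(tube=2, k=4)
        assert len(g1.gates) == 6
        assert len(g2.gates) == 4

    def test_gates_pairwise_disjoint_and_avoid_normal_region(self):
        gates, _ = _cluster_gateset()
        labels = sorted(gates.gates)
        for i in labels:
            for j in labels:
                if i < j:
                    inter = gates.gates[i].intersection(gates.gates[j])
                    assert inter.area < 1e-9
            assert gates.gates[i].intersection(gates.normal_region).area \
                < 1e-9

    def test_tight_clusters_map_to_distinct_gates(self):
        gates, centers = _cluster_gateset()
        assigned = gates.assign_events(centers)
        assert len(set(assigned)) == 6
        assert 0 not in assigned

    def test_insufficient_centroids(self):
        with pytest.raises(ValueError):
            define_position_gates(np.zeros((3, 2)), 1, ((0, 0), 0.1))

    def test_yaml_roundtrip(self, tmp_path):
        gates, centers = _cluster_gateset()
        p = tmp_path / "gates.yaml"
        gates.save(p)
        back = radar.PositionGateSet.load(p)
        assert sorted(back.gates) == sorted(gates.gates)
        np.testing.assert_array_equal(
            back.assign_events(centers), gates.assign_events(centers))


class TestAssignPosition:
    def test_all_in_one_gate(self):
        gates, centers = _cluster_gateset()
        lab = int(gates.assign_events(centers[2:3])[0])
        pts = np.tile(centers[2], (100, 1))
        assert assign_position(pts, gates) == lab

    def test_plurality_wins(self):
        gates, centers = _cluster_gateset()
        la = int(gates.assign_events(centers[0:1])[0])
        lb = int(gates.assign_events(centers[3:4])[0])
        pts = np.vstack([np.tile(centers[0], (60, 1)),
                         np.tile(centers[3], (40, 1))])
        assert assign_position(pts, gates) == la
        pts = np.vstack([np.tile(centers[0], (40, 1)),
                         np.tile(centers[3], (60, 1))])
        assert assign_position(pts, gates) == lb

    def test_tie_breaks_to_lower_label(self):
        gates, centers = _cluster_gateset()
        la = int(gates.assign_events(centers[0:1])[0])
        lb = int(gates.assign_events(centers[3:4])[0])
        pts = np.vstack([np.tile(centers[0], (50, 1)),
                         np.tile(centers[3], (50, 1))])
        assert assign_position(pts, gates) == min(la, lb)

    def test_empty_blast_set_raises(self):
        gates, _ = _cluster_gateset()
        with pytest.raises(ValueError, match="no blasts"):
            assign_position(np.empty((0, 2)), gates)


class TestLayoutSerialization:
    def test_yaml_roundtrip(self, tmp_path):
        layout = RadarLayout(
            (RadarAxis("CD19", 0.0, 1.0), RadarAxis("CD10", 1.0, 2.0),
             RadarAxis("CD45", 2.0, 0.5)),
            score=1.25,
        )
        p = tmp_path / "layout.yaml"
        layout.save(p)
        back = RadarLayout.load(p)
        assert back.markers == layout.markers
        assert back.score == 1.25
        for a, b in zip(back.axes, layout.axes):
            assert a.angle == pytest.approx(b.angle, abs=1e-12)


class TestReferenceSeparability:
    def test_normal_blast_linearly_separable_in_optimized_space(
            self, reference_bundle):
        """Normal and pathological events are close to linearly separable
        in the optimized radar space.

        Perfect separation is not attainable: a sampled blast phenotype
        can genuinely shadow the hematogone maturation continuum, so
        even an unrestricted linear classifier in the full scaled marker
        space tops out near 96-97% on this merged fixture (see the
        methods note). The property asserted is that the optimized 2-D
        projection stays within 2.5 points of that full-space linear
        ceiling, and comfortably above 90%."""
        from sklearn.linear_model import LogisticRegression

        pts = reference_bundle.points()
        y = reference_bundle.is_normal()
        sel = np.isin(
            reference_bundle.sep_labels,
            reference_bundle.normal_labels + reference_bundle.path_labels)
        acc_2d = LogisticRegression().fit(
            pts[sel], y[sel]).score(pts[sel], y[sel])
        S = reference_bundle.scaler.transform(
            reference_bundle.merged, reference_bundle.scaler.markers)
        acc_full = LogisticRegression(max_iter=2000).fit(
            S[sel], y[sel]).score(S[sel], y[sel])
        assert acc_2d >= acc_full - 0.025
        assert acc_2d >= 0.90
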