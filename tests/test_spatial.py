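import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from histoquant.spatial import (
    IPDMatrix,
    cluster_angular_difference,
    cluster_nuclei,
    compute_ipd_matrix,
    ipd_dispersion,
)
from histoquant.synthetic import generate_point_pattern


def _frame(xy, ids=None, orientations=None, scores=None):
    df = pd.DataFrame(xy, columns=["x_um", "y_um"])
    df["nucleus_id"] = ids if ids is not None else np.arange(1, len(df) + 1)
    if orientations is not None:
        df["orientation_deg"] = orientations
    if scores is not None:
        df["score"] = scores
    return df


def brute_force_ipd(xy):
    import math

    n = len(xy)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dx = float(xy[i][0]) - float(xy[j][0])
            dy = float(xy[i][1]) - float(xy[j][1])
            out[i, j] = math.sqrt(dx * dx + dy * dy)
    return out


class TestIPDMatrix:
    def test_three_four_five(self):
        m = compute_ipd_matrix(_frame([(0.0, 0.0), (3.0, 4.0)]))
        assert m.matrix[0, 1] == 5.0
        assert m.matrix[1, 0] == 5.0

    def test_symmetry_zero_diagonal(self):
        xy = generate_point_pattern(40, 15.0, seed=0)
        m = compute_ipd_matrix(_frame(xy))
        assert np.array_equal(m.matrix, m.matrix.T)
        assert np.all(np.diag(m.matrix) == 0.0)

    def test_matches_brute_force_oracle_exactly(self):
        xy = generate_point_pattern(100, 25.0, seed=1)
        m = compute_ipd_matrix(_frame(xy))
        assert np.array_equal(m.matrix, brute_force_ipd(xy))

    def test_scaling_homogeneity(self):
        xy = generate_point_pattern(50, 10.0, seed=2)
        m1 = compute_ipd_matrix(_frame(xy))
        m2 = compute_ipd_matrix(_frame(xy * 2.0))
        assert np.allclose(m2.matrix, 2.0 * m1.matrix, rtol=1e-12)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            compute_ipd_matrix(_frame([(0, 0), (1, 1)], ids=[1, 1]))

    def test_requires_two(self):
        with pytest.raises(ValueError):
            compute_ipd_matrix(_frame([(0.0, 0.0)]))

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            IPDMatrix(ids=[1, 2], matrix=np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_triangle_inequality(self):
        xy = generate_point_pattern(30, 8.0, seed=3)
        m = compute_ipd_matrix(_frame(xy)).matrix
        lhs = m[:, :, None]
        rhs = m[:, None, :] + m[None, :, :]
        assert np.all(lhs <= rhs + 1e-9)

    def test_csv_roundtrip(self, tmp_path):
        m = compute_ipd_matrix(_frame(generate_point_pattern(10, 5.0, seed=4)))
        m.to_csv(tmp_path / "ipd.csv")
        back = IPDMatrix.from_csv(tmp_path / "ipd.csv")
        assert np.allclose(back.matrix, m.matrix)


class TestDispersion:
    def test_collinear_hand_computation(self):
        # Distances {1, 1, 2}: sample SD = 0.5774 to 4 decimal places.
        m = compute_ipd_matrix(_frame([(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)]))
        assert ipd_dispersion(m) == pytest.approx(0.5774, abs=5e-5)

    def test_coincident_points(self):
        m = compute_ipd_matrix(_frame([(1.0, 1.0)] * 5, ids=list(range(5))))
        assert ipd_dispersion(m) == 0.0

    def test_two_points_returns_zero(self, caplog):
        m = compute_ipd_matrix(_frame([(0.0, 0.0), (3.0, 4.0)]))
        with caplog.at_level(logging.INFO):
            assert ipd_dispersion(m) == 0.0
        assert "one distance" in caplog.text

    def test_rigid_motion_invariance(self):
        xy = generate_point_pattern(60, 12.0, seed=5)
        th = np.deg2rad(37.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = xy @ rot.T + np.array([100.0, -50.0])
        d1 = ipd_dispersion(compute_ipd_matrix(_frame(xy)))
        d2 = ipd_dispersion(compute_ipd_matrix(_frame(moved)))
        assert d2 == pytest.approx(d1, rel=1e-9)

    def test_linear_scaling(self):
        xy = generate_point_pattern(60, 12.0, seed=6)
        d1 = ipd_dispersion(compute_ipd_matrix(_frame(xy)))
        d3 = ipd_dispersion(compute_ipd_matrix(_frame(xy * 3.0)))
        assert d3 == pytest.approx(3.0 * d1, rel=1e-9)

    def test_generator_dispersion_ratio(self):
        ratios = []
        for seed in range(20):
            m1 = compute_ipd_matrix(_frame(generate_point_pattern(200, 10.0, seed=seed)))
            m2 = compute_ipd_matrix(_frame(generate_point_pattern(200, 20.0, seed=500 + seed)))
            ratios.append(ipd_dispersion(m2) / ipd_dispersion(m1))
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)


class TestClustering:
    @staticmethod
    def _two_blobs(seed=0, n=150, sep=500.0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 20.0, size=(n, 2))
        b = rng.normal(0.0, 20.0, size=(n, 2)) + np.array([sep, 0.0])
        xy = np.vstack([a, b])
        scores = np.concatenate(
            [np.clip(rng.normal(0.2, 0.02, n), 0, 1), np.clip(rng.normal(0.8, 0.02, n), 0, 1)]
        )
        orientations = rng.uniform(-90, 90, 2 * n)
        planted = np.array([0] * n + [1] * n)
        return _frame(xy, orientations=orientations, scores=scores), planted

    def test_two_planted_blobs_recovered(self):
        df, planted = self._two_blobs()
        assignment = cluster_nuclei(df, min_cluster_size=5, extent=1000.0)
        assert len(assignment.table) == 2
        means = sorted(assignment.table.mean_score)
        assert means[0] == pytest.approx(0.2, abs=0.05)
        assert means[1] == pytest.approx(0.8, abs=0.05)

    def test_planted_label_agreement(self):
        df, planted = self._two_blobs(seed=1)
        assignment = cluster_nuclei(df, min_cluster_size=5, extent=1000.0)
        keep = assignment.labels != -1
        assert adjusted_rand_score(planted[keep], assignment.labels[keep]) >= 0.9

    def test_single_blob(self):
        rng = np.random.default_rng(2)
        xy = rng.normal(0.0, 10.0, size=(100, 2))
        df = _frame(xy, scores=np.full(100, 0.5) + rng.normal(0, 0.01, 100))
        assignment = cluster_nuclei(df, min_cluster_size=5, extent=600.0)
        assert len(assignment.table) == 1
        assert assignment.table.n.max() >= 90

    def test_min_cluster_size_exceeds_n(self):
        df, _ = self._two_blobs(seed=3, n=10)
        assignment = cluster_nuclei(df, min_cluster_size=100)
        assert np.all(assignment.labels == -1)
        assert assignment.table.empty

    def test_missing_scores_rejected(self):
        df = _frame(generate_point_pattern(20, 5.0, seed=4))
        with pytest.raises(ValueError, match="scores"):
            cluster_nuclei(df)

    def test_bad_feature_set(self):
        df, _ = self._two_blobs()
        with pytest.raises(ValueError, match="feature_set"):
            cluster_nuclei(df, feature_set="bogus")


class TestAngularDifference:
    def test_identical_orientations_zero(self):
        df, _ = self._blob_with_orientations(np.full(20, 33.0))
        assignment = cluster_nuclei(df, min_cluster_size=5, extent=300.0)
        diffs = cluster_angular_difference(assignment, df)
        assert np.allclose(diffs.dropna(), 0.0)

    def test_axial_wrap_pair(self):
        from histoquant.axial import mean_pairwise_axial_difference

        assert mean_pairwise_axial_difference([10.0, 170.0]) == pytest.approx(20.0)

    def test_uniform_orientations_expect_45(self):
        rng = np.random.default_rng(5)
        df, _ = self._blob_with_orientations(rng.uniform(-90, 90, 300))
        assignment = cluster_nuclei(df, min_cluster_size=5, extent=300.0)
        diffs = cluster_angular_difference(assignment, df)
        big = assignment.table.sort_values("n", ascending=False).iloc[0]
        assert diffs.loc[big.cluster] == pytest.approx(45.0, abs=1.0)

    @staticmethod
    def _blob_with_orientations(orientations):
        n = len(orientations)
        rng = np.random.default_rng(9)
        xy = rng.normal(0.0, 5.0, size=(n, 2))
        scores = np.full(n, 0.5) + rng.normal(0, 0.005, n)
        return _frame(xy, orientations=orientations, scores=scores), None

    @given(st.lists(st.floats(-90, 90), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_pairwise_mean_bounded(self, angles):
        from histoquant.axial import mean_pairwise_axial_difference

        d = mean_pairwise_axial_difference(angles)
        assert 0.0 <= d <= 90.0
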