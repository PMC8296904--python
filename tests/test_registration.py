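"""Similarity fitting and ICP: closed-form optimality, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from eeglocate import (
    DegenerateGeometryError,
    ICPParams,
    SimilarityTransform,
    apply_transform,
    fit_similarity,
    icp,
)
from .conftest import random_similarity


def numeric_fit_rms(src: np.ndarray, tgt: np.ndarray) -> float:
    """Independent oracle: 7-parameter least-squares over (rotvec, log s, t)."""

    def resid(p):
        R = Rotation.from_rotvec(p[:3]).as_matrix()
        return (np.exp(p[3]) * src @ R.T + p[4:] - tgt).ravel()

    p0 = np.zeros(7)
    p0[4:] = tgt.mean(axis=0) - src.mean(axis=0)
    sol = least_squares(resid, p0, method="lm", xtol=1e-15, ftol=1e-15)
    return float(np.sqrt(np.mean(np.sum(sol.fun.reshape(-1, 3) ** 2, axis=1))))


def rms(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


class TestFitSimilarity:
    def test_identity_on_equal_sets(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [3, 4, 12.0]])
        T = fit_similarity(pts, pts)
        assert T.scale == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(T.translation, 0.0, atol=1e-9)

    def test_pure_translation(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [3, 4, 12.0]])
        T = fit_similarity(pts, pts + np.array([10.0, 0.0, 0.0]))
        assert T.scale == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(T.translation, [10, 0, 0], atol=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_numerical_minimizer(self, seed):
        """The closed form attains the brute-force least-squares optimum."""
        rng = np.random.default_rng([seed, 99])
        src = rng.uniform(-50, 50, (6, 3))
        T_true = random_similarity(rng, 45.0, (0.8, 1.2), 30.0)
        tgt = T_true.apply(src) + rng.normal(0, 0.3, src.shape)
        T = fit_similarity(src, tgt)
        assert rms(T.apply(src), tgt) <= numeric_fit_rms(src, tgt) + 1e-6

    @pytest.mark.parametrize("seed", range(10))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng([seed, 5])
        src = rng.uniform(-50, 50, (8, 3))
        tgt = random_similarity(rng).apply(src) + rng.normal(0, 5.0, src.shape)
        perm = rng.permutation(8)
        T = fit_similarity(src, tgt)
        Tp = fit_similarity(src[perm], tgt[perm])
        assert Tp.scale == pytest.approx(T.scale, abs=1e-12)
        np.testing.assert_allclose(Tp.rotation, T.rotation, atol=1e-10)
        np.testing.assert_allclose(Tp.translation, T.translation, atol=1e-8)

    def test_too_few_points(self):
        pts = np.array([[0, 0, 0], [1, 0, 0.0]])
        with pytest.raises(DegenerateGeometryError):
            fit_similarity(pts, pts)

    def test_collinear_source(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]])
        tgt = np.random.default_rng(0).uniform(-10, 10, (4, 3))
        with pytest.raises(DegenerateGeometryError):
            fit_similarity(src, tgt)

    def test_reflection_never_returned(self):
        rng = np.random.default_rng(7)
        src = rng.uniform(-50, 50, (10, 3))
        tgt = src * np.array([-1.0, 1.0, 1.0])  # mirrored target
        T = fit_similarity(src, tgt)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_extreme_scale_warns(self):
        rng = np.random.default_rng(3)
        src = rng.uniform(-50, 50, (6, 3))
        with pytest.warns(UserWarning, match="scale"):
            fit_similarity(src, src * 3.0)


class TestApplyTransform:
    def test_identity(self):
        pts = np.random.default_rng(0).uniform(-10, 10, (5, 3))
        np.testing.assert_array_equal(
            apply_transform(SimilarityTransform.identity(), pts), pts
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_inverse_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        T = random_similarity(rng, 60.0, (0.7, 1.4), 50.0)
        pts = rng.uniform(-80, 80, (12, 3))
        back = apply_transform(T.inverse(), apply_transform(T, pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_scaling_doubles_distances(self):
        pts = np.random.default_rng(1).uniform(-10, 10, (6, 3))
        T = SimilarityTransform(2.0, np.eye(3), np.zeros(3))
        out = apply_transform(T, pts)
        d_in = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d_out = np.linalg.norm(out[:, None] - out[None], axis=-1)
        np.testing.assert_allclose(d_out, 2.0 * d_in, atol=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        angle=st.floats(0, np.pi),
        scale=st.floats(0.5, 2.0),
        tx=st.floats(-100, 100),
    )
    def test_compose_matches_sequential_application(self, angle, scale, tx):
        A = SimilarityTransform(
            scale, Rotation.from_rotvec([0, 0, angle]).as_matrix(), [tx, 1.0, -2.0]
        )
        B = SimilarityTransform(
            1.1, Rotation.from_rotvec([angle / 2, 0, 0]).as_matrix(), [0.0, tx, 3.0]
        )
        pts = np.array([[1, 2, 3], [-4, 5, -6], [7, -8, 9.0]])
        np.testing.assert_allclose(
            A.compose(B).apply(pts), A.apply(B.apply(pts)), atol=1e-8
        )


class TestICP:
    def test_already_aligned(self, default_cap):
        res = icp(default_cap.points, default_cap.points)
        assert res.rms_residual == pytest.approx(0.0, abs=1e-9)
        assert res.transform.scale == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_array_equal(res.correspondence, np.arange(65))

    def test_recovers_known_transform_noise_free(self, default_cap):
        rng = np.random.default_rng(11)
        T = random_similarity(rng, 15.0, (1.05, 1.05), 20.0)
        fixed = T.apply(default_cap.points)
        res = icp(default_cap.points, fixed)
        assert res.rms_residual < 1e-3
        assert rms(res.transform.apply(default_cap.points), fixed) < 1e-3

    @pytest.mark.parametrize("seed", range(20))
    def test_residual_history_non_increasing(self, default_cap, seed):
        rng = np.random.default_rng([seed, 3])
        T = random_similarity(rng)
        fixed = T.apply(default_cap.points) + rng.normal(
            0, 1.0, default_cap.points.shape
        )
        res = icp(default_cap.points, fixed)
        hist = np.asarray(res.residual_history)
        assert np.all(np.diff(hist) <= 1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_conjugation_consistency(self, default_cap, seed):
        """Transforming both clouds by A leaves the aligned residual unchanged."""
        rng = np.random.default_rng([seed, 8])
        T = random_similarity(rng, 10.0, (0.98, 1.02), 10.0)
        fixed = T.apply(default_cap.points) + rng.normal(
            0, 0.5, default_cap.points.shape
        )
        A = random_similarity(rng, 30.0, (0.9, 1.1), 40.0)
        res = icp(default_cap.points, fixed)
        res_conj = icp(A.apply(default_cap.points), A.apply(fixed))
        # residuals scale with A's isotropic factor
        assert res_conj.rms_residual == pytest.approx(
            A.scale * res.rms_residual, abs=1e-6
        )

    def test_empty_fixed_rejected(self, default_cap):
        with pytest.raises(ValueError):
            icp(default_cap.points, np.empty((0, 3)))

    def test_degenerate_moving_rejected(self):
        fixed = np.random.default_rng(0).uniform(-10, 10, (10, 3))
        with pytest.raises(DegenerateGeometryError):
            icp(np.array([[0, 0, 0], [1, 1, 1.0]]), fixed)

    def test_deterministic(self, default_cap):
        rng = np.random.default_rng(21)
        fixed = random_similarity(rng).apply(default_cap.points) + rng.normal(
            0, 1.0, default_cap.points.shape
        )
        a = icp(default_cap.points, fixed)
        b = icp(default_cap.points, fixed)
        np.testing.assert_array_equal(a.transform.rotation, b.transform.rotation)
        assert a.rms_residual == b.rms_residual
        assert a.iterations_used == b.iterations_used


def test_icp_params_validation():
    with pytest.raises(ValueError):
        ICPParams(max_iterations=0)
    with pytest.raises(ValueError):
        ICPParams(tolerance=0.0)
    with pytest.raises(ValueError):
        ICPParams(initialization="given")


def test_transform_json_round_trip(tmp_path):
    T = random_similarity(np.random.default_rng(2))
    path = tmp_path / "t.json"
    T.to_json(path)
    T2 = SimilarityTransform.from_json(path)
    assert T2.scale == pytest.approx(T.scale)
    np.testing.assert_allclose(T2.rotation, T.rotation)
    np.testing.assert_allclose(T2.translation, T.translation)
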