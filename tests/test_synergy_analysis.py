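"""Windowed PCA pipeline: unfolding, pooling, synergies, derived measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from goalbabbling.arm_model import HOME_H1, HOME_H2, BASELINE_POSTURE, forward_kinematics
from goalbabbling.io_cli import BlockRecord, SessionRecord, TestTrial
from goalbabbling.synergy_analysis import (
    DegenerateWindowError,
    analyze_store,
    morphology_vs_task_pca,
    pca_synergies,
    performance_curve,
    pool_windows,
    principal_angle,
    project_central_posture,
    q2_loading,
    summed_variance,
    unfold_angles,
)
from goalbabbling.synthetic_human import HumanGeneratorParams, generate_population
from goalbabbling.task_interface import FingerMapping, fingers_to_posture


def _session(postures_by_block, targets=None, missing=(), condition="H1", mapping=None):
    """Build a minimal session from a (blocks, trials, 3) posture array."""
    blocks = []
    for b, rows in enumerate(postures_by_block):
        trials = []
        for j, q in enumerate(rows):
            if (b + 1, j) in missing:
                trials.append(TestTrial(target=[0.0, 0.5], posture=None, endpoint=None,
                                        missing=True))
            else:
                endpoint = forward_kinematics(q).tolist()
                target = list(targets[j]) if targets is not None else [0.0, 0.5]
                trials.append(TestTrial(target=target, posture=list(q), endpoint=endpoint))
        blocks.append(BlockRecord(index=b + 1, test=trials))
    return SessionRecord(
        session_id="toy", kind="synthetic_human", condition=condition,
        mapping=mapping, seed=0, config={}, blocks=blocks,
    )


class TestUnfoldAngles:
    def test_negative_angles_retained(self):
        np.testing.assert_array_equal(unfold_angles([-0.5, 7.0, 1.0]), [-0.5, 7.0, 1.0])

    def test_in_range_unchanged(self, rng):
        q = rng.uniform(0, 2 * np.pi, (5, 3))
        np.testing.assert_array_equal(unfold_angles(q), q)

    def test_goal_space_effect_is_periodic(self, rng):
        q = rng.uniform(-10, 10, 3)
        wrapped = np.mod(q, 2 * np.pi)
        np.testing.assert_allclose(
            forward_kinematics(unfold_angles(q)), forward_kinematics(wrapped), atol=1e-12
        )


class TestPoolWindows:
    def test_complete_human_session_pools_27_rows(self, rng):
        postures = rng.normal(size=(24, 9, 3))
        windows = pool_windows(_session(postures), bin_size=3)
        assert len(windows) == 8
        assert all(w.matrix.shape == (27, 3) for w in windows)

    def test_missing_trials_dropped_rowwise(self, rng):
        postures = rng.normal(size=(24, 9, 3))
        windows = pool_windows(
            _session(postures, missing={(1, 0), (2, 5)}), bin_size=3
        )
        assert windows[0].matrix.shape == (25, 3)
        assert windows[0].n_missing == 2
        assert all(w.matrix.shape == (27, 3) for w in windows[1:])

    def test_agent_windowing_is_per_block(self, rng):
        postures = rng.normal(size=(10, 9, 3))
        windows = pool_windows(_session(postures), bin_size=1)
        assert len(windows) == 10
        assert all(w.matrix.shape == (9, 3) for w in windows)

    def test_bin_size_must_divide_blocks(self, rng):
        with pytest.raises(ValueError, match="divide"):
            pool_windows(_session(rng.normal(size=(24, 9, 3))), bin_size=5)


class TestPcaSynergies:
    def test_collinear_cloud_is_rank_one(self, rng):
        direction = np.array([1.0, 2.0, -1.0])
        X = BASELINE_POSTURE + np.outer(rng.normal(size=27), direction)
        res = pca_synergies(X)
        np.testing.assert_allclose(res.variance_fractions, [1.0, 0.0, 0.0], atol=1e-12)

    def test_planted_plane_recovered_exactly(self, rng):
        basis, _ = np.linalg.qr(rng.normal(size=(3, 2)))
        t = np.linspace(0, 2 * np.pi, 27, endpoint=False)
        Z = np.column_stack([np.cos(t), 0.5 * np.sin(t)])
        X = BASELINE_POSTURE + Z @ basis.T
        res = pca_synergies(X)
        assert res.variance_fractions[2] == pytest.approx(0.0, abs=1e-12)
        assert principal_angle(basis, res.loadings[:2].T) < 1e-6

    def test_fractions_match_explicit_covariance_eigendecomposition(self, rng):
        X = rng.normal(size=(27, 3))
        res = pca_synergies(X)
        # independent oracle: explicit covariance sums, then eigenvalues
        n = X.shape[0]
        mu = X.sum(axis=0) / n
        C = np.zeros((3, 3))
        for row in X:
            C += np.outer(row - mu, row - mu)
        C /= n - 1
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        np.testing.assert_allclose(res.variance_fractions, evals / evals.sum(), atol=1e-10)
        np.testing.assert_allclose(res.variances, evals, atol=1e-10)

    def test_loadings_orthonormal_with_positive_peak(self, rng):
        res = pca_synergies(rng.normal(size=(30, 3)))
        np.testing.assert_allclose(res.loadings @ res.loadings.T, np.eye(3), atol=1e-10)
        for row in res.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_degenerate_windows_rejected(self):
        with pytest.raises(DegenerateWindowError, match="insufficient"):
            pca_synergies(np.zeros((3, 3)))
        with pytest.raises(DegenerateWindowError, match="variance"):
            pca_synergies(np.ones((5, 3)))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_rotation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 3)) * [2.0, 1.0, 0.3]
        R = Rotation.random(random_state=seed).as_matrix()
        res = pca_synergies(X)
        res_rot = pca_synergies(X @ R.T)
        np.testing.assert_allclose(
            res_rot.variance_fractions, res.variance_fractions, atol=1e-8
        )
        # rotated loadings span the rotated components
        for i in range(3):
            dot = abs(res_rot.loadings[i] @ (R @ res.loadings[i]))
            assert dot == pytest.approx(1.0, abs=1e-8)


class TestLocationProjection:
    def test_endpoints(self):
        assert project_central_posture(HOME_H1) == pytest.approx(0.0)
        assert project_central_posture(HOME_H2) == pytest.approx(1.0)

    def test_baseline_posture_is_midway(self):
        assert project_central_posture(BASELINE_POSTURE) == pytest.approx(0.5, abs=1e-3)

    def test_orthogonal_offsets_ignored(self, rng):
        axis = HOME_H2 - HOME_H1
        v = rng.normal(size=3)
        v -= (v @ axis) / (axis @ axis) * axis
        c = rng.normal(size=3)
        assert project_central_posture(c + v) == pytest.approx(
            project_central_posture(c), abs=1e-10
        )

    def test_coincident_homes_rejected(self):
        with pytest.raises(ValueError):
            project_central_posture(HOME_H1, HOME_H1, HOME_H1)


class TestLoadingsAndVariance:
    def test_pure_q2_component(self, rng):
        X = BASELINE_POSTURE + np.outer(rng.normal(size=20), [0.0, 1.0, 0.0])
        res = pca_synergies(X)
        assert q2_loading(res, 1) == pytest.approx(1.0)

    def test_sign_flip_invariance(self, rng):
        res = pca_synergies(rng.normal(size=(20, 3)))
        flipped = res.loadings.copy()
        flipped[0] = -flipped[0]
        assert abs(flipped[0][1]) == q2_loading(res, 1)

    def test_summed_variance_is_trace_and_pc_sum(self, rng):
        X = rng.normal(size=(27, 3)) * [1.0, 2.0, 0.5]
        res = pca_synergies(X)
        sv = summed_variance(X)
        assert sv == pytest.approx(res.variances.sum(), abs=1e-10)
        # direct per-column variance oracle on a tiny matrix
        toy = np.array([[0.0, 1.0, 2.0], [2.0, 1.0, 0.0], [1.0, 1.0, 1.0]])
        expected = sum(np.var(toy[:, j], ddof=1) for j in range(3))
        assert summed_variance(toy) == pytest.approx(expected)

    def test_identical_rows_have_zero_variance(self):
        assert summed_variance(np.tile([1.0, 2.0, 3.0], (5, 1))) == pytest.approx(0.0)


class TestPerformanceCurve:
    def test_exact_reaches_score_zero_error(self, geometry, rng):
        # postures chosen so endpoints equal targets is impractical; instead
        # targets set equal to each posture's endpoint
        postures = rng.normal(size=(4, 9, 3))
        sess = _session(postures)
        for b in sess.blocks:
            for t in b.test:
                t.target = list(t.endpoint)
        curve = performance_curve(sess, geometry)
        np.testing.assert_allclose(curve["mean_error"], 0.0, atol=1e-12)

    def test_two_target_toy_block_matches_distance_oracle(self, geometry):
        q = [BASELINE_POSTURE, HOME_H1]
        sess = _session([q])
        sess.blocks[0].test[0].target = [0.0, 0.5]
        sess.blocks[0].test[1].target = [0.2, 0.3]
        curve = performance_curve(sess, geometry)
        d0 = np.linalg.norm(forward_kinematics(q[0]) - [0.0, 0.5])
        d1 = np.linalg.norm(forward_kinematics(q[1]) - [0.2, 0.3])
        assert curve["mean_error"].iloc[0] == pytest.approx((d0 + d1) / 2)

    def test_all_missing_block_flagged(self, rng):
        postures = rng.normal(size=(2, 9, 3))
        missing = {(2, j) for j in range(9)}
        curve = performance_curve(_session(postures, missing=missing))
        assert curve["defined"].tolist() == [True, False]
        assert np.isnan(curve["mean_error"].iloc[1])


class TestFractionConservation:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_fractions_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(rng.integers(4, 40), 3))
        res = pca_synergies(X)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(res.variance_fractions) <= 1e-12)


class TestMorphologyVsTask:
    def test_identity_mappings_give_identical_fractions(self, rng):
        postures = rng.normal(size=(6, 9, 3)) + BASELINE_POSTURE
        sessions = [
            _session(postures + 0.1 * k, mapping=(1, 2, 3)) for k in range(3)
        ]
        df = morphology_vs_task_pca(sessions, bin_size=3)
        finger = df[df.space == "finger"].variance_fraction.to_numpy()
        task = df[df.space == "task"].variance_fraction.to_numpy()
        np.testing.assert_allclose(finger, task, atol=1e-10)

    def test_row_bookkeeping(self, rng):
        postures = rng.normal(size=(6, 9, 3))
        sessions = [_session(postures, mapping=(-2, 3, -1)) for _ in range(4)]
        df = morphology_vs_task_pca(sessions, bin_size=3)
        assert set(df.n_rows) == {4 * 27}

    def test_task_consolidation_with_randomized_mappings(self):
        # synthetic population with planted task-space consolidation: task
        # PC1+PC2 rises across windows, finger-space stays comparatively flat
        params = HumanGeneratorParams(seed=21)
        sessions, _ = generate_population(params, n_participants=8)
        df = morphology_vs_task_pca(sessions, bin_size=3)

        def pc12(space, window):
            sub = df[(df.space == space) & (df.window == window) & df.pc.isin([1, 2])]
            return sub.variance_fraction.sum()

        last = df.window.max()
        assert pc12("task", last) > pc12("task", 0)
        assert abs(pc12("finger", last) - pc12("finger", 0)) < 0.10


def test_analyze_store_tables_are_tidy(synthetic_session, geometry):
    tables = analyze_store([synthetic_session], bin_size=3, geometry=geometry)
    assert set(tables) == {
        "variance_fractions", "location", "q2_loading", "summed_variance", "performance",
    }
    assert len(tables["variance_fractions"]) == 8 * 3
    assert len(tables["location"]) == 8
    assert tables["performance"]["block"].tolist() == list(range(1, 25))
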