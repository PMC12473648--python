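"""Unit and property tests for the global motion-parameter solver."""

import numpy as np
import pytest

from fallflow.gloria_core import (
    GENERATOR_NAMES,
    GloriaConfig,
    MotionParameters,
    NormalSystem,
    assemble_normal_system,
    estimate_motion,
    make_generator_basis,
    motion_array,
    motion_sequence,
    solve_motion,
    spatial_gradients,
)
from fallflow.synthetic_scenes import render_sequence, render_texture, warp_frame

from conftest import scene_spec


def _index(name):
    return GENERATOR_NAMES.index(name)


# ----------------------------------------------------------------------
# spatial_gradients
# ----------------------------------------------------------------------
class TestSpatialGradients:
    def test_ramp_gradient(self):
        x = np.tile(np.arange(32, dtype=float), (32, 1))
        g = spatial_gradients(x, x, smooth_sigma=0.0)
        assert np.allclose(g.gx[1:-1, 1:-1], 1.0)
        assert np.allclose(g.gy[1:-1, 1:-1], 0.0)
        assert np.allclose(g.gt, 0.0)

    def test_constant_offset_temporal(self):
        a = np.random.default_rng(0).random((16, 16))
        g = spatial_gradients(a, a + 0.3, smooth_sigma=0.0)
        assert np.allclose(g.gt, 0.3)

    def test_sinusoid_matches_closed_form(self):
        # oracle: d/dx sin(2 pi x / 32) = (2 pi / 32) cos(2 pi x / 32)
        xs = np.arange(64, dtype=float)
        frame = np.tile(np.sin(2 * np.pi * xs / 32.0), (64, 1))
        g = spatial_gradients(frame, frame, smooth_sigma=0.0)
        expected = (2 * np.pi / 32.0) * np.cos(2 * np.pi * xs / 32.0)
        got = g.gx[32, 2:-2, 0]
        want = np.tile(expected, (1,))[2:-2]
        assert np.max(np.abs(got - want)) < 0.01 * np.max(np.abs(want))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="differ"):
            spatial_gradients(np.zeros((16, 16)), np.zeros((16, 17)))


# ----------------------------------------------------------------------
# make_generator_basis
# ----------------------------------------------------------------------
class TestGeneratorBasis:
    def test_generators_vanish_at_origin(self):
        b = make_generator_basis(33, 33)  # odd size: exact center pixel
        for name in ("dilation", "rotation", "shear1", "shear2"):
            u = _index(name)
            assert b.vx[u, 16, 16] == 0.0
            assert b.vy[u, 16, 16] == 0.0

    @pytest.mark.parametrize("origin", ["center", "corner"])
    @pytest.mark.parametrize("scale", ["pixels", "normalized"])
    def test_translation_fields_unit(self, origin, scale):
        b = make_generator_basis(16, 24, origin=origin, scale=scale)
        assert np.all(b.vx[0] == 1.0) and np.all(b.vy[0] == 0.0)
        assert np.all(b.vx[1] == 0.0) and np.all(b.vy[1] == 1.0)

    def test_dilation_translation_orthogonal_on_centered_grid(self):
        # oracle: direct summation of the dot product over the grid
        b = make_generator_basis(32, 32, origin="center")
        dot = np.sum(b.vx[2] * b.vx[0] + b.vy[2] * b.vy[0])
        assert abs(dot) < 1e-10

    def test_fields_linearly_independent(self):
        b = make_generator_basis(16, 16)
        mat = np.concatenate([b.vx.reshape(6, -1), b.vy.reshape(6, -1)], axis=1)
        assert np.linalg.matrix_rank(mat) == 6

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            make_generator_basis(4, 64)


# ----------------------------------------------------------------------
# assemble_normal_system
# ----------------------------------------------------------------------
class TestNormalSystem:
    def test_zero_temporal_derivative_gives_zero_H(self, texture64):
        g = spatial_gradients(texture64, texture64)
        system = assemble_normal_system(g, make_generator_basis(64, 64))
        assert np.all(system.H == 0.0)

    def test_constant_frame_gives_zero_system(self):
        c = np.full((32, 32), 0.5)
        g = spatial_gradients(c, c, smooth_sigma=0.0)
        system = assemble_normal_system(g, make_generator_basis(32, 32))
        assert np.all(system.S == 0.0) and np.all(system.H == 0.0)

    def test_gram_matrix_matches_double_loop(self):
        # oracle: explicit double loop over generator pairs on a 16x16 crop
        tex = render_texture(scene_spec(seed=3, size=16))
        warped = warp_frame(tex, np.array([0.3, -0.2, 0, 0.01, 0, 0]))
        g = spatial_gradients(tex, warped)
        basis = make_generator_basis(16, 16)
        system = assemble_normal_system(g, basis)

        S_brute = np.zeros((6, 6))
        H_brute = np.zeros(6)
        proj = []
        for u in range(6):
            d = (
                basis.vx[u][1:-1, 1:-1, None] * g.gx[1:-1, 1:-1]
                + basis.vy[u][1:-1, 1:-1, None] * g.gy[1:-1, 1:-1]
            )
            proj.append(d)
        for u in range(6):
            H_brute[u] = -np.sum(g.gt[1:-1, 1:-1] * proj[u])
            for v in range(6):
                S_brute[u, v] = np.sum(proj[u] * proj[v])
        assert np.allclose(system.S, S_brute, atol=1e-10)
        assert np.allclose(system.H, H_brute, atol=1e-10)

    def test_S_symmetric_psd(self, texture64):
        warped = warp_frame(texture64, np.array([0.4, 0.1, 0.01, 0, 0.01, 0]))
        g = spatial_gradients(texture64, warped)
        system = assemble_normal_system(g, make_generator_basis(64, 64))
        assert np.array_equal(system.S, system.S.T)
        eig = np.linalg.eigvalsh(system.S)
        assert np.all(eig >= -1e-10 * np.trace(system.S))


# ----------------------------------------------------------------------
# solve_motion
# ----------------------------------------------------------------------
class TestSolveMotion:
    def test_zero_H_gives_zero_solution(self):
        S = np.diag([5.0, 4, 3, 2, 1, 1])
        m = solve_motion(NormalSystem(S=S, H=np.zeros(6)))
        assert np.all(m.a == 0.0)
        assert not m.degenerate_flag

    def test_diagonal_solve(self):
        k = 3.7
        m = solve_motion(NormalSystem(S=k * np.eye(6), H=np.array([k, 0, 0, 0, 0, 0])))
        assert np.allclose(m.a, [1, 0, 0, 0, 0, 0])
        assert m.condition_number == pytest.approx(1.0)

    def test_matches_pseudo_inverse_oracle(self, rng):
        # oracle: independent pinv route on random well-conditioned systems
        for _ in range(10):
            M = rng.standard_normal((40, 6))
            b = rng.standard_normal(40)
            S = M.T @ M
            H = M.T @ b
            system = NormalSystem(S=S, H=H, gt_sq_sum=float(b @ b), n_terms=40)
            m = solve_motion(system)
            a_oracle = np.linalg.pinv(M) @ b
            assert np.max(np.abs(m.a - a_oracle)) < 1e-8

    def test_degenerate_zero_trace(self):
        m = solve_motion(NormalSystem(S=np.zeros((6, 6)), H=np.zeros(6)))
        assert m.degenerate_flag
        assert np.all(m.a == 0.0)
        assert np.isinf(m.condition_number)

    def test_residual_rms_matches_direct_computation(self, rng):
        M = rng.standard_normal((50, 6))
        b = rng.standard_normal(50)
        system = NormalSystem(S=M.T @ M, H=M.T @ b, gt_sq_sum=float(b @ b), n_terms=50)
        m = solve_motion(system)
        direct = np.sqrt(np.mean((-b + M @ m.a) ** 2))
        assert m.residual_rms == pytest.approx(direct, abs=1e-10)

    def test_rejects_asymmetric(self):
        S = np.eye(6)
        S[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            solve_motion(NormalSystem(S=S, H=np.zeros(6)))

    def test_rejects_nan(self):
        S = np.eye(6)
        H = np.zeros(6)
        H[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            solve_motion(NormalSystem(S=S, H=H))


# ----------------------------------------------------------------------
# estimate_motion / motion_sequence
# ----------------------------------------------------------------------
class TestEstimateMotion:
    def test_identical_frames_zero(self, texture64):
        m = estimate_motion(texture64, texture64)
        assert np.allclose(m.a, 0.0, atol=1e-12)

    def test_translation_recovery(self, texture64):
        warped = warp_frame(texture64, np.array([0.5, 0, 0, 0, 0, 0]))
        m = estimate_motion(texture64, warped)
        assert 0.45 <= m.a[0] <= 0.55
        assert np.all(np.abs(m.a[1:]) < 0.05)

    def test_rotation_recovery(self, texture64):
        # 0.01 rad about center; in normalized units A_rot = 0.01 * 32
        a_true = 0.01 * 32.0
        warped = warp_frame(texture64, np.array([0, 0, 0, a_true, 0, 0]))
        m = estimate_motion(texture64, warped)
        assert abs(m.a[3] - a_true) < 0.1 * a_true
        assert np.all(np.abs(m.a[[0, 1]]) < 0.1 * a_true)

    def test_channel_consistency(self, texture64):
        warped = warp_frame(texture64, np.array([0.3, -0.2, 0, 0, 0, 0]))
        m1 = estimate_motion(texture64, warped)
        m3 = estimate_motion(
            np.repeat(texture64, 3, axis=2), np.repeat(warped, 3, axis=2)
        )
        assert np.allclose(m1.a, m3.a, atol=1e-10)

    def test_horizontal_flip_equivariance(self, texture64):
        a = np.array([0.4, 0.3, 0.01, 0.2, 0.15, 0.01])
        warped = warp_frame(texture64, a)
        m = estimate_motion(texture64, warped)
        m_flip = estimate_motion(texture64[:, ::-1], warped[:, ::-1])
        # x -> -x negates tx, rotation and shear1; preserves ty, dil, shear2
        signs = np.array([-1, 1, 1, -1, -1, 1])
        assert np.allclose(m_flip.a, signs * m.a, atol=5e-3)

    def test_linearity_in_amplitude(self, texture64):
        amps = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        recovered = []
        for amp in amps:
            warped = warp_frame(texture64, np.array([amp, 0, 0, 0, 0, 0]))
            recovered.append(estimate_motion(texture64, warped).a[0])
        slope = np.polyfit(amps, recovered, 1)[0]
        assert abs(slope - 1.0) < 0.1

    def test_sequence_length_contract(self):
        spec = scene_spec(schedule=[MotionParameters(a=[0.1, 0, 0, 0, 0, 0])] * 150)
        frames, truth = render_sequence(spec)
        assert len(frames) == 151
        seq = motion_sequence(frames)
        assert len(seq) == 150

    def test_identical_frames_sequence_zero(self, texture64):
        seq = motion_sequence([texture64] * 5)
        assert len(seq) == 4
        for m in seq:
            assert np.allclose(m.a, 0.0, atol=1e-12)

    def test_recovery_correlates_with_truth(self, rng):
        schedule = []
        for _ in range(40):
            a = 0.3 * rng.standard_normal(6) * np.array([1, 1, 0.3, 0.3, 0.3, 0.3])
            schedule.append(MotionParameters(a=a))
        frames, truth = render_sequence(scene_spec(schedule=schedule))
        est = motion_array(motion_sequence(frames))
        truth_arr = np.stack([t.a for t in truth])
        for ch in range(6):
            r = np.corrcoef(est[:, ch], truth_arr[:, ch])[0, 1]
            assert r >= 0.95, f"channel {GENERATOR_NAMES[ch]}: r={r:.3f}"

    def test_shape_drift_names_index(self, texture64):
        frames = [texture64, texture64, texture64[:32]]
        with pytest.raises(ValueError, match="frame 2"):
            motion_sequence(frames)

    def test_too_few_frames(self, texture64):
        with pytest.raises(ValueError):
            motion_sequence([texture64])
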