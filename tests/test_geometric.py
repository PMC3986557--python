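"""Head->eye transform, linear eye model and geometric calibration."""

import numpy as np
import pytest

from gazecal.dataset import SessionDataset
from gazecal.geometry import (
    EyeAngles,
    HeadPose,
    InputSample,
    PupilSample,
    rotation_from_euler,
)
from gazecal.geometric import (
    EyeModelParams,
    GeometricModel,
    HeadEyeParams,
    calibrate_user,
    fit_eye_model,
    geometric_cost,
    head_to_eye,
    predict_geometric,
    predict_geometric_batch,
    pupil_to_angles,
)
from gazecal.evaluate import angular_error_batch
from gazecal.simulate import SimulationConfig, simulate_session


def _head(x=0, y=0, z=0, phi=0, theta=0, psi=0, t=0.0):
    return HeadPose(t=t, h_x=x, h_y=y, h_z=z, h_phi=phi, h_theta=theta, h_psi=psi)


class TestHeadToEye:
    def test_identity_transform(self):
        head = _head(1, 2, 3, 10, -5, 80)
        eye = head_to_eye(head, HeadEyeParams())
        assert np.allclose(eye.position, head.position)
        assert np.allclose(eye.rotation, head.rotation)

    def test_pure_translation(self):
        eye = head_to_eye(_head(), HeadEyeParams(z_T=5.0))
        assert np.allclose(eye.position, [0, 0, 5])

    def test_rotated_offset(self):
        """Yawed head carries the head-frame offset with it: for a 90 deg
        yaw (about up), the forward offset (10,0,0) lands at (0,0,-10)."""
        head = _head(psi=90)
        eye = head_to_eye(head, HeadEyeParams(x_T=10.0))
        expected = head.position + rotation_from_euler(0, 0, 90) @ [10.0, 0, 0]
        assert np.allclose(eye.position, expected)
        assert np.allclose(eye.position, [0, 0, -10], atol=1e-12)


class TestEyeModel:
    def test_unit_slope(self):
        a = pupil_to_angles(PupilSample(0, 10, 5), EyeModelParams(1, 0, 1, 0))
        assert (a.phi, a.theta) == (10.0, 5.0)

    def test_zero_slope_gives_intercept(self):
        a = pupil_to_angles(PupilSample(0, 123, -5), EyeModelParams(0, 2.5, 0, -1.0))
        assert (a.phi, a.theta) == (2.5, -1.0)

    def test_exact_fit_two_points(self):
        pairs = [
            (PupilSample(0, 0.0, 0.0), EyeAngles(1.0, -2.0)),
            (PupilSample(0, 10.0, 5.0), EyeAngles(6.0, 3.0)),
        ]
        p = fit_eye_model(pairs)
        for ps, ang in pairs:
            out = pupil_to_angles(ps, p)
            assert out.phi == pytest.approx(ang.phi, abs=1e-9)
            assert out.theta == pytest.approx(ang.theta, abs=1e-9)

    def test_noiseless_linear_recovery(self, rng):
        px = rng.uniform(-2000, 2000, 50)
        py = rng.uniform(-1500, 1500, 50)
        pairs = [
            (PupilSample(0, x, y), EyeAngles(0.012 * x + 1.5, -0.011 * y + 0.2))
            for x, y in zip(px, py)
        ]
        p = fit_eye_model(pairs)
        assert p.m_phi == pytest.approx(0.012, abs=1e-9)
        assert p.b_phi == pytest.approx(1.5, abs=1e-9)
        assert p.m_theta == pytest.approx(-0.011, abs=1e-9)
        assert p.b_theta == pytest.approx(0.2, abs=1e-9)

    def test_noisy_fit_matches_normal_equations(self, rng):
        x = rng.uniform(-100, 100, 200)
        y = 0.5 * x + 3 + rng.normal(0, 2, 200)
        pairs = [(PupilSample(0, xi, xi), EyeAngles(yi, yi)) for xi, yi in zip(x, y)]
        p = fit_eye_model(pairs)
        # independent closed-form simple-linear-regression oracle
        X = np.column_stack([x, np.ones_like(x)])
        m_ref, b_ref = np.linalg.solve(X.T @ X, X.T @ y)
        assert p.m_phi == pytest.approx(m_ref, rel=1e-9)
        assert p.b_phi == pytest.approx(b_ref, rel=1e-9)

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            fit_eye_model([(PupilSample(0, 1, 1), EyeAngles(0, 0))])

    def test_constant_coordinate_errors(self):
        pairs = [(PupilSample(0, 5.0, float(i)), EyeAngles(0, 0)) for i in range(5)]
        with pytest.raises(ValueError):
            fit_eye_model(pairs)


class TestPredictionAndCost:
    def test_forward_inverse_consistency(self, noiseless_walking_session):
        cfg, ds = noiseless_walking_session
        uv, valid = predict_geometric_batch(cfg.ground_truth, ds)
        assert valid.all()
        assert np.nanmax(np.linalg.norm(uv - ds.targets, axis=1)) < 1e-6

    def test_off_screen_flag(self, screen):
        truth = SimulationConfig(seed=0).ground_truth
        head = _head(z=140, psi=90)
        # enormous pupil displacement -> gaze far off the panel
        sample = InputSample(head=head, pupil=PupilSample(0.0, 30000.0, 0.0))
        p, on = predict_geometric(truth, sample)
        assert not on

    def test_cost_zero_iff_exact(self, noiseless_walking_session):
        cfg, ds = noiseless_walking_session
        assert geometric_cost(cfg.ground_truth, ds.subsample(500)) < 1e-6

    def test_cost_of_uniform_shift_is_shift(self, noiseless_walking_session):
        """Shifting every target by 10 px must give cost exactly 10."""
        cfg, ds = noiseless_walking_session
        sub = ds.subsample(300)
        df = sub.df.copy()
        df["stim_u"] += 8.0
        df["stim_v"] += 6.0
        shifted = SessionDataset(df)
        assert geometric_cost(cfg.ground_truth, shifted) == pytest.approx(10.0, abs=1e-6)

    def test_cost_matches_per_sample_loop(self, noiseless_walking_session):
        cfg, ds = noiseless_walking_session
        sub = ds.subsample(40)
        model = GeometricModel(
            HeadEyeParams(x_T=7.0, y_T=-8.0),
            EyeModelParams(0.011, 0.5, 0.009, -0.2),
            cfg.ground_truth.screen,
        )
        # brute-force re-implementation, one sample at a time
        total = 0.0
        for i in range(len(sub)):
            row = sub.df.iloc[i]
            head = HeadPose(row.t_s, row.h_x, row.h_y, row.h_z,
                            row.h_phi, row.h_theta, row.h_psi)
            p, _on = predict_geometric(
                model, InputSample(head, PupilSample(row.t_s, row.p_x, row.p_y))
            )
            total += np.hypot(p.u - row.stim_u, p.v - row.stim_v)
        assert geometric_cost(model, sub) == pytest.approx(total / len(sub), rel=1e-9)

    def test_cost_empty_dataset_errors(self, noiseless_walking_session):
        cfg, ds = noiseless_walking_session
        with pytest.raises(ValueError):
            geometric_cost(cfg.ground_truth, ds.select(np.zeros(len(ds), bool)))

    def test_por_invariant_to_translation_along_gaze(self, noiseless_walking_session):
        """Moving the head along each sample's gaze direction leaves the
        predicted POR unchanged (pure ray geometry)."""
        cfg, ds = noiseless_walking_session
        sub = ds.subsample(50)
        uv0, _ = predict_geometric_batch(cfg.ground_truth, sub)
        from gazecal.geometric import _eye_poses
        from gazecal.screen import gaze_direction

        e, R_e = _eye_poses(sub.head_positions, sub.head_rotations,
                            cfg.ground_truth.head_eye)
        eye = cfg.ground_truth.eye
        phi = eye.m_phi * sub.pupil[:, 0] + eye.b_phi
        theta = eye.m_theta * sub.pupil[:, 1] + eye.b_theta
        dirs = gaze_direction(R_e, phi, theta)
        df = sub.df.copy()
        df[["h_x", "h_y", "h_z"]] -= 25.0 * dirs
        uv1, _ = predict_geometric_batch(cfg.ground_truth, SessionDataset(df))
        assert np.allclose(uv0, uv1, atol=1e-6)


class TestCalibrateUser:
    def test_empty_dataset_errors(self, noiseless_walking_session):
        cfg, ds = noiseless_walking_session
        with pytest.raises(ValueError):
            calibrate_user(ds.select(np.zeros(len(ds), bool)), cfg.ground_truth.screen)

    def test_noiseless_prediction_recovery(self, noiseless_walking_session):
        """Calibrating on a noiseless walking session recovers the prediction
        function: < 0.1 deg mean combined error on held-out data."""
        cfg, ds = noiseless_walking_session
        calib = ds.phase("dynamic").time_slice(0, 120)
        res = calibrate_user(calib, cfg.ground_truth.screen, subset_size=400)
        model = GeometricModel(res.head_eye, res.eye, cfg.ground_truth.screen)
        valid = ds.phase("dynamic").time_slice(120, 1e9)
        uv, ok = predict_geometric_batch(model, valid)
        assert ok.all()
        _, _, comb = angular_error_batch(
            valid.head_positions, uv, valid.targets, cfg.ground_truth.screen
        )
        assert np.mean(comb) < 0.1

    def test_zero_offset_ground_truth_recovered(self):
        """Data generated with a zero head-eye transform calibrates to a
        model predicting like the identity transform."""
        from gazecal.simulate import default_ground_truth
        import dataclasses

        truth = default_ground_truth()
        truth = dataclasses.replace(truth, head_eye=HeadEyeParams())
        cfg = SimulationConfig(seed=7, mobility="head_free",
                               ground_truth=truth).noiseless()
        ds = simulate_session(cfg, protocol="dynamic").subsample(400)
        res = calibrate_user(ds, truth.screen)
        model = GeometricModel(res.head_eye, res.eye, truth.screen)
        uv, _ = predict_geometric_batch(model, ds)
        # reference: the identity-transform model with the true eye model
        uv_ref, _ = predict_geometric_batch(truth, ds)
        assert np.nanmean(np.linalg.norm(uv - uv_ref, axis=1)) < 1.0
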