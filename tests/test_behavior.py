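"""Head-movement and gaze analyses: angles, velocities, areas, tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import chi2, mannwhitneyu

from palscale.behavior import (
    behavior_ols,
    classify_movement,
    gaze_area,
    mann_whitney_u,
    quaternion_to_tait_bryan,
    angular_velocity,
)
from palscale.observer import HeadTrace, ObserverProfile, simulate_gaze


def _euler_trace(yaw, pitch, roll, rate=90.0) -> HeadTrace:
    n = len(yaw)
    rot = Rotation.from_euler("YXZ", np.column_stack([yaw, pitch, roll]), degrees=True)
    q = rot.as_quat()
    return HeadTrace(
        t=np.arange(n) / rate,
        quaternions=np.column_stack([q[:, 3], q[:, :3]]),
    )


class TestTaitBryan:
    def test_identity_quaternion(self):
        assert np.allclose(quaternion_to_tait_bryan(np.array([1.0, 0, 0, 0])), 0.0)

    def test_pure_yaw_quarter_turn(self):
        rot = Rotation.from_euler("y", 90, degrees=True)
        x, y, z, w = rot.as_quat()
        angles = quaternion_to_tait_bryan(np.array([w, x, y, z]))
        assert np.allclose(angles, [90.0, 0.0, 0.0], atol=1e-9)

    def test_round_trip_against_rotation_matrix_oracle(self):
        rng = np.random.default_rng(0)
        q = rng.standard_normal((1000, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        angles = quaternion_to_tait_bryan(q)
        direct = Rotation.from_quat(
            np.column_stack([q[:, 1], q[:, 2], q[:, 3], q[:, 0]])
        ).as_matrix()
        recomposed = Rotation.from_euler("YXZ", angles, degrees=True).as_matrix()
        assert np.abs(direct - recomposed).max() < 1e-8

    def test_non_unit_quaternion_rejected(self):
        with pytest.raises(ValueError, match="norm"):
            quaternion_to_tait_bryan(np.array([1.0, 1.0, 0.0, 0.0]))


class TestAngularVelocity:
    def test_constant_orientation_zero_velocity(self):
        n = 200
        trace = _euler_trace(np.full(n, 10.0), np.full(n, -5.0), np.zeros(n))
        assert np.allclose(angular_velocity(trace), 0.0, atol=1e-9)

    def test_linear_yaw_ramp(self):
        t = np.arange(300) / 90.0
        trace = _euler_trace(20.0 * t, np.zeros_like(t), np.zeros_like(t))
        v = angular_velocity(trace)
        assert np.abs(v[:, 0]).mean() == pytest.approx(20.0, abs=1e-6)
        assert np.allclose(v[:, 1:], 0.0, atol=1e-6)

    def test_wraparound_produces_no_spike(self):
        # constant-rate yaw crossing the +/-180 degree boundary
        t = np.arange(600) / 90.0
        yaw = 150.0 + 20.0 * t  # crosses 180 at t = 1.5 s
        wrapped = (yaw + 180.0) % 360.0 - 180.0
        trace = _euler_trace(wrapped, np.zeros_like(t), np.zeros_like(t))
        v = angular_velocity(trace)[:, 0]
        assert np.abs(v).max() == pytest.approx(20.0, rel=0.01)

    def test_non_monotone_timestamps_rejected(self):
        trace = _euler_trace(np.zeros(5), np.zeros(5), np.zeros(5))
        with pytest.raises(ValueError):
            HeadTrace(t=trace.t[::-1].copy(), quaternions=trace.quaternions)


class TestClassifyMovement:
    @pytest.mark.parametrize(
        "means,expected",
        [
            ((2.0, 3.0, 1.0), "static"),
            ((2.0, 30.0, 1.0), "dynamic"),
            ((10.0, 10.0, 10.0), "static"),  # boundary is strict
            ((10.0001, 0.0, 0.0), "dynamic"),
        ],
    )
    def test_threshold_rule(self, means, expected):
        assert classify_movement(means) == expected

    def test_monotone_in_velocity(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            v = rng.uniform(0, 20, 3)
            if classify_movement(v) == "dynamic":
                assert classify_movement(v + rng.uniform(0, 10, 3)) == "dynamic"


class TestGazeArea:
    def test_point_mass_matches_smoothed_gaussian_closed_form(self):
        pts = np.tile([[0.0, 0.0]], (50, 1))
        area = gaze_area(pts, bandwidth=2.0, mass=0.95)
        analytic = 100 * np.pi * chi2.ppf(0.95, 2) * np.deg2rad(2.0) ** 2 / (2 * np.pi)
        assert area == pytest.approx(analytic, rel=0.15)

    def test_gaussian_cloud_matches_closed_form(self):
        profile = ObserverProfile(gaze_center=(0.0, -10.0), gaze_spread=5.0, seed=9)
        gaze = simulate_gaze(profile, n=10_000)
        area = gaze_area(gaze, bandwidth=2.0, mass=0.95)
        sigma_eff_sq = 5.0**2 + 2.0**2
        analytic = (
            100 * np.pi * chi2.ppf(0.95, 2) * sigma_eff_sq * np.deg2rad(1.0) ** 2 / (2 * np.pi)
        )
        assert area == pytest.approx(analytic, rel=0.15)

    def test_mass_monotonicity(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 8, size=(500, 2))
        assert gaze_area(pts, mass=0.5) < gaze_area(pts, mass=0.95)

    def test_rotation_symmetry_in_longitude(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 5, size=(2000, 2))
        base = gaze_area(pts)
        shifted = pts + np.array([90.0, 0.0])
        # pure longitude shift at the equator: same solid angle
        assert gaze_area(shifted) == pytest.approx(base, rel=0.02)

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            gaze_area(np.zeros((5, 2)), mass=1.0)


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups(self):
        _, p = mann_whitney_u([1, 2], [1, 2])
        assert p == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        a, b = [1.0, 5.0, 3.0, 7.0], [2.0, 8.0, 6.0]
        u_ab, p_ab = mann_whitney_u(a, b)
        u_ba, p_ba = mann_whitney_u(b, a)
        assert p_ab == pytest.approx(p_ba)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))

    def test_matches_scipy_exact_oracle_without_ties(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0.5, 1, 6)
            u, p = mann_whitney_u(a, b)
            ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == pytest.approx(float(ref.statistic))
            assert p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def _ols_table(rng, n_subjects=13, sph_effect=0.0, noise_sd=1.0):
    sph = np.array([-5, -2.5, 0, 2.5, 5.0])
    add = np.array([1.0, 3.0])
    rows = []
    for s in range(n_subjects):
        dynamic = "dynamic" if s < 7 else "static"
        area = rng.uniform(1, 10)
        for sp in sph:
            for ad in add:
                rows.append(
                    {
                        "value": sph_effect * sp + rng.normal(0, noise_sd),
                        "sph": sp,
                        "add": ad,
                        "movement_class": dynamic,
                        "gaze_area": area,
                    }
                )
    return pd.DataFrame(rows)


class TestBehaviorOls:
    def test_recovers_sph_effect(self):
        rng = np.random.default_rng(1)
        table = _ols_table(rng, n_subjects=40, sph_effect=0.1, noise_sd=0.01)
        out = behavior_ols(table)
        sph_row = out[out["term"] == "sph"].iloc[0]
        assert sph_row["estimate"] == pytest.approx(0.1, abs=0.01)
        assert sph_row["p"] < 1e-6

    def test_full_factorial_term_count(self):
        rng = np.random.default_rng(2)
        out = behavior_ols(_ols_table(rng))
        assert len(out) == 16  # intercept + 4 + 6 + 4 + 1

    def test_collinear_column_rejected_by_name(self):
        rng = np.random.default_rng(3)
        table = _ols_table(rng)
        table["gaze_area"] = table["add"]  # duplicate a predictor exactly
        with pytest.raises(ValueError, match="collinear"):
            behavior_ols(table)
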