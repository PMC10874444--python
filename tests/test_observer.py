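"""Synthetic observers: ground-truth scale, decisions, motion, gaze."""

import numpy as np
import pytest
from scipy.special import expit

from palscale.design import build_trial_list, default_stimulus_set
from palscale.observer import (
    ObserverProfile,
    ScaleParams,
    answer_triplet,
    materialize_scale,
    simulate_gaze,
    simulate_head_trace,
    simulate_responses,
)
from palscale.stimuli import LensSpec, REFERENCE_LENS


class TestMaterializeScale:
    def test_flat_degenerate_params(self):
        params = ScaleParams(a1=0, b1=0, a3=0, b3=0, c=1.6)
        scale = materialize_scale(params, (REFERENCE_LENS, LensSpec(2.5, 1), LensSpec(5, 3)))
        assert np.all(scale.values == 0.0)

    def test_sph_zero_gives_a_plus_b(self):
        params = ScaleParams()
        scale = materialize_scale(params, (LensSpec(0, 1), LensSpec(0, 3)))
        assert scale.values[0] == pytest.approx(params.a1 + params.b1)
        assert scale.values[1] == pytest.approx(params.a3 + params.b3)

    def test_add_compensation_at_negative_sph(self):
        # higher addition power pulls strongly negative-sph lenses toward 0
        scale = materialize_scale(ScaleParams(), (LensSpec(-5, 1), LensSpec(-5, 3)))
        assert abs(scale.values[1]) < abs(scale.values[0])

    def test_reference_maps_to_zero_and_values_unique(self):
        stimuli = default_stimulus_set()
        scale = materialize_scale(ScaleParams(), tuple(stimuli))
        assert scale.values[0] == 0.0
        assert np.unique(scale.values).size == len(stimuli)

    def test_unmapped_add_rejected(self):
        with pytest.raises(ValueError, match="add"):
            materialize_scale(ScaleParams(), (LensSpec(2.5, 2.0),))


class TestAnswerTriplet:
    @pytest.fixture(scope="class")
    def setup(self):
        stimuli = default_stimulus_set()
        tl = build_trial_list(stimuli, catch_fraction=0.2, seed=3)
        scale = materialize_scale(ScaleParams(), tl.extended_lenses)
        return tl, scale

    def test_noiseless_argmin(self, setup):
        tl, scale = setup
        profile = ObserverProfile(sigma=0.0, lapse=0.0, seed=0)
        rng = np.random.default_rng(0)
        for trial in tl.core_trials()[:50]:
            d1 = abs(scale.value_of(trial.choice1) - scale.value_of(trial.anchor))
            d2 = abs(scale.value_of(trial.choice2) - scale.value_of(trial.anchor))
            resp = answer_triplet(trial, scale, profile, rng)
            assert resp.answer == (1 if d1 < d2 else 2)

    def test_logistic_choice_rate_matches_closed_form(self, setup):
        tl, scale = setup
        # construct a trial with known distance gap d2 - d1 = 0.1
        trial = next(
            t
            for t in tl.core_trials()
            if abs(
                abs(scale.value_of(t.choice2) - scale.value_of(t.anchor))
                - abs(scale.value_of(t.choice1) - scale.value_of(t.anchor))
            )
            > 1e-6
        )
        d1 = abs(scale.value_of(trial.choice1) - scale.value_of(trial.anchor))
        d2 = abs(scale.value_of(trial.choice2) - scale.value_of(trial.anchor))
        sigma = 0.1
        expected = float(expit((d2 - d1) / sigma))
        rng = np.random.default_rng(123)
        profile = ObserverProfile(sigma=sigma, lapse=0.0, seed=0)
        n = 100_000
        hits = sum(
            answer_triplet(trial, scale, profile, rng).answer == 1 for _ in range(n)
        )
        assert hits / n == pytest.approx(expected, abs=0.01)

    def test_lapse_shrinks_choice_probability_toward_half(self, setup):
        tl, scale = setup
        trial = tl.core_trials()[0]
        rng = np.random.default_rng(9)
        base = ObserverProfile(sigma=0.05, lapse=0.0, seed=0)
        lapsing = ObserverProfile(sigma=0.05, lapse=0.4, seed=0)
        n = 20_000
        p0 = np.mean([answer_triplet(trial, scale, base, rng).answer == 1 for _ in range(n)])
        p1 = np.mean([answer_triplet(trial, scale, lapsing, rng).answer == 1 for _ in range(n)])
        assert abs(p1 - 0.5) < abs(p0 - 0.5)

    def test_noiseless_observer_answers_all_catch_trials_correctly(self, setup):
        tl, scale = setup
        profile = ObserverProfile(sigma=0.0, lapse=0.0, seed=11)
        catch_index = len(tl.stimuli)
        for resp in simulate_responses(tl, scale, profile):
            if resp.trial.is_catch:
                assert resp.winner != catch_index

    def test_noiseless_observer_mirrors_flipped_pairs(self, setup):
        tl, scale = setup
        profile = ObserverProfile(sigma=0.0, lapse=0.0, seed=2)
        responses = simulate_responses(tl, scale, profile)
        by_pair: dict[int, list] = {}
        for r in responses:
            if not r.trial.is_catch:
                by_pair.setdefault(r.trial.pair_id, []).append(r)
        for a, b in by_pair.values():
            assert a.winner == b.winner  # same stimulus wins on both presentations

    def test_determinism_under_fixed_seed(self, setup):
        tl, scale = setup
        profile = ObserverProfile(sigma=0.2, lapse=0.1, seed=77)
        r1 = [r.answer for r in simulate_responses(tl, scale, profile)]
        r2 = [r.answer for r in simulate_responses(tl, scale, profile)]
        assert r1 == r2


class TestHeadTrace:
    def test_sampling_contract(self):
        trace = simulate_head_trace(ObserverProfile(seed=1), duration=10.0, rate=90.0)
        assert len(trace) == 900
        assert np.all(np.diff(trace.t) > 0)
        assert np.allclose(np.linalg.norm(trace.quaternions, axis=1), 1.0, atol=1e-9)

    def test_dynamic_pitch_mean_velocity_is_4af(self):
        profile = ObserverProfile(
            strategy="dynamic-pitch", head_amplitude=15.0, head_frequency=0.5, seed=3
        )
        from palscale.behavior import angular_velocity

        trace = simulate_head_trace(profile, duration=20.0, rate=90.0)
        mean_pitch = np.abs(angular_velocity(trace)[:, 1]).mean()
        assert mean_pitch == pytest.approx(4 * 15.0 * 0.5, rel=0.02)

    def test_static_profile_stays_below_threshold(self):
        from palscale.behavior import angular_velocity

        for seed in (0, 1, 2):
            trace = simulate_head_trace(
                ObserverProfile(strategy="static", seed=seed), duration=20.0, rate=90.0
            )
            v = np.abs(angular_velocity(trace)).mean(axis=0)
            assert np.all(v < 10.0)

    def test_determinism(self):
        p = ObserverProfile(strategy="dynamic-yaw", seed=5)
        a = simulate_head_trace(p, duration=5, rate=90)
        b = simulate_head_trace(p, duration=5, rate=90)
        assert np.array_equal(a.quaternions, b.quaternions)


class TestGaze:
    def test_degenerate_spread_collapses_to_center(self):
        profile = ObserverProfile(gaze_center=(5.0, -10.0), gaze_spread=1e-6, seed=2)
        lon_lat = simulate_gaze(profile, n=100).lon_lat()
        assert np.allclose(lon_lat, [5.0, -10.0], atol=1e-4)

    def test_sample_mean_matches_center(self):
        profile = ObserverProfile(gaze_center=(0.0, -10.0), gaze_spread=5.0, seed=9)
        lon_lat = simulate_gaze(profile, n=10_000).lon_lat()
        assert lon_lat[:, 1].mean() == pytest.approx(-10.0, abs=0.2)
        assert lon_lat[:, 0].mean() == pytest.approx(0.0, abs=0.2)

    def test_eyes_average_to_binocular_direction(self):
        profile = ObserverProfile(gaze_center=(0.0, 0.0), gaze_spread=3.0, seed=4)
        gaze = simulate_gaze(profile, n=500)
        mean = 0.5 * (gaze.left + gaze.right)
        mean /= np.linalg.norm(mean, axis=1, keepdims=True)
        assert np.allclose(mean, gaze.binocular)
        assert np.allclose(np.linalg.norm(gaze.left, axis=1), 1.0)
        assert np.allclose(np.linalg.norm(gaze.right, axis=1), 1.0)
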