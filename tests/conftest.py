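"""Shared fixtures: canonical designs and simulated subjects."""

from __future__ import annotations

import numpy as np
import pytest

from palscale.design import build_trial_list, default_stimulus_set
from palscale.observer import (
    ObserverProfile,
    ScaleParams,
    materialize_scale,
    simulate_responses,
)


@pytest.fixture(scope="session")
def stimuli():
    return default_stimulus_set()


@pytest.fixture(scope="session")
def trial_list(stimuli):
    return build_trial_list(stimuli, catch_fraction=0.2, seed=7)


@pytest.fixture(scope="session")
def ground_truth(trial_list):
    return materialize_scale(ScaleParams(), trial_list.extended_lenses)


@pytest.fixture(scope="session")
def noiseless_responses(trial_list, ground_truth):
    profile = ObserverProfile(sigma=0.0, lapse=0.0, seed=5)
    return simulate_responses(trial_list, ground_truth, profile)


@pytest.fixture(scope="session")
def noiseless_core(noiseless_responses):
    return [r for r in noiseless_responses if not r.trial.is_catch]


@pytest.fixture(scope="session")
def noisy_core(trial_list, ground_truth):
    profile = ObserverProfile(sigma=0.05, lapse=0.0, seed=13)
    responses = simulate_responses(trial_list, ground_truth, profile)
    return [r for r in responses if not r.trial.is_catch]


def synthetic_cohort_scales(
    n_subjects: int = 13, noise_sd: float = 0.05, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject raw scales = affine+sign copies of the exponential ground
    truth plus Gaussian noise; returns (scales, truth_values)."""
    stimuli = default_stimulus_set()
    truth = materialize_scale(ScaleParams(), tuple(stimuli)).values
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_subjects):
        a = rng.uniform(0.5, 2.0) * (1 if rng.random() < 0.5 else -1)
        b = rng.normal(0, 1)
        rows.append(a * truth + b + rng.normal(0, noise_sd, truth.size))
    return np.vstack(rows), truth
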