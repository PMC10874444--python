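"""Synthetic observers: triplet decisions, head motion, and gaze clouds.

The simulator stands in for human subjects so the whole analysis chain can
be exercised without experimental data.  Three streams are generated:

* **Triplet responses.**  Each observer carries a 1-D ground-truth
  perceptual scale ``s(lens)``.  Given a trial (choice 1, anchor, choice 2)
  the observer compares the scale distances ``d1 = |s(c1) - s(a)|`` and
  ``d2 = |s(c2) - s(a)|`` and answers choice 1 with probability
  ``lapse/2 + (1 - lapse) * logistic((d2 - d1) / sigma)``.  With
  ``sigma = 0`` the decision is a deterministic argmin (exact ties broken by
  a fair seeded coin).
* **Head traces.**  Dynamic observers oscillate one rotation component
  (pitch for nodders, yaw for shakers) sinusoidally; all remaining
  components carry temporally smooth small-amplitude jitter.  Static
  observers produce jitter only.  Traces are emitted as unit quaternions at
  a fixed sampling rate.
* **Gaze clouds.**  Binocular gaze directions with longitude/latitude
  distributed as independent Gaussians about an observer-specific center,
  decomposed into per-eye unit vectors with a small symmetric vergence.

The ground-truth scale follows the exponential law ``s = a + b * c**sph``
with separate offset/slope per addition power, the reference fixed at 0.
Default parameters produce the qualitative regime of interest: negative
scale values for negative ``sph``, partial compensation by ``add`` at
negative ``sph``, and steeper growth for positive ``sph``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.transform import Rotation
from scipy.special import expit

from .design import TrialList, TripletTrial
from .stimuli import LensSpec

__all__ = [
    "ScaleParams",
    "GroundTruthScale",
    "ObserverProfile",
    "TripletResponse",
    "HeadTrace",
    "GazeSamples",
    "materialize_scale",
    "answer_triplet",
    "simulate_responses",
    "simulate_head_trace",
    "simulate_gaze",
    "default_cohort_profiles",
]

MovementStrategy = Literal["dynamic-pitch", "dynamic-yaw", "static"]


@dataclass(frozen=True)
class ScaleParams:
    """Parameters of the exponential ground-truth scale ``a + b * c**sph``.

    ``(a1, b1)`` apply to lenses with add = 1, ``(a3, b3)`` to add = 3; the
    base ``c`` is shared, matching the empirical pattern that addition power
    shifts offset and slope but barely the base.

    The default offsets place the sph = 0 lenses slightly above the
    reference (s(0, add=1) = 0.02, s(0, add=3) = 0.04): perceived distortion
    increases monotonically with addition power near sph = 0, and no two
    stimuli share an exact scale value — coincident values would make a
    noiseless observer answer some triplets by coin flip.
    """

    a1: float = -0.33
    b1: float = 0.35
    a3: float = -0.21
    b3: float = 0.25
    c: float = 1.6

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError(f"base c must be positive, got {self.c}")


@dataclass(frozen=True)
class GroundTruthScale:
    """Materialized per-stimulus scale values for a lens list."""

    lenses: tuple[LensSpec, ...]
    values: np.ndarray
    params: ScaleParams

    def __post_init__(self) -> None:
        if len(self.lenses) != self.values.shape[0]:
            raise ValueError("one value per lens required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scale values must be finite")

    def value_of(self, index: int) -> float:
        return float(self.values[index])


def materialize_scale(
    params: ScaleParams, lenses: Sequence[LensSpec]
) -> GroundTruthScale:
    """Evaluate the exponential ground truth on a lens list.

    The reference maps to exactly 0; lenses with add = 1 or add = 3 use
    their group's ``(a, b)``.  Any other non-reference lens is unmapped.
    """
    values = np.empty(len(lenses))
    for i, lens in enumerate(lenses):
        if lens.is_reference:
            values[i] = 0.0
        elif lens.add == 1.0:
            values[i] = params.a1 + params.b1 * params.c**lens.sph
        elif lens.add == 3.0:
            values[i] = params.a3 + params.b3 * params.c**lens.sph
        else:
            raise ValueError(
                f"no scale parameters for lens {lens} (add must be 1 or 3)"
            )
    return GroundTruthScale(tuple(lenses), values, params)


@dataclass(frozen=True)
class ObserverProfile:
    """Behavioral parameters of one synthetic observer.

    ``sigma`` is the decision noise in scale units, ``lapse`` the rate of
    stimulus-independent guesses.  ``strategy`` selects the head-movement
    style; ``head_amplitude`` (deg) and ``head_frequency`` (Hz) shape the
    dominant oscillation, ``jitter_sd`` (deg) the residual components.
    Gaze is centered at ``gaze_center`` (lon, lat in deg) with isotropic
    spread ``gaze_spread`` (deg).
    """

    sigma: float = 0.05
    lapse: float = 0.0
    strategy: MovementStrategy = "dynamic-pitch"
    head_amplitude: float = 15.0
    head_frequency: float = 0.5
    jitter_sd: float = 0.5
    gaze_center: tuple[float, float] = (0.0, -5.0)
    gaze_spread: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("decision noise sigma must be non-negative")
        if not (0 <= self.lapse < 0.5):
            raise ValueError("lapse rate must lie in [0, 0.5)")
        if self.gaze_spread <= 0:
            raise ValueError("gaze spread must be positive")


@dataclass(frozen=True)
class TripletResponse:
    """Binary answer to one triplet trial: 1 = choice 1, 2 = choice 2."""

    trial: TripletTrial
    answer: int
    n_repeats: int = 1

    def __post_init__(self) -> None:
        if self.answer not in (1, 2):
            raise ValueError(f"answer must be 1 or 2, got {self.answer}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")

    @property
    def winner(self) -> int:
        """Extended stimulus index of the choice judged more similar to the anchor."""
        return self.trial.choice1 if self.answer == 1 else self.trial.choice2

    @property
    def loser(self) -> int:
        return self.trial.choice2 if self.answer == 1 else self.trial.choice1


def answer_triplet(
    trial: TripletTrial,
    scale: GroundTruthScale,
    profile: ObserverProfile,
    rng: np.random.Generator | None = None,
) -> TripletResponse:
    """Draw one observer answer to a triplet trial."""
    rng = rng if rng is not None else np.random.default_rng(profile.seed)
    d1 = abs(scale.value_of(trial.choice1) - scale.value_of(trial.anchor))
    d2 = abs(scale.value_of(trial.choice2) - scale.value_of(trial.anchor))
    if profile.sigma == 0:
        p_core = 0.5 if d1 == d2 else (1.0 if d1 < d2 else 0.0)
    else:
        p_core = float(expit((d2 - d1) / profile.sigma))
    p1 = profile.lapse / 2.0 + (1.0 - profile.lapse) * p_core
    answer = 1 if rng.random() < p1 else 2
    return TripletResponse(trial, answer)


def simulate_responses(
    trial_list: TrialList,
    scale: GroundTruthScale,
    profile: ObserverProfile,
) -> list[TripletResponse]:
    """Answer every trial in a list with one seeded RNG stream."""
    rng = np.random.default_rng(profile.seed)
    return [answer_triplet(t, scale, profile, rng) for t in trial_list.trials]


@dataclass(frozen=True)
class HeadTrace:
    """Head-orientation time series: seconds and scalar-first unit quaternions."""

    t: np.ndarray
    quaternions: np.ndarray  # (n, 4) as (w, x, y, z)

    def __post_init__(self) -> None:
        if self.t.ndim != 1 or self.quaternions.shape != (self.t.size, 4):
            raise ValueError("need matching (n,) timestamps and (n, 4) quaternions")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        norms = np.linalg.norm(self.quaternions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("quaternions must be unit norm")

    def __len__(self) -> int:
        return self.t.size


def _smooth_jitter(rng: np.random.Generator, n: int, rate: float, sd: float) -> np.ndarray:
    """Temporally smooth Gaussian jitter (deg) with the requested marginal sd.

    White noise low-passed with a 0.15 s Gaussian kernel, then rescaled;
    the smoothing bounds the angular velocity well below the 10 deg/s
    dynamic/static threshold for sub-degree amplitudes.
    """
    if sd == 0:
        return np.zeros(n)
    noise = rng.standard_normal(n)
    smoothed = gaussian_filter1d(noise, sigma=0.15 * rate, mode="reflect")
    s = smoothed.std()
    return smoothed * (sd / s) if s > 0 else smoothed


def simulate_head_trace(
    profile: ObserverProfile, duration: float = 10.0, rate: float = 90.0
) -> HeadTrace:
    """Simulate a head-orientation trace for one trial or session segment.

    Dynamic observers produce ``A * sin(2*pi*f*t)`` on their dominant
    component (mean absolute angular velocity ``4*A*f``); every other
    component carries smooth jitter.  Static observers produce jitter only.
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    rng = np.random.default_rng(profile.seed)

    yaw = _smooth_jitter(rng, n, rate, profile.jitter_sd)
    pitch = _smooth_jitter(rng, n, rate, profile.jitter_sd)
    roll = _smooth_jitter(rng, n, rate, profile.jitter_sd)
    osc = profile.head_amplitude * np.sin(2 * np.pi * profile.head_frequency * t)
    if profile.strategy == "dynamic-pitch":
        pitch = osc
    elif profile.strategy == "dynamic-yaw":
        yaw = osc
    elif profile.strategy != "static":
        raise ValueError(f"unknown movement strategy {profile.strategy!r}")

    rot = Rotation.from_euler("YXZ", np.column_stack([yaw, pitch, roll]), degrees=True)
    q_xyzw = rot.as_quat()
    quats = np.column_stack([q_xyzw[:, 3], q_xyzw[:, :3]])
    return HeadTrace(t=t, quaternions=quats)


@dataclass(frozen=True)
class GazeSamples:
    """Binocular gaze samples in head-relative coordinates.

    ``left``/``right`` are per-eye unit direction vectors (n, 3) in a
    right-handed frame with y up and z backward (straight ahead is -z).
    The binocular direction is the normalized mean of the two eyes.
    """

    t: np.ndarray
    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        n = self.t.size
        if self.left.shape != (n, 3) or self.right.shape != (n, 3):
            raise ValueError("per-eye vectors must be (n, 3)")

    def __len__(self) -> int:
        return self.t.size

    @property
    def binocular(self) -> np.ndarray:
        mean = 0.5 * (self.left + self.right)
        return mean / np.linalg.norm(mean, axis=1, keepdims=True)

    def lon_lat(self) -> np.ndarray:
        """Binocular directions as (lon, lat) in degrees."""
        return direction_to_lon_lat(self.binocular)


def lon_lat_to_direction(lon_lat: np.ndarray) -> np.ndarray:
    """Unit direction vectors from (lon, lat) degrees; straight ahead is -z."""
    ll = np.deg2rad(np.atleast_2d(lon_lat))
    lon, lat = ll[:, 0], ll[:, 1]
    return np.column_stack(
        [np.cos(lat) * np.sin(lon), np.sin(lat), -np.cos(lat) * np.cos(lon)]
    )


def direction_to_lon_lat(vectors: np.ndarray) -> np.ndarray:
    """Inverse of :func:`lon_lat_to_direction` for unit vectors."""
    v = np.atleast_2d(vectors)
    lat = np.arcsin(np.clip(v[:, 1], -1.0, 1.0))
    lon = np.arctan2(v[:, 0], -v[:, 2])
    return np.rad2deg(np.column_stack([lon, lat]))


def simulate_gaze(
    profile: ObserverProfile,
    n: int,
    rate: float = 120.0,
    vergence_half_angle: float = 1.5,
) -> GazeSamples:
    """Draw ``n`` binocular gaze samples.

    Binocular (lon, lat) are independent Gaussians centered at the profile's
    gaze center with sd ``gaze_spread``.  Each eye's vector is the binocular
    direction rotated by +/- the vergence half-angle about the sample's
    local vertical axis; rotating about an axis orthogonal to the direction
    makes the eyes' mean exactly proportional to the binocular direction.
    """
    if n <= 0:
        raise ValueError("need a positive number of gaze samples")
    rng = np.random.default_rng(profile.seed + 1)
    lon = rng.normal(profile.gaze_center[0], profile.gaze_spread, size=n)
    lat = rng.normal(profile.gaze_center[1], profile.gaze_spread, size=n)
    bino = lon_lat_to_direction(np.column_stack([lon, lat]))
    up = np.array([0.0, 1.0, 0.0])
    axis = up[None, :] - (bino @ up)[:, None] * bino  # local vertical, perp to gaze
    axis /= np.linalg.norm(axis, axis=1, keepdims=True)
    theta = np.deg2rad(vergence_half_angle)
    swing = np.cross(axis, bino)  # unit, horizontal, perp to gaze
    left = np.cos(theta) * bino + np.sin(theta) * swing
    right = np.cos(theta) * bino - np.sin(theta) * swing
    t = np.arange(n) / rate
    return GazeSamples(t=t, left=left, right=right)


def default_cohort_profiles(
    n_subjects: int = 13,
    sigma: float = 0.05,
    lapse: float = 0.0,
    seed: int = 0,
) -> list[ObserverProfile]:
    """Profiles for a synthetic cohort mirroring the studied population:
    7 dynamic observers (mostly nodders, some yaw) and 6 static ones, with
    individual gaze centers and spreads.  Strategies are interleaved so
    small cohorts still mix movement classes."""
    rng = np.random.default_rng(seed)
    base: list[MovementStrategy] = [
        "dynamic-pitch", "static", "dynamic-pitch", "static", "dynamic-yaw",
        "static", "dynamic-pitch", "static", "dynamic-pitch", "static",
        "dynamic-yaw", "static", "dynamic-pitch",
    ]
    strategies = [base[i % 13] for i in range(n_subjects)]
    profiles = []
    for i in range(n_subjects):
        profiles.append(
            ObserverProfile(
                sigma=sigma,
                lapse=lapse,
                strategy=strategies[i],
                head_amplitude=float(rng.uniform(12.0, 18.0)),
                head_frequency=float(rng.uniform(0.4, 0.6)),
                gaze_center=(float(rng.normal(0, 2)), float(rng.normal(-5, 4))),
                gaze_spread=float(rng.uniform(3.0, 9.0)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return profiles
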