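"""Head-movement and gaze analyses.

Head orientation quaternions are decomposed into Tait-Bryan angles with
intrinsic order y-x-z — yaw about the vertical axis first, then pitch about
the interaural axis, then roll — in a right-handed frame with y up and z
backward.  Per-component angular velocities (after unwrapping 360-degree
jumps) summarize movement; an observer whose mean absolute velocity on any
component strictly exceeds a threshold (default 10 deg/s) counts as a
dynamic observer, otherwise static.

Gaze behavior is summarized by the solid angle of the visual field covered:
a fixed-bandwidth Gaussian kernel density estimate of the binocular gaze
(lon, lat) distribution is evaluated on a regular grid, the smallest
superlevel set holding the requested probability mass (default 95%) is
found, and its solid angle — cos(latitude)-weighted — is reported as a
percentage of the half-sphere (2*pi steradian).

Group comparisons use the Mann-Whitney U rank test (exact by enumeration
for small samples, normal approximation with tie correction otherwise), and
the influence of behavior on the perceptual scale is probed with an OLS
model of scale value on Sph, Add, movement group, gaze area, and all their
interactions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation
from scipy.stats import mannwhitneyu, rankdata

from .observer import GazeSamples, HeadTrace

__all__ = [
    "BehaviorSummary",
    "quaternion_to_tait_bryan",
    "trace_to_angles",
    "angular_velocity",
    "mean_abs_velocity",
    "classify_movement",
    "gaze_area",
    "mann_whitney_u",
    "behavior_ols",
]

MOVEMENT_THRESHOLD = 10.0  # deg/s


@dataclass(frozen=True)
class BehaviorSummary:
    """Per-subject behavioral aggregates."""

    mean_velocity: tuple[float, float, float]  # yaw, pitch, roll (deg/s)
    movement_class: str  # "dynamic" | "static"
    gaze_area_pct: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.mean_velocity):
            raise ValueError("mean absolute velocities cannot be negative")
        if not (0.0 <= self.gaze_area_pct <= 100.0):
            raise ValueError("gaze area is a percentage of the half-sphere")


def quaternion_to_tait_bryan(q: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Decompose unit quaternions (w, x, y, z) into (yaw, pitch, roll) degrees.

    Intrinsic y-x-z order; at gimbal lock (|pitch| -> 90 deg) the roll is
    assigned 0 and the yaw absorbs the remaining rotation.
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if q.shape[-1] != 4:
        raise ValueError("quaternions must have 4 components (w, x, y, z)")
    norms = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(norms - 1.0) > tol):
        raise ValueError("quaternion norm deviates from 1 beyond tolerance")
    rot = Rotation.from_quat(np.column_stack([q[:, 1], q[:, 2], q[:, 3], q[:, 0]]))
    import warnings as _warnings

    with _warnings.catch_warnings():
        # scipy warns at gimbal lock; its convention (third angle = 0)
        # is exactly the one adopted here
        _warnings.filterwarnings("ignore", message=".*[Gg]imbal.*")
        angles = rot.as_euler("YXZ", degrees=True)
    return angles if np.asarray(q).ndim == 2 else angles[0]


def trace_to_angles(trace: HeadTrace) -> np.ndarray:
    """(n, 3) yaw/pitch/roll in degrees for every sample of a head trace."""
    return quaternion_to_tait_bryan(trace.quaternions)


def angular_velocity(trace: HeadTrace) -> np.ndarray:
    """Per-component angular velocity (deg/s), shape (n, 3).

    Angles are unwrapped (period 360 degrees) before differencing so a
    crossing of the +/-180 boundary does not produce a spurious spike;
    derivatives use central differences in the interior and one-sided
    differences at the ends.
    """
    if len(trace) < 2:
        raise ValueError("need at least 2 samples to differentiate")
    angles = trace_to_angles(trace)
    unwrapped = np.unwrap(angles, axis=0, period=360.0)
    return np.gradient(unwrapped, trace.t, axis=0)


def mean_abs_velocity(trace: HeadTrace) -> tuple[float, float, float]:
    """Mean absolute yaw/pitch/roll velocity of a trace (deg/s)."""
    v = np.abs(angular_velocity(trace)).mean(axis=0)
    return float(v[0]), float(v[1]), float(v[2])


def classify_movement(
    mean_velocity: tuple[float, float, float] | np.ndarray,
    threshold: float = MOVEMENT_THRESHOLD,
) -> str:
    """"dynamic" iff any component's mean |velocity| strictly exceeds the
    threshold; values exactly at the threshold count as static."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return "dynamic" if np.any(np.asarray(mean_velocity) > threshold) else "static"


def gaze_area(
    samples: GazeSamples | np.ndarray,
    bandwidth: float = 2.0,
    mass: float = 0.95,
    grid_spacing: float = 0.5,
) -> float:
    """Solid angle covered by gaze, as % of the half-sphere.

    A Gaussian KDE with fixed isotropic ``bandwidth`` (degrees) on the
    binocular (lon, lat) samples is evaluated on a regular grid; the
    smallest density threshold whose superlevel set holds at least ``mass``
    of the KDE's integral defines the covered region, whose solid angle is
    integrated with cos(lat) weighting and reported relative to 2*pi sr.

    The KDE is computed by binning the samples at ``grid_spacing`` and
    convolving with the Gaussian kernel, which is exact up to the bin width
    (well below the bandwidth at the defaults).
    """
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must lie strictly between 0 and 1")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid_spacing <= 0:
        raise ValueError("grid spacing must be positive")
    lon_lat = samples.lon_lat() if isinstance(samples, GazeSamples) else np.atleast_2d(samples)
    if lon_lat.shape[0] < 2:
        raise ValueError("need at least 2 gaze samples")
    lon, lat = lon_lat[:, 0], lon_lat[:, 1]

    pad = 6.0 * bandwidth
    lon_edges = np.arange(lon.min() - pad, lon.max() + pad + grid_spacing, grid_spacing)
    lat_edges = np.arange(lat.min() - pad, lat.max() + pad + grid_spacing, grid_spacing)
    counts, _, _ = np.histogram2d(lon, lat, bins=[lon_edges, lat_edges])
    density = gaussian_filter(counts, sigma=bandwidth / grid_spacing, mode="constant")

    lat_centers = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    cell_sr = np.broadcast_to(
        np.cos(np.deg2rad(lat_centers))[None, :] * np.deg2rad(grid_spacing) ** 2,
        density.shape,
    )

    # smallest superlevel set with >= mass of the planar KDE integral
    flat = density.ravel()
    order = np.argsort(flat)[::-1]
    cum = np.cumsum(flat[order])
    k = int(np.searchsorted(cum, mass * flat.sum())) + 1
    area_sr = float(cell_sr.ravel()[order[:k]].sum())
    return 100.0 * area_sr / (2.0 * np.pi)


def _mwu_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney test by enumerating group assignments.

    Uses midranks, so remains exact under ties; feasible for small pooled
    sizes (C(12, 6) = 924 assignments at the cutoff used here).
    """
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a, n = len(a), len(pooled)
    u_obs = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    mu = n_a * (n - n_a) / 2.0
    dist = np.array(
        [
            ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0
            for idx in itertools.combinations(range(n), n_a)
        ]
    )
    p = float(np.mean(np.abs(dist - mu) >= np.abs(u_obs - mu) - 1e-12))
    return u_obs, p


def mann_whitney_u(
    group_a: np.ndarray, group_b: np.ndarray, exact_max_n: int = 12
) -> tuple[float, float]:
    """Mann-Whitney U rank test, two-sided.

    Returns ``(U, p)`` with U counted for ``group_a``.  The null
    distribution is enumerated exactly (midranks for ties) when the pooled
    sample size is at most ``exact_max_n``; larger samples use the normal
    approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size + b.size <= exact_max_n:
        return _mwu_exact(a, b)
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def behavior_ols(table: pd.DataFrame) -> pd.DataFrame:
    """OLS of scale value on lens power and behavior with all interactions.

    ``table`` is long format with columns value, sph, add, movement_class
    (categorical, "dynamic"/"static" or 0/1) and gaze_area.  Continuous
    predictors are centered; the movement class enters as a 0/1 indicator
    (dynamic = 1).  The design is the full factorial expansion: 4 main
    effects plus all 2-, 3- and 4-way interactions.

    Returns a coefficient table with estimates, standard errors, t values
    and two-sided p-values (no multiplicity correction).
    """
    required = {"value", "sph", "add", "movement_class", "gaze_area"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")

    mv = table["movement_class"]
    moving = (
        (mv == "dynamic").astype(float) if mv.dtype == object else mv.astype(float)
    )
    cols = {
        "sph": table["sph"].to_numpy(dtype=float),
        "add": table["add"].to_numpy(dtype=float),
        "dynamic": moving.to_numpy(),
        "gaze_area": table["gaze_area"].to_numpy(dtype=float),
    }
    for name in ("sph", "add", "gaze_area"):
        cols[name] = cols[name] - cols[name].mean()

    names = list(cols)
    design = {"Intercept": np.ones(len(table))}
    for order in range(1, 5):
        for combo in itertools.combinations(names, order):
            design[":".join(combo)] = np.prod([cols[c] for c in combo], axis=0)
    X = pd.DataFrame(design)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by sequential rank growth
        collinear = []
        kept: list[str] = []
        for col in X.columns:
            trial = X[kept + [col]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(kept):
                collinear.append(col)
            else:
                kept.append(col)
        raise ValueError(f"rank-deficient design; collinear terms: {collinear}")

    fit = sm.OLS(table["value"].to_numpy(dtype=float), X).fit()
    return pd.DataFrame(
        {
            "term": X.columns,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
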