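"""Cross-subject alignment and normalization of 1-D perceptual scales.

An ordinal embedding determines a scale only up to shift, positive
rescaling, and sign.  To compare subjects or form an average-observer
scale, the per-subject scales are aligned by generalized Procrustes
analysis (GPA) restricted to those 1-D similarity transforms: each scale
is regressed onto a running reference (sign flips allowed), the reference
is replaced by the mean of the aligned scales and re-standardized to unit
root-mean-square to prevent the classic shrink-to-zero degeneracy, and the
loop repeats to convergence.

After alignment one common affine map normalizes the convention: the
cross-subject mean of the undistorted reference lens becomes exactly 0 and
the cross-subject mean of the strongest lens (sph = 5, add = 3) exactly +1.
The map is shared by all subjects — individual subjects need not hit 0/1,
only the means do — so between-subject spread survives normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AlignedScales", "ScaleTransform", "gpa_align_1d", "normalize_scales"]


@dataclass(frozen=True)
class ScaleTransform:
    """Affine record mapping a raw scale to its aligned version:
    ``aligned = shift + sign * scale * raw`` with ``scale > 0``."""

    shift: float
    scale: float
    sign: int

    def apply(self, raw: np.ndarray) -> np.ndarray:
        return self.shift + self.sign * self.scale * np.asarray(raw, dtype=float)


@dataclass(frozen=True)
class AlignedScales:
    """Per-subject aligned scale values plus the transforms that produced them."""

    values: np.ndarray  # (n_subjects, n_stimuli)
    mean_scale: np.ndarray  # (n_stimuli,)
    transforms: tuple[ScaleTransform, ...]
    n_iterations: int = 0

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be (n_subjects, n_stimuli)")
        if len(self.transforms) != self.values.shape[0]:
            raise ValueError("one transform per subject required")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


def _fit_similarity_1d(raw: np.ndarray, reference: np.ndarray) -> ScaleTransform:
    """Least-squares shift + signed scale mapping ``raw`` toward ``reference``."""
    rc = raw - raw.mean()
    var = float(np.dot(rc, rc))
    beta1 = float(np.dot(rc, reference - reference.mean())) / var
    if beta1 == 0:
        beta1 = 1e-12  # orthogonal case: keep the (vanishing) magnitude, sign +
    sign = 1 if beta1 >= 0 else -1
    beta0 = reference.mean() - beta1 * raw.mean()
    return ScaleTransform(shift=beta0, scale=abs(beta1), sign=sign)


def gpa_align_1d(
    scales: np.ndarray | list,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> AlignedScales:
    """Generalized Procrustes alignment of 1-D scales.

    Parameters
    ----------
    scales : (n_subjects, n_stimuli) array-like
        Raw per-subject scale values; every row needs nonzero variance.

    Iterates similarity fits of each scale to the current reference with the
    reference re-centered and re-standardized to unit RMS each round, until
    the reference changes by less than ``tol`` (max-norm).
    """
    raw = np.asarray(scales, dtype=float)
    if raw.ndim != 2 or raw.shape[0] < 1:
        raise ValueError("scales must be a (n_subjects, n_stimuli) array")
    variances = raw.var(axis=1)
    degenerate = np.flatnonzero(variances == 0)
    if degenerate.size:
        raise ValueError(
            f"subject(s) {degenerate.tolist()} have zero-variance scales; "
            "cannot align a constant scale"
        )

    def standardize(v: np.ndarray) -> np.ndarray:
        v = v - v.mean()
        return v / np.sqrt(np.mean(v**2))

    reference = standardize(raw[0])
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        transforms = [_fit_similarity_1d(row, reference) for row in raw]
        aligned = np.vstack([tr.apply(row) for tr, row in zip(transforms, raw)])
        new_reference = standardize(aligned.mean(axis=0))
        # the reference is sign-arbitrary; compare up to sign
        if np.dot(new_reference, reference) < 0:
            new_reference = -new_reference
        delta = float(np.max(np.abs(new_reference - reference)))
        reference = new_reference
        if delta < tol:
            break
    transforms = [_fit_similarity_1d(row, reference) for row in raw]
    aligned = np.vstack([tr.apply(row) for tr, row in zip(transforms, raw)])
    return AlignedScales(
        values=aligned,
        mean_scale=aligned.mean(axis=0),
        transforms=tuple(transforms),
        n_iterations=n_iter,
    )


def normalize_scales(
    aligned: AlignedScales, zero_stimulus: int, unit_stimulus: int
) -> AlignedScales:
    """Apply the common 0/1 normalization convention.

    One affine map — shared across subjects — shifts and rescales every
    aligned scale so that the cross-subject mean at ``zero_stimulus`` (the
    undistorted lens) is exactly 0 and at ``unit_stimulus`` (the sph=5,
    add=3 lens) exactly +1.  Idempotent, and commutes with any common
    affine transform of the inputs.
    """
    n_stimuli = aligned.values.shape[1]
    for idx in (zero_stimulus, unit_stimulus):
        if not (0 <= idx < n_stimuli):
            raise ValueError(f"stimulus index {idx} out of range")
    m0 = float(aligned.values[:, zero_stimulus].mean())
    m1 = float(aligned.values[:, unit_stimulus].mean())
    if m1 == m0:
        raise ValueError(
            "degenerate normalization: the anchor stimuli have equal mean values"
        )
    denom = m1 - m0
    values = (aligned.values - m0) / denom
    sign = 1 if denom > 0 else -1
    transforms = tuple(
        ScaleTransform(
            shift=(tr.shift - m0) / denom,
            scale=tr.scale / abs(denom),
            sign=tr.sign * sign,
        )
        for tr in aligned.transforms
    )
    return AlignedScales(
        values=values,
        mean_scale=values.mean(axis=0),
        transforms=transforms,
        n_iterations=aligned.n_iterations,
    )
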