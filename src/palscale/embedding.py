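"""Soft ordinal embedding (SOE) of triplet similarity judgments.

Given responses "choice c was more similar to anchor a than the other
choice", SOE assigns each stimulus a coordinate vector so that embedding
distances agree with the judgments.  With winner ``w`` and loser ``l`` per
response, the objective is the squared hinge on squared distances

    L(X) = sum_r max(0, margin + ||x_a - x_w||^2 - ||x_a - x_l||^2)^2,

minimized by a full-batch first-order method (L-BFGS-B with the analytic
gradient) from several random initializations; the restart with the lowest
converged loss is returned.  The margin fixes the otherwise arbitrary
global scale of the solution; the embedding remains defined only up to a
similarity transform (shift, rotation/sign, positive rescaling), which all
downstream consumers must be — and are — invariant to.

Dimensionality is selected by k-fold cross-validation on held-out triplet
accuracy with a one-standard-error rule: the smallest dimension whose mean
held-out accuracy is within one standard error of the best mean.  Scale
robustness is quantified by bootstrap resampling of responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.model_selection import KFold

from .observer import TripletResponse

__all__ = [
    "PerceptualScale",
    "CVReport",
    "BootstrapEnsemble",
    "responses_to_triples",
    "soe_embed",
    "soe_embed_triples",
    "triplet_accuracy",
    "cv_dimension_select",
    "bootstrap_scales",
    "procrustes_align_1d",
]


@dataclass(frozen=True)
class PerceptualScale:
    """A fitted embedding: one coordinate row per stimulus."""

    coordinates: np.ndarray  # (n_stimuli, dim)
    loss: float
    accuracy: float
    seed: int
    best_restart: int

    def __post_init__(self) -> None:
        if self.coordinates.ndim != 2:
            raise ValueError("coordinates must be (n_stimuli, dim)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    @property
    def dim(self) -> int:
        return self.coordinates.shape[1]

    @property
    def values_1d(self) -> np.ndarray:
        """The scale as a 1-D vector (requires dim == 1)."""
        if self.dim != 1:
            raise ValueError(f"scale has dimension {self.dim}, not 1")
        return self.coordinates[:, 0].copy()


@dataclass(frozen=True)
class CVReport:
    """Cross-validated held-out accuracy per candidate dimension."""

    dims: tuple[int, ...]
    mean_accuracy: np.ndarray
    se_accuracy: np.ndarray
    selected_dim: int
    fold_accuracy: np.ndarray = field(repr=False, default=None)  # (n_dims, k)


@dataclass(frozen=True)
class BootstrapEnsemble:
    """Aligned bootstrap re-estimates of a 1-D scale and their spread."""

    samples: np.ndarray  # (B, n_stimuli)
    spread: np.ndarray  # (n_stimuli,) sd across samples
    point_estimate: np.ndarray


def responses_to_triples(responses: Sequence[TripletResponse]) -> np.ndarray:
    """Convert responses to an (m, 3) int array of (anchor, winner, loser)."""
    if len(responses) == 0:
        return np.empty((0, 3), dtype=np.intp)
    return np.array(
        [(r.trial.anchor, r.winner, r.loser) for r in responses], dtype=np.intp
    )


def _loss_grad(X: np.ndarray, triples: np.ndarray, margin: float):
    a, w, l = triples[:, 0], triples[:, 1], triples[:, 2]
    daw = X[a] - X[w]
    dal = X[a] - X[l]
    h = margin + np.einsum("ij,ij->i", daw, daw) - np.einsum("ij,ij->i", dal, dal)
    active = h > 0
    ha = h[active]
    loss = float(np.dot(ha, ha))
    grad = np.zeros_like(X)
    if ha.size:
        coef = (2.0 * ha)[:, None]
        ga = coef * 2.0 * (X[l[active]] - X[w[active]])
        gw = -coef * 2.0 * daw[active]
        gl = coef * 2.0 * dal[active]
        n = X.shape[0]
        idx = np.concatenate([a[active], w[active], l[active]])
        contrib = np.concatenate([ga, gw, gl])
        for d in range(X.shape[1]):
            grad[:, d] = np.bincount(idx, weights=contrib[:, d], minlength=n)
    return loss, grad


def _soe_single_fit(
    triples: np.ndarray,
    n_stimuli: int,
    dim: int,
    margin: float,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float]:
    """One first-order fit from a random normal initialization.

    L-BFGS-B with the analytic gradient: line-searched, loss non-increasing
    across accepted iterations, terminating when the relative loss change
    drops below ``tol`` (or the gradient vanishes).
    """
    x0 = rng.standard_normal(n_stimuli * dim)

    def fun_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        loss, grad = _loss_grad(x.reshape(n_stimuli, dim), triples, margin)
        return loss, grad.ravel()

    res = minimize(
        fun_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-12},
    )
    return res.x.reshape(n_stimuli, dim), float(res.fun)


def soe_embed_triples(
    triples: np.ndarray,
    n_stimuli: int,
    dim: int = 1,
    margin: float = 1.0,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> PerceptualScale:
    """Fit SOE on raw (anchor, winner, loser) triples; best of ``restarts``."""
    if n_stimuli < 2:
        raise ValueError("need at least 2 stimuli")
    if dim < 1:
        raise ValueError("dimension must be at least 1")
    if margin <= 0:
        raise ValueError("margin must be positive")
    if restarts < 1:
        raise ValueError("need at least one restart")
    triples = np.asarray(triples, dtype=np.intp).reshape(-1, 3)
    if triples.size and (triples.min() < 0 or triples.max() >= n_stimuli):
        raise ValueError("response references an unknown stimulus index")

    if len(triples) == 0:
        warnings.warn(
            "no responses: returning an arbitrary zero configuration "
            "(accuracy 1.0 by convention)",
            stacklevel=2,
        )
        return PerceptualScale(
            coordinates=np.zeros((n_stimuli, dim)),
            loss=0.0,
            accuracy=1.0,
            seed=seed,
            best_restart=0,
        )

    best: tuple[np.ndarray, float] | None = None
    best_restart = 0
    for r in range(restarts):
        rng = np.random.default_rng([seed, r])
        X, loss = _soe_single_fit(triples, n_stimuli, dim, margin, rng, tol, max_iter)
        if best is None or loss < best[1]:
            best = (X, loss)
            best_restart = r
    X, loss = best
    acc = _accuracy_from_triples(X, triples)
    return PerceptualScale(
        coordinates=X, loss=loss, accuracy=acc, seed=seed, best_restart=best_restart
    )


def soe_embed(
    responses: Sequence[TripletResponse],
    n_stimuli: int,
    dim: int = 1,
    margin: float = 1.0,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> PerceptualScale:
    """Fit a perceptual scale to triplet responses by soft ordinal embedding.

    Catch trials should be excluded by the caller; they are attention
    checks, not similarity evidence.
    """
    triples = responses_to_triples(responses)
    return soe_embed_triples(
        triples, n_stimuli, dim, margin, restarts, seed, tol, max_iter
    )


def _accuracy_from_triples(X: np.ndarray, triples: np.ndarray) -> float:
    a, w, l = triples[:, 0], triples[:, 1], triples[:, 2]
    dw = np.linalg.norm(X[a] - X[w], axis=1)
    dl = np.linalg.norm(X[a] - X[l], axis=1)
    return float(np.mean(np.where(dw < dl, 1.0, np.where(dw == dl, 0.5, 0.0))))


def triplet_accuracy(
    scale: PerceptualScale | np.ndarray, responses: Sequence[TripletResponse]
) -> float:
    """Fraction of responses whose winner is nearer the anchor in the embedding.

    Exact distance ties score 0.5.  Invariant under any global similarity
    transform of the embedding.
    """
    if len(responses) == 0:
        raise ValueError("accuracy of an empty response list is undefined")
    X = scale.coordinates if isinstance(scale, PerceptualScale) else np.asarray(scale)
    if X.ndim == 1:
        X = X[:, None]
    return _accuracy_from_triples(X, responses_to_triples(responses))


def cv_dimension_select(
    responses: Sequence[TripletResponse],
    n_stimuli: int,
    dims: Sequence[int] = (1, 2, 3),
    folds: int = 10,
    seed: int = 0,
    margin: float = 1.0,
    restarts: int = 3,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> CVReport:
    """Select embedding dimensionality by k-fold cross-validation.

    Responses are split into ``folds`` seeded folds; per dimension and fold
    the embedding is fit on the training responses and scored by triplet
    accuracy on the held-out ones.  The selected dimension is the smallest
    whose mean accuracy is within one standard error of the best mean
    (one-SE rule).  Catch trials must be excluded beforehand.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    dims = tuple(int(d) for d in dims)
    if not dims:
        raise ValueError("need at least one candidate dimension")
    triples = responses_to_triples(responses)
    if len(triples) < folds:
        raise ValueError("fewer responses than folds")

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_acc = np.empty((len(dims), folds))
    for i, dim in enumerate(dims):
        for k, (train_idx, test_idx) in enumerate(kf.split(triples)):
            if len(train_idx) == 0:
                raise ValueError("empty training fold")
            fit = soe_embed_triples(
                triples[train_idx],
                n_stimuli,
                dim=dim,
                margin=margin,
                restarts=restarts,
                seed=seed * 1000 + 7 * k + dim,
                tol=tol,
                max_iter=max_iter,
            )
            fold_acc[i, k] = _accuracy_from_triples(fit.coordinates, triples[test_idx])

    mean = fold_acc.mean(axis=1)
    se = fold_acc.std(axis=1, ddof=1) / np.sqrt(folds)
    best = int(np.argmax(mean))
    threshold = mean[best] - se[best]
    selected = min(d for d, m in zip(dims, mean) if m >= threshold)
    return CVReport(
        dims=dims,
        mean_accuracy=mean,
        se_accuracy=se,
        selected_dim=selected,
        fold_accuracy=fold_acc,
    )


def procrustes_align_1d(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Map ``source`` onto ``target`` by least-squares shift + signed scale.

    The 1-D similarity alignment used to compare re-estimated scales: the
    returned vector is ``beta0 + beta1 * source`` with ``beta1`` carrying
    the sign of the correlation (flip allowed).
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    sc = source - source.mean()
    var = float(np.dot(sc, sc))
    if var == 0:
        return np.full_like(target, target.mean())
    beta1 = float(np.dot(sc, target - target.mean())) / var
    beta0 = target.mean() - beta1 * source.mean()
    return beta0 + beta1 * source


def bootstrap_scales(
    responses: Sequence[TripletResponse],
    n_stimuli: int,
    dim: int = 1,
    B: int = 50,
    seed: int = 0,
    margin: float = 1.0,
    restarts: int = 3,
    point_estimate: PerceptualScale | None = None,
) -> BootstrapEnsemble:
    """Bootstrap the 1-D scale: resample responses with replacement, refit,
    align each refit to the point estimate, and report per-stimulus spread.

    Low spread indicates the responses determine the scale well.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap sample")
    if dim != 1:
        raise ValueError("bootstrap spread is defined for 1-D scales")
    triples = responses_to_triples(responses)
    if point_estimate is None:
        point_estimate = soe_embed_triples(
            triples, n_stimuli, dim=dim, margin=margin, restarts=max(restarts, 10),
            seed=seed,
        )
    ref = point_estimate.coordinates[:, 0]

    rng = np.random.default_rng(seed)
    samples = np.empty((B, n_stimuli))
    for b in range(B):
        idx = rng.integers(0, len(triples), size=len(triples))
        # common random numbers: every resample is fit from the same
        # initializations, so the spread reflects data variability rather
        # than the optimizer's init-dependent placement inside the
        # feasible region
        fit = soe_embed_triples(
            triples[idx], n_stimuli, dim=dim, margin=margin, restarts=restarts,
            seed=seed,
        )
        samples[b] = procrustes_align_1d(fit.coordinates[:, 0], ref)
    spread = samples.std(axis=0, ddof=0) if B > 1 else np.zeros(n_stimuli)
    return BootstrapEnsemble(samples=samples, spread=spread, point_estimate=ref.copy())
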