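"""Predictive models of the perceptual scale as a function of lens power.

The normalized scale values follow a strongly nonlinear law in the far
power: an exponential ``s(sph) = a + b * c**sph`` per addition-power group
captures it well, with the two groups differing mainly in offset ``a`` and
slope ``b`` but barely in the base ``c``.  This module fits that model and
benchmarks it in a leave-one-subject-out (LOSO) protocol against a linear
baseline (OLS on sph, add and their product) and a bagged-tree ceiling.

Out-of-sample R^2 is computed against the held-out subject's own mean and
reported unclipped — negative values are meaningful and must survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "ExponentialFit",
    "LosoReport",
    "fit_exponential",
    "predict_exponential",
    "fit_exponential_by_add",
    "loso_evaluate",
    "MODEL_FAMILIES",
]

MODEL_FAMILIES = ("linear", "exponential", "tree-ensemble")

#: Multi-start grid for the exponential base; brackets the plausible range
#: and avoids the slope/base exchange degeneracy near c = 1.
_C_INIT_GRID = (1.1, 1.3, 1.6, 2.0)
_C_MAX = 5.0


@dataclass(frozen=True)
class ExponentialFit:
    """Fitted parameters of ``value = a + b * c**sph`` for one add group."""

    a: float
    b: float
    c: float
    rss: float
    converged: bool
    degenerate: bool = False

    def predict(self, sph: np.ndarray) -> np.ndarray:
        return self.a + self.b * self.c ** np.asarray(sph, dtype=float)


@dataclass(frozen=True)
class LosoReport:
    """Per-subject out-of-sample R^2 for each model family."""

    table: pd.DataFrame  # columns: subject, family, r2

    def median_r2(self, family: str) -> float:
        sub = self.table[self.table["family"] == family]
        if sub.empty:
            raise KeyError(f"no rows for family {family!r}")
        return float(sub["r2"].median())


def fit_exponential(
    sph: np.ndarray,
    values: np.ndarray,
    c_grid: tuple[float, ...] = _C_INIT_GRID,
    c_max: float = _C_MAX,
) -> ExponentialFit:
    """Nonlinear least-squares fit of ``a + b * c**sph``.

    Multi-start: for each candidate base the offset and slope are seeded by
    the linear fit at that base, then all three parameters are refined
    jointly with the base bounded in ``(0, c_max]``.  Constant data short-
    circuits to the degenerate flat fit ``(a=mean, b=0, c=1)``.
    """
    sph = np.asarray(sph, dtype=float)
    values = np.asarray(values, dtype=float)
    if sph.shape != values.shape or sph.ndim != 1:
        raise ValueError("sph and values must be matching 1-D arrays")
    if np.unique(sph).size < 3:
        raise ValueError("need at least 3 distinct sph values")

    if np.allclose(values, values[0], rtol=0.0, atol=0.0):
        return ExponentialFit(
            a=float(values[0]), b=0.0, c=1.0, rss=0.0, converged=True, degenerate=True
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b, c = theta
        return a + b * c**sph - values

    best: ExponentialFit | None = None
    for c0 in c_grid:
        basis = np.column_stack([np.ones_like(sph), c0**sph])
        (a0, b0), *_ = np.linalg.lstsq(basis, values, rcond=None)
        try:
            sol = least_squares(
                residuals,
                x0=[a0, b0, c0],
                bounds=([-np.inf, -np.inf, 1e-8], [np.inf, np.inf, c_max]),
                method="trf",
            )
        except ValueError:
            continue
        rss = float(2.0 * sol.cost)
        fit = ExponentialFit(
            a=float(sol.x[0]),
            b=float(sol.x[1]),
            c=float(sol.x[2]),
            rss=rss,
            converged=bool(sol.success),
        )
        if best is None or (fit.converged and rss < best.rss):
            best = fit
    assert best is not None
    return best


def predict_exponential(fit: ExponentialFit, sph: np.ndarray) -> np.ndarray:
    return fit.predict(sph)


def fit_exponential_by_add(scale_table: pd.DataFrame) -> dict[float, ExponentialFit]:
    """Fit one exponential per addition-power group.

    ``scale_table`` needs columns sph, add, value and no reference rows
    (the undistorted condition belongs to no add group; its normalized
    cross-subject mean is 0 by convention and is predicted as such).
    """
    fits: dict[float, ExponentialFit] = {}
    for add, group in scale_table.groupby("add"):
        means = group.groupby("sph")["value"].mean()
        fits[float(add)] = fit_exponential(means.index.to_numpy(), means.to_numpy())
    return fits


def _r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    sse = float(np.sum((y_true - y_pred) ** 2))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0:
        return 1.0 if sse == 0 else -np.inf
    return 1.0 - sse / sst


def _predict_family(
    family: str,
    train: pd.DataFrame,
    test: pd.DataFrame,
    seed: int,
) -> np.ndarray:
    if family == "linear":
        def design(frame: pd.DataFrame) -> np.ndarray:
            s, a = frame["sph"].to_numpy(), frame["add"].to_numpy()
            return np.column_stack([np.ones(len(frame)), s, a, s * a])

        beta, *_ = np.linalg.lstsq(design(train), train["value"].to_numpy(), rcond=None)
        return design(test) @ beta

    if family == "exponential":
        fits = fit_exponential_by_add(train[~train["is_reference"]])
        pred = np.zeros(len(test))
        for i, row in enumerate(test.itertuples(index=False)):
            # the reference is the normalization origin: predicted 0
            pred[i] = 0.0 if row.is_reference else float(fits[row.add].predict(row.sph))
        return pred

    if family == "tree-ensemble":
        # bagging of unpruned trees: all features considered at every split
        model = RandomForestRegressor(
            n_estimators=100, max_features=1.0, random_state=seed
        )
        model.fit(train[["sph", "add"]].to_numpy(), train["value"].to_numpy())
        return model.predict(test[["sph", "add"]].to_numpy())

    raise ValueError(f"unknown model family {family!r}; choose from {MODEL_FAMILIES}")


def loso_evaluate(
    scale_table: pd.DataFrame,
    families: tuple[str, ...] = MODEL_FAMILIES,
    seed: int = 0,
) -> LosoReport:
    """Leave-one-subject-out evaluation of the model families.

    ``scale_table`` is long format with columns subject, sph, add, value
    and optionally is_reference (inferred as sph == 0 & add == 0 when
    absent).  For each held-out subject every family is trained on the
    remaining subjects' rows and scored by out-of-sample R^2 on the held-out
    subject's values, with total sum of squares about that subject's mean.
    """
    required = {"subject", "sph", "add", "value"}
    missing = required - set(scale_table.columns)
    if missing:
        raise ValueError(f"scale table missing columns: {sorted(missing)}")
    table = scale_table.copy()
    if "is_reference" not in table.columns:
        table["is_reference"] = (table["sph"] == 0) & (table["add"] == 0)
    subjects = table["subject"].unique()
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    for family in families:
        if family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {family!r}")

    rows = []
    for held_out in subjects:
        train = table[table["subject"] != held_out]
        test = table[table["subject"] == held_out]
        for family in families:
            pred = _predict_family(family, train, test, seed)
            rows.append(
                {
                    "subject": held_out,
                    "family": family,
                    "r2": _r2(test["value"].to_numpy(), pred),
                }
            )
    return LosoReport(table=pd.DataFrame(rows))
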