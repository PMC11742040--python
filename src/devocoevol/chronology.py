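"""Embryo weight -> developmental age calibration and relative-time mapping.

Embryo weight is a reliable proxy for developmental age within a species.
Calibration fits a monotone smoother of age (days post-coitum) on
Box-Cox-transformed weight (mg): the Box-Cox exponent is chosen by profile
likelihood, and the smoother is a non-negative combination of I-splines
(integrated B-splines), which is monotone non-decreasing by construction.

Ages are then mapped onto a species-homologous relative timeline (0-10 by
convention) anchored on two morphological milestones, so time courses from
species with different absolute developmental tempos become comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import nnls


class CalibrationError(ValueError):
    """Too few or degenerate weight/age pairs for calibration."""


class ExtrapolationError(ValueError):
    """Requested weight lies outside the calibrated range."""


@dataclass(frozen=True)
class WeightAgePair:
    weight: float  # mg, > 0
    age: float     # days post-coitum, > 0

    def __post_init__(self):
        if not (np.isfinite(self.weight) and np.isfinite(self.age)):
            raise ValueError("weight and age must be finite")
        if self.weight <= 0 or self.age <= 0:
            raise ValueError("weight and age must be strictly positive")


@dataclass(frozen=True)
class Milestones:
    """Ages (dpc) of the early (relative time 0) and late (10) milestones."""

    species: str
    age_at_0: float
    age_at_10: float

    def __post_init__(self):
        if not self.age_at_10 > self.age_at_0:
            raise ValueError("age_at_10 must exceed age_at_0")


@dataclass
class ChronologyModel:
    """Monotone weight -> age map for one species.

    The smoother is sum_j beta_j * I_j(boxcox(weight)) + intercept with
    beta_j >= 0 and I_j non-decreasing, hence predictions are monotone
    non-decreasing in weight over the training range. Predictions outside
    the training range raise rather than extrapolate.
    """

    species: str
    transform_lambda: float
    knots: np.ndarray = field(repr=False)
    degree: int = field(repr=False, default=3)
    coef: np.ndarray = field(repr=False, default=None)
    intercept: float = 0.0
    training_range: tuple[float, float] = (0.0, 0.0)
    rmse: float = float("nan")

    def _ispline_matrix(self, x: np.ndarray) -> np.ndarray:
        n_basis = len(self.knots) - self.degree - 1
        lo, hi = self.knots[0], self.knots[-1]
        xc = np.clip(x, lo, hi)
        cols = []
        for j in range(n_basis):
            c = np.zeros(n_basis)
            c[j] = 1.0
            anti = BSpline(self.knots, c, self.degree, extrapolate=False).antiderivative()
            cols.append(anti(xc) - anti(lo))
        return np.column_stack(cols)

    def predict(self, weight: np.ndarray | float) -> np.ndarray | float:
        scalar = np.isscalar(weight)
        w = np.atleast_1d(np.asarray(weight, dtype=float))
        lo, hi = self.training_range
        if np.any(w < lo - 1e-9) or np.any(w > hi + 1e-9):
            raise ExtrapolationError(
                f"weight outside training range [{lo:.6g}, {hi:.6g}] mg for {self.species}"
            )
        x = _boxcox(np.clip(w, lo, hi), self.transform_lambda)
        ages = self._ispline_matrix(x) @ self.coef + self.intercept
        return float(ages[0]) if scalar else ages


def _boxcox(w: np.ndarray, lam: float) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if abs(lam) < 1e-12:
        return np.log(w)
    return (w ** lam - 1.0) / lam


def _fit_monotone(x: np.ndarray, age: np.ndarray, n_interior: int):
    """NNLS fit of age on I-splines of x plus a free intercept."""
    lo, hi = float(x.min()), float(x.max())
    if n_interior > 0:
        interior = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
        interior = np.clip(interior, lo + 1e-12, hi - 1e-12)
    else:
        interior = np.array([])
    degree = 3
    knots = np.concatenate([np.full(degree + 1, lo), np.sort(interior),
                            np.full(degree + 1, hi)])
    model = ChronologyModel(species="", transform_lambda=0.0, knots=knots, degree=degree,
                            coef=None, training_range=(lo, hi))
    I = model._ispline_matrix(x)
    # free intercept realized inside NNLS as the difference of two columns
    A = np.column_stack([np.ones_like(x), -np.ones_like(x), I])
    sol, _ = nnls(A, age)
    intercept = sol[0] - sol[1]
    coef = sol[2:]
    resid = age - (I @ coef + intercept)
    return knots, degree, coef, intercept, float(np.sum(resid ** 2))


def fit_weight_age(
    pairs: list[WeightAgePair],
    species: str,
    *,
    lambda_grid: np.ndarray | None = None,
    n_interior: int | None = None,
) -> ChronologyModel:
    """Calibrate a monotone weight -> age model for one species.

    The Box-Cox exponent of weight is chosen on a grid by profile (Gaussian)
    likelihood of the monotone fit; the smoother itself is an I-spline NNLS
    fit, monotone non-decreasing by construction. Requires >= 10 pairs
    spanning a non-degenerate weight range.
    """
    if len(pairs) < 10:
        raise CalibrationError(f"need >= 10 weight/age pairs, got {len(pairs)}")
    w = np.array([p.weight for p in pairs], dtype=float)
    age = np.array([p.age for p in pairs], dtype=float)
    if np.ptp(w) <= 0:
        raise CalibrationError("all calibration weights identical")
    if n_interior is None:
        n_interior = int(np.clip(np.unique(w).size // 10, 1, 8))
    if lambda_grid is None:
        lambda_grid = np.linspace(-1.0, 2.0, 61)

    best = None
    for lam in lambda_grid:
        x = _boxcox(w, lam)
        knots, degree, coef, intercept, rss = _fit_monotone(x, age, n_interior)
        if best is None or rss < best[0] - 1e-12:
            best = (rss, lam, knots, degree, coef, intercept)
    rss, lam, knots, degree, coef, intercept = best
    model = ChronologyModel(
        species=species, transform_lambda=float(lam), knots=knots, degree=degree,
        coef=coef, intercept=intercept,
        training_range=(float(w.min()), float(w.max())),
        rmse=float(np.sqrt(rss / len(w))),
    )
    return model


def predict_age(model: ChronologyModel, weight: float) -> float:
    """Predicted developmental age (dpc) at a weight inside the training range."""
    return model.predict(weight)


def to_relative_time(age: np.ndarray | float, milestones: Milestones):
    """Affine map of age onto the milestone-anchored 0-10 relative timeline.

    Values outside [0, 10] are returned as-is (the sample predates or
    postdates the milestones); use `flag_out_of_window` to mark them.
    """
    age = np.asarray(age, dtype=float)
    # ratio first so the anchors map to 0 and 10 exactly
    rel = 10.0 * ((age - milestones.age_at_0)
                  / (milestones.age_at_10 - milestones.age_at_0))
    return float(rel) if rel.ndim == 0 else rel


def flag_out_of_window(relative_time: np.ndarray | float) -> np.ndarray | bool:
    rel = np.asarray(relative_time, dtype=float)
    flag = (rel < 0) | (rel > 10)
    return bool(flag) if flag.ndim == 0 else flag
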