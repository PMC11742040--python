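"""Cubic B-spline bases for temporal expression curves.

Curves live on the relative developmental timeline (0-10 by default).
The default basis is a third-degree B-spline with 2 interior knots placed
at quantiles of the observed sampling times; for sparse designs (fewer
distinct timepoints than basis functions) the basis auto-reduces so the
design stays identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class SplineConfig:
    """Specification of the per-curve spline basis.

    degree : polynomial degree of the B-spline pieces (default cubic).
    interior_knots : number of interior knots, placed at quantiles of the
        observed times (default 2, i.e. the 33%/67% quantiles).
    domain : closed interval on which curves are defined.
    """

    degree: int = 3
    interior_knots: int = 2
    domain: tuple[float, float] = (0.0, 10.0)

    @property
    def n_basis(self) -> int:
        return self.degree + self.interior_knots + 1

    def reduced_for(self, times: np.ndarray) -> "SplineConfig":
        """Auto-reduce the basis for sparse designs.

        With fewer distinct timepoints than basis functions the full basis
        is unidentifiable; drop interior knots first, then degree, so that
        n_basis <= number of distinct timepoints. Three distinct timepoints
        yield a quadratic polynomial (degree 2, no interior knots).
        """
        n_distinct = np.unique(np.asarray(times, float)).size
        if n_distinct < 2:
            raise ValueError("need at least 2 distinct timepoints for a temporal basis")
        degree, interior = self.degree, self.interior_knots
        while degree + interior + 1 > n_distinct and interior > 0:
            interior -= 1
        while degree + interior + 1 > n_distinct and degree > 1:
            degree -= 1
        if (degree, interior) == (self.degree, self.interior_knots):
            return self
        return SplineConfig(degree=degree, interior_knots=interior, domain=self.domain)


@dataclass(frozen=True)
class SplineBasis:
    """A concrete knot vector, built from a SplineConfig and observed times."""

    config: SplineConfig
    knots: np.ndarray = field(repr=False)

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.config.degree - 1

    def evaluate(self, times: np.ndarray) -> np.ndarray:
        """Evaluate all basis functions at `times` -> (len(times), n_basis).

        B-splines form a partition of unity on the domain: rows are
        non-negative and sum to 1.
        """
        t = np.asarray(times, dtype=float)
        lo, hi = self.config.domain
        if np.any(t < lo - 1e-9) or np.any(t > hi + 1e-9):
            raise ValueError(f"times outside spline domain [{lo}, {hi}]")
        t = np.clip(t, lo, hi)
        mat = BSpline.design_matrix(t, self.knots, self.config.degree,
                                    extrapolate=False).toarray()
        return mat


def build_basis(config: SplineConfig, times: np.ndarray) -> SplineBasis:
    """Place interior knots at quantiles of the observed times."""
    cfg = config.reduced_for(times)
    lo, hi = cfg.domain
    t = np.asarray(times, dtype=float)
    if cfg.interior_knots > 0:
        qs = np.linspace(0, 1, cfg.interior_knots + 2)[1:-1]
        interior = np.quantile(t, qs)
        interior = np.clip(interior, lo + 1e-9, hi - 1e-9)
    else:
        interior = np.array([])
    knots = np.concatenate([
        np.full(cfg.degree + 1, lo), np.sort(interior), np.full(cfg.degree + 1, hi)
    ])
    return SplineBasis(config=cfg, knots=knots)
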