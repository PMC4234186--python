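"""P-spline building blocks: B-spline design matrices, random-walk penalties
and the centering used to keep additive terms identifiable.

A smooth f(x) is represented as B(x) @ beta with B a cubic B-spline basis on
equidistant knots and beta carrying a second-order random-walk prior
beta ~ N(0, tau^2 K^-), K = D2' D2.  K has rank m-2: constants and linear
trends in the coefficients are unpenalised, which is what lets the smooth
borrow a straight line for free and spend tau^2 only on curvature.
"""

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


def bspline_design(x, bounds, n_inner_knots, degree=3):
    """Clamped B-spline design matrix on equidistant knots.

    ``n_inner_knots`` counts the equal-width knot intervals partitioning
    ``bounds``; the basis has ``m = n_inner_knots + degree`` functions and
    every row sums to one (partition of unity) for x inside the range.

    Raises ``ValueError`` naming the first offending value for x outside
    ``bounds``.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    lo, hi = float(bounds[0]), float(bounds[1])
    if not np.isfinite([lo, hi]).all() or hi <= lo:
        raise ValueError(f"invalid covariate range ({lo}, {hi})")
    if n_inner_knots < 1:
        raise ValueError("n_inner_knots must be >= 1")
    bad = x[(x < lo) | (x > hi) | ~np.isfinite(x)]
    if bad.size:
        raise ValueError(f"covariate value {bad[0]} outside spline range [{lo}, {hi}]")
    knots = np.r_[np.full(degree, lo), np.linspace(lo, hi, n_inner_knots + 1), np.full(degree, hi)]
    design = BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()
    return design


def rw2_penalty(m):
    """Second-order random-walk penalty K = D2' D2 for m coefficients.

    K is symmetric PSD with rank m-2 and annihilates constant and linear
    coefficient sequences.
    """
    if m < 3:
        raise ValueError("a second-order penalty needs at least 3 coefficients")
    d2 = np.diff(np.eye(m), n=2, axis=0)
    return d2.T @ d2


def center(values, weights=None):
    """Remove the (weighted) mean from ``values``.

    Returns ``(centered, constant)`` where ``constant`` is the removed mean,
    to be absorbed into the model intercept by the caller.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot center an empty vector")
    if weights is None:
        const = float(values.mean())
    else:
        weights = np.asarray(weights, dtype=float)
        total = weights.sum()
        if total <= 0:
            raise ValueError("total weight must be positive")
        const = float(values @ weights / total)
    return values - const, const


@dataclass(frozen=True)
class SplineBasis:
    """A penalised B-spline basis over a fixed covariate range."""

    bounds: tuple[float, float]
    n_inner_knots: int
    degree: int = 3
    penalty_order: int = 2
    m: int = field(init=False)
    penalty: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "m", self.n_inner_knots + self.degree)
        if self.penalty_order != 2:
            raise ValueError("only second-order penalties are supported")
        object.__setattr__(self, "penalty", rw2_penalty(self.m))

    @property
    def knots(self):
        lo, hi = self.bounds
        return np.r_[
            np.full(self.degree, lo),
            np.linspace(lo, hi, self.n_inner_knots + 1),
            np.full(self.degree, hi),
        ]

    def design(self, x):
        return bspline_design(x, self.bounds, self.n_inner_knots, self.degree)

    def greville(self):
        """Knot averages; coefficients on a line there evaluate to that line."""
        t = self.knots
        k = self.degree
        return np.array([t[i + 1 : i + 1 + k].mean() for i in range(self.m)])
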