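"""Dose-rate dependence of fitted kinetic rates.

Once a growth rate r and a senescence rate p have been estimated per
exposure condition, their dependence on dose rate (mGy/h) is summarised by
weighted polynomial fits — linear, or linear-quadratic when curvature is
suspected — with the per-condition rate SDs treated as known weights.
Nested models are compared by the extra-sum-of-squares F test, the
standard small-sample choice when only a handful of dose rates exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RatePoint",
    "TrendFit",
    "TrendComparison",
    "fit_trend",
    "compare_nested",
    "percent_change",
]


@dataclass(frozen=True)
class RatePoint:
    """A fitted kinetic rate at one dose rate, with its uncertainty."""

    dose_rate: float  # mGy/h
    rate: float       # per week
    rate_sd: float    # per week

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        if not self.rate_sd > 0:
            raise ValueError(f"rate_sd must be > 0, got {self.rate_sd}")


@dataclass(frozen=True)
class TrendFit:
    """Weighted polynomial fit of rate vs dose rate.

    ``coefficients`` are (intercept, linear[, quadratic]) in units of
    per-week, per-week-per-mGy/h and per-week-per-(mGy/h)^2.
    """

    degree: int
    coefficients: tuple[float, ...]
    coefficient_sd: tuple[float, ...]
    weighted_rss: float
    dof: int
    dose_rates: tuple[float, ...]
    rates: tuple[float, ...]
    rate_sds: tuple[float, ...]

    @property
    def slope(self) -> float:
        return self.coefficients[1]

    def predict(self, dose_rate) -> np.ndarray:
        x = np.asarray(dose_rate, dtype=float)
        return sum(c * x**k for k, c in enumerate(self.coefficients))


@dataclass(frozen=True)
class TrendComparison:
    """Extra-sum-of-squares comparison of nested trend fits."""

    f_statistic: float
    p_value: float
    preferred_degree: int
    alpha: float


def fit_trend(points: list[RatePoint], degree: int = 1) -> TrendFit:
    """Weighted least-squares polynomial fit of rate against dose rate.

    Weights are 1/rate_sd^2 and are treated as known (coefficient SDs are
    the unscaled (X'WX)^-1 diagonal — the rate SDs come from the upstream
    kinetic fits, not from these residuals).  Solved by the closed-form
    normal equations.
    """
    if degree not in (1, 2):
        raise ValueError(f"degree must be 1 or 2, got {degree}")
    if len(points) < degree + 1:
        raise ValueError(f"need >= {degree + 1} points for degree {degree}")
    x = np.array([p.dose_rate for p in points])
    y = np.array([p.rate for p in points])
    sd = np.array([p.rate_sd for p in points])
    w = 1.0 / sd**2

    X = np.vander(x, degree + 1, increasing=True)
    XtW = X.T * w
    normal = XtW @ X
    beta = np.linalg.solve(normal, XtW @ y)
    cov = np.linalg.inv(normal)
    resid = y - X @ beta
    rss = float(np.sum(w * resid**2))
    return TrendFit(
        degree=degree,
        coefficients=tuple(float(b) for b in beta),
        coefficient_sd=tuple(float(s) for s in np.sqrt(np.diag(cov))),
        weighted_rss=rss,
        dof=len(points) - (degree + 1),
        dose_rates=tuple(x),
        rates=tuple(y),
        rate_sds=tuple(sd),
    )


def compare_nested(linear: TrendFit, quadratic: TrendFit,
                   alpha: float = 0.05) -> TrendComparison:
    """Extra-sum-of-squares F test of linear vs linear-quadratic.

    F = [(RSS_1 - RSS_2) / (dof_1 - dof_2)] / (RSS_2 / dof_2); the
    quadratic is preferred only when its improvement is significant at
    ``alpha``.
    """
    if linear.degree != 1 or quadratic.degree != 2:
        raise ValueError("pass the degree-1 fit first and the degree-2 fit second")
    if (linear.dose_rates != quadratic.dose_rates
            or linear.rates != quadratic.rates
            or linear.rate_sds != quadratic.rate_sds):
        raise ValueError("fits were not computed on the same points")
    if quadratic.dof < 1:
        raise ValueError("quadratic fit needs at least 1 residual dof")
    dfn = linear.dof - quadratic.dof
    dfd = quadratic.dof
    if quadratic.weighted_rss <= 0:
        f_stat = np.inf if linear.weighted_rss > quadratic.weighted_rss else 0.0
    else:
        f_stat = ((linear.weighted_rss - quadratic.weighted_rss) / dfn
                  / (quadratic.weighted_rss / dfd))
    f_stat = max(float(f_stat), 0.0)
    p = float(stats.f.sf(f_stat, dfn, dfd))
    return TrendComparison(
        f_statistic=f_stat,
        p_value=p,
        preferred_degree=2 if p < alpha else 1,
        alpha=alpha,
    )


def percent_change(rate_a: float, rate_b: float) -> float:
    """Relative reduction 100 (a - b) / a of rate b versus reference a."""
    if rate_a == 0:
        raise ZeroDivisionError("reference rate must be non-zero")
    return 100.0 * (rate_a - rate_b) / rate_a
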