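"""Logistic kinetics of population growth and senescence accumulation.

The cell population of a chronically irradiated primary culture grows
logistically: the ratio N(t)/N0 of counted to seeded cells follows

    N(t)/N0 = K / (1 + A * exp(-r * t)),        dN/dt = r N (1 - N/K)

with carrying capacity K (in ratio units, so N(0)/N0 = 1 when A = K - 1),
shape parameter A and growth rate r per week.  The percentage S(t) of
senescence-marker-positive (SA-beta-gal stained) cells follows the same
law with the asymptote pinned at 100%:

    S(t) = 100 / (1 + B * exp(-p * t))

leaving only the shape B and the senescence rate p free.

Fitting is weighted nonlinear least squares against replicate-summarised
time series (week, mean, SEM, n), minimising sum w_i (y_i - f(t_i))^2 with
w_i = 1/SEM_i^2 when every SEM is positive and unweighted otherwise.
Parameters are fitted on the log scale to enforce positivity; reported
standard deviations come from the Jacobian-based covariance scaled by the
reduced chi-square (the convention of classic Levenberg-Marquardt fit
routines) and are mapped back to natural scale by the delta method.

The fitters are scikit-learn style estimators (:class:`LogisticGrowthFitter`
and :class:`LogisticSenescenceFitter`); :func:`fit_growth` and
:func:`fit_senescence` are thin functional wrappers returning a
:class:`FitResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

__all__ = [
    "GrowthParams",
    "SenescenceParams",
    "TimeSeries",
    "FitResult",
    "logistic_growth",
    "logistic_growth_ode_rhs",
    "logistic_senescence",
    "population_doubling",
    "LogisticGrowthFitter",
    "LogisticSenescenceFitter",
    "fit_growth",
    "fit_senescence",
    "predict_with_band",
]

Endpoint = Literal["growth_ratio", "senescence_percent"]


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth parameters: carrying capacity K (ratio units),
    shape A (dimensionless) and growth rate r (per week)."""

    K: float
    A: float
    r: float

    def __post_init__(self) -> None:
        if not self.K > 1:
            raise ValueError(f"K must be > 1 (ratio units), got {self.K}")
        if not self.A > 0:
            raise ValueError(f"A must be > 0, got {self.A}")
        if not self.r > 0:
            raise ValueError(f"r must be > 0 per week, got {self.r}")

    @classmethod
    def from_carrying_capacity(cls, K: float, r: float) -> "GrowthParams":
        """Parameters with A = K - 1, i.e. N(0)/N0 = 1 exactly."""
        return cls(K=K, A=K - 1.0, r=r)


@dataclass(frozen=True)
class SenescenceParams:
    """Senescence logistic parameters: shape B and rate p (per week).
    The asymptote is fixed at 100% stained cells."""

    B: float
    p: float

    def __post_init__(self) -> None:
        if not self.B > 0:
            raise ValueError(f"B must be > 0, got {self.B}")
        if not self.p > 0:
            raise ValueError(f"p must be > 0 per week, got {self.p}")

    @classmethod
    def from_initial_percent(cls, s0: float, p: float) -> "SenescenceParams":
        """Fix B so that S(0) equals `s0` percent."""
        if not 0 < s0 < 100:
            raise ValueError(f"S(0) must be in (0, 100), got {s0}")
        return cls(B=100.0 / s0 - 1.0, p=p)


@dataclass(frozen=True)
class TimeSeries:
    """Replicate-summarised observations of one endpoint in one condition.

    ``t`` in weeks (strictly increasing), ``mean`` and ``sem`` in the
    endpoint's units (dimensionless ratio, or percent in [0, 100]),
    ``n`` the replicate count per point.
    """

    condition: str
    endpoint: Endpoint
    t: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t", "mean", "sem", "n"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.endpoint not in ("growth_ratio", "senescence_percent"):
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if not (len(self.t) == len(self.mean) == len(self.sem) == len(self.n)):
            raise ValueError("t, mean, sem, n must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(self.mean < 0) or np.any(self.sem < 0):
            raise ValueError("means and SEMs must be non-negative")
        if self.endpoint == "senescence_percent" and np.any(self.mean > 100):
            raise ValueError("senescence percentages must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a weighted NLLS fit.

    ``params`` is a :class:`GrowthParams` or :class:`SenescenceParams`;
    ``param_sd`` maps parameter name to its reported standard deviation;
    ``covariance`` is the natural-scale covariance of the free parameters
    (rows/columns in ``free_names`` order); ``dof`` = points - free
    parameters; ``weighted_rss`` the minimised objective.
    """

    params: GrowthParams | SenescenceParams
    param_sd: dict[str, float]
    dof: int
    weighted_rss: float
    converged: bool
    n_iterations: int
    free_names: tuple[str, ...] = ()
    covariance: np.ndarray | None = None
    message: str = ""
    endpoint: Endpoint = "growth_ratio"
    condition: str = ""

    def predict(self, t: Sequence[float] | np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if isinstance(self.params, GrowthParams):
            return logistic_growth(t, self.params)
        return logistic_senescence(t, self.params)


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------

def logistic_growth(t, params: GrowthParams):
    """Closed-form logistic ratio K / (1 + A e^{-rt}); increasing, bounded by K."""
    t = np.asarray(t, dtype=float)
    return params.K / (1.0 + params.A * np.exp(-params.r * t))


def logistic_growth_ode_rhs(N, params: GrowthParams):
    """Right-hand side r N (1 - N/K) of the logistic growth law (per week)."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("population ratio N must be >= 0")
    return params.r * N * (1.0 - N / params.K)


def logistic_senescence(t, params: SenescenceParams):
    """Percentage of senescent cells 100 / (1 + B e^{-pt}), asymptote 100."""
    t = np.asarray(t, dtype=float)
    return 100.0 / (1.0 + params.B * np.exp(-params.p * t))


def population_doubling(n_ratio):
    """Population doublings PD = log2(N/N0) accumulated since seeding."""
    n_ratio = np.asarray(n_ratio, dtype=float)
    if np.any(n_ratio <= 0):
        raise ValueError("population ratio must be > 0")
    return np.log2(n_ratio)


# ---------------------------------------------------------------------------
# fitting machinery
# ---------------------------------------------------------------------------

def _weights(sem: np.ndarray, weighted: bool) -> np.ndarray:
    """Square-root weights for the residual vector: 1/SEM when all SEMs are
    positive, else 1 (unweighted)."""
    if weighted and np.all(sem > 0):
        return 1.0 / sem
    return np.ones_like(sem)


def _solve_nlls(model, t, y, sqrt_w, theta0, max_iter, ftol, gtol):
    """Minimise the weighted RSS over log-scale parameters theta.

    Returns (theta_hat, cov_theta, rss_w, converged, n_iter, message).
    cov_theta is the log-scale covariance scaled by the reduced chi-square;
    with zero dof it is a matrix of zeros (no residual information).
    """

    def resid(theta):
        return sqrt_w * (y - model(t, np.exp(theta)))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # LM can overflow transiently in exp
        res = least_squares(
            resid,
            theta0,
            method="lm",
            ftol=ftol,
            xtol=ftol,
            gtol=gtol,
            max_nfev=max_iter * (len(theta0) + 1),
        )
    rss = float(2.0 * res.cost)
    dof = len(y) - len(theta0)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.full((len(theta0), len(theta0)), np.nan)
    s2 = rss / dof if dof > 0 else 0.0
    return res.x, cov * s2, rss, bool(res.status > 0), int(res.nfev), res.message


def _is_degenerate(y: np.ndarray, upper: float | None = None) -> bool:
    """No usable kinetic signal: flat series, or saturated at the asymptote."""
    if np.ptp(y) <= 1e-12 * max(1.0, float(np.max(np.abs(y)))):
        return True
    if upper is not None and np.all(y >= upper - 1e-9):
        return True
    return False


class LogisticGrowthFitter(BaseEstimator):
    """Three-parameter logistic fit of the population ratio N(t)/N0.

    Parameters
    ----------
    constrain_shape : bool, default False
        If True, tie A = K - 1 (so the fitted curve passes exactly through
        ratio 1 at t = 0) and fit only (K, r).  The default fits K, A and r
        independently.
    weighted : bool, default True
        Weight residuals by 1/SEM^2 when all SEMs are positive.
    init : GrowthParams or None
        Starting point; when absent a deterministic scale-aware guess is
        used (K = 1.5 max(y), r = 4/t-range, A inverted from the first
        point).
    max_iter : int
        Iteration budget for the Levenberg-Marquardt solver.
    ftol, gtol : float
        Convergence tolerances on the relative RSS change and gradient norm.

    Attributes
    ----------
    K_, A_, r_ : float
        Best-fit parameters (natural scale).
    params_ : GrowthParams
    param_sd_ : dict mapping name -> standard deviation (delta method,
        covariance scaled by reduced chi-square).
    covariance_ : ndarray, natural-scale covariance of the free parameters.
    dof_, weighted_rss_, converged_, n_iter_ : fit diagnostics.
    """

    _FREE = ("K", "A", "r")

    def __init__(self, constrain_shape=False, weighted=True, init=None,
                 max_iter=500, ftol=1e-10, gtol=1e-8):
        self.constrain_shape = constrain_shape
        self.weighted = weighted
        self.init = init
        self.max_iter = max_iter
        self.ftol = ftol
        self.gtol = gtol

    # -- model over the free (exponentiated) parameter vector ---------------
    def _model(self, t, p):
        if self.constrain_shape:
            K, r = p
            return K / (1.0 + (K - 1.0) * np.exp(-r * t))
        K, A, r = p
        return K / (1.0 + A * np.exp(-r * t))

    def _default_init(self, t, y):
        K0 = 1.5 * float(np.max(y))
        K0 = max(K0, 1.0 + 1e-6)
        r0 = 4.0 / float(t[-1] - t[0]) if t[-1] > t[0] else 1.0
        # invert the first observation through the model for the shape
        ratio = max(K0 / max(y[0], 1e-12) - 1.0, 1e-6)
        A0 = ratio * np.exp(r0 * t[0])
        return K0, A0, r0

    def fit(self, t, y, sem=None):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        n_free = 2 if self.constrain_shape else 3
        if len(t) < n_free + 1:
            raise ValueError(
                f"need at least {n_free + 1} points for {n_free} free parameters"
            )
        sem = np.zeros_like(y) if sem is None else np.asarray(sem, dtype=float)
        sqrt_w = _weights(sem, self.weighted)

        if self.init is not None:
            K0, A0, r0 = self.init.K, self.init.A, self.init.r
        else:
            K0, A0, r0 = self._default_init(t, y)
        theta0 = np.log([K0, r0] if self.constrain_shape else [K0, A0, r0])

        if _is_degenerate(y):
            self._set_fitted(
                np.log([max(K0, 1 + 1e-6), r0] if self.constrain_shape
                       else [max(K0, 1 + 1e-6), A0, r0]),
                np.zeros((n_free, n_free)), np.nan, False, 0,
                "degenerate series: no growth signal", len(t) - n_free)
            return self

        theta, cov, rss, ok, nit, msg = _solve_nlls(
            self._model, t, y, sqrt_w, theta0, self.max_iter, self.ftol, self.gtol
        )
        self._set_fitted(theta, cov, rss, ok, nit, msg, len(t) - n_free)
        return self

    def _set_fitted(self, theta, cov_log, rss, ok, nit, msg, dof):
        p = np.exp(theta)
        if self.constrain_shape:
            self.K_, self.r_ = float(p[0]), float(p[1])
            self.A_ = self.K_ - 1.0
            names = ("K", "r")
        else:
            self.K_, self.A_, self.r_ = (float(v) for v in p)
            names = self._FREE
        # delta method: cov_natural = diag(p) cov_log diag(p)
        D = np.diag(p)
        cov_nat = D @ cov_log @ D
        sd = np.sqrt(np.clip(np.diag(cov_nat), 0.0, None))
        self.params_ = GrowthParams(K=self.K_, A=self.A_, r=self.r_)
        self.free_names_ = names
        self.param_sd_ = dict(zip(names, (float(s) for s in sd)))
        self.covariance_ = cov_nat
        self.dof_ = int(dof)
        self.weighted_rss_ = float(rss)
        self.converged_ = bool(ok)
        self.n_iter_ = int(nit)
        self.message_ = msg

    def predict(self, t):
        return logistic_growth(np.asarray(t, dtype=float), self.params_)

    def result(self) -> FitResult:
        return FitResult(
            params=self.params_, param_sd=self.param_sd_, dof=self.dof_,
            weighted_rss=self.weighted_rss_, converged=self.converged_,
            n_iterations=self.n_iter_, free_names=self.free_names_,
            covariance=self.covariance_, message=self.message_,
            endpoint="growth_ratio",
        )


class LogisticSenescenceFitter(BaseEstimator):
    """Two-parameter logistic fit of the senescent-cell percentage S(t).

    The asymptote is pinned at 100% (every cell eventually stains), so only
    the shape B and the senescence rate p per week are free.  Interface and
    conventions mirror :class:`LogisticGrowthFitter`.
    """

    _FREE = ("B", "p")

    def __init__(self, weighted=True, init=None, max_iter=500,
                 ftol=1e-10, gtol=1e-8):
        self.weighted = weighted
        self.init = init
        self.max_iter = max_iter
        self.ftol = ftol
        self.gtol = gtol

    @staticmethod
    def _model(t, p):
        B, rate = p
        return 100.0 / (1.0 + B * np.exp(-rate * t))

    def fit(self, t, y, sem=None):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(t) < 3:
            raise ValueError("need at least 3 points for 2 free parameters")
        sem = np.zeros_like(y) if sem is None else np.asarray(sem, dtype=float)
        sqrt_w = _weights(sem, self.weighted)

        if self.init is not None:
            B0, p0 = self.init.B, self.init.p
        else:
            p0 = 4.0 / float(t[-1] - t[0]) if t[-1] > t[0] else 0.5
            y0 = min(max(float(y[0]), 1e-6), 100.0 - 1e-6)
            B0 = max((100.0 / y0 - 1.0), 1e-6) * np.exp(p0 * t[0])
        theta0 = np.log([B0, p0])

        if _is_degenerate(y, upper=100.0):
            self._set_fitted(theta0, np.zeros((2, 2)), np.nan, False, 0,
                             "degenerate series: flat or saturated", len(t) - 2)
            return self

        theta, cov, rss, ok, nit, msg = _solve_nlls(
            self._model, t, y, sqrt_w, theta0, self.max_iter, self.ftol, self.gtol
        )
        self._set_fitted(theta, cov, rss, ok, nit, msg, len(t) - 2)
        return self

    def _set_fitted(self, theta, cov_log, rss, ok, nit, msg, dof):
        p = np.exp(theta)
        self.B_, self.p_ = float(p[0]), float(p[1])
        D = np.diag(p)
        cov_nat = D @ cov_log @ D
        sd = np.sqrt(np.clip(np.diag(cov_nat), 0.0, None))
        self.params_ = SenescenceParams(B=self.B_, p=self.p_)
        self.free_names_ = self._FREE
        self.param_sd_ = dict(zip(self._FREE, (float(s) for s in sd)))
        self.covariance_ = cov_nat
        self.dof_ = int(dof)
        self.weighted_rss_ = float(rss)
        self.converged_ = bool(ok)
        self.n_iter_ = int(nit)
        self.message_ = msg

    def predict(self, t):
        return logistic_senescence(np.asarray(t, dtype=float), self.params_)

    def result(self) -> FitResult:
        return FitResult(
            params=self.params_, param_sd=self.param_sd_, dof=self.dof_,
            weighted_rss=self.weighted_rss_, converged=self.converged_,
            n_iterations=self.n_iter_, free_names=self.free_names_,
            covariance=self.covariance_, message=self.message_,
            endpoint="senescence_percent",
        )


# ---------------------------------------------------------------------------
# functional wrappers over TimeSeries
# ---------------------------------------------------------------------------

def fit_growth(series: TimeSeries, init: GrowthParams | None = None,
               constrain_shape: bool = False, weighted: bool = True) -> FitResult:
    """Fit the three-parameter growth logistic to a growth-ratio series."""
    if series.endpoint != "growth_ratio":
        raise ValueError(f"expected a growth_ratio series, got {series.endpoint}")
    est = LogisticGrowthFitter(constrain_shape=constrain_shape, weighted=weighted,
                               init=init)
    est.fit(series.t, series.mean, series.sem)
    res = est.result()
    return FitResult(**{**res.__dict__, "condition": series.condition})


def fit_senescence(series: TimeSeries, init: SenescenceParams | None = None,
                   weighted: bool = True) -> FitResult:
    """Fit the two-parameter senescence logistic to a percentage series."""
    if series.endpoint != "senescence_percent":
        raise ValueError(f"expected a senescence_percent series, got {series.endpoint}")
    est = LogisticSenescenceFitter(weighted=weighted, init=init)
    est.fit(series.t, series.mean, series.sem)
    res = est.result()
    return FitResult(**{**res.__dict__, "condition": series.condition})


def predict_with_band(fit: FitResult, t_grid) -> tuple[np.ndarray, np.ndarray]:
    """Model curve on ``t_grid`` with a first-order propagated SD band.

    The band is sqrt(g' C g) where g is the gradient of the model with
    respect to the free parameters (numerically differenced) and C the
    natural-scale parameter covariance of the fit.
    """
    if not fit.converged:
        raise ValueError("cannot propagate uncertainty from a non-converged fit")
    if fit.covariance is None:
        raise ValueError("fit carries no covariance")
    t_grid = np.asarray(t_grid, dtype=float)
    base = dict(zip(fit.free_names, (getattr(fit.params, n) for n in fit.free_names)))

    def curve(values: dict[str, float]) -> np.ndarray:
        kw = {f: getattr(fit.params, f) for f in fit.params.__dataclass_fields__}
        kw.update(values)
        params = type(fit.params)(**kw)
        return (logistic_growth(t_grid, params)
                if isinstance(fit.params, GrowthParams)
                else logistic_senescence(t_grid, params))

    y = curve(base)
    grads = []
    for name in fit.free_names:
        h = 1e-6 * max(abs(base[name]), 1e-6)
        up = dict(base, **{name: base[name] + h})
        dn = dict(base, **{name: max(base[name] - h, 1e-300)})
        grads.append((curve(up) - curve(dn)) / (up[name] - dn[name]))
    G = np.vstack(grads)  # (n_free, n_t)
    var = np.einsum("it,ij,jt->t", G, fit.covariance, G)
    return y, np.sqrt(np.clip(var, 0.0, None))
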