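"""Primary developmental-kinetics models.

Three sigmoid descriptions of a normalized cumulative pupariation (or
eclosion) curve, each exposing the two biologically meaningful parameters:

``t_mid``
    mean developmental time — the time at which the normalized curve
    reaches 0.5;
``s_dvp``
    developmental synchrony. For the Gompertz model this is the maximum
    developmental rate (the steepest slope of the curve, 1/h); for the
    logit linearization it is the slope of the logit line (1/h); for the
    dose–response model it is a dimensionless steepness on a log10-time
    axis.

All models are fitted to curves normalized to y in [0, 1] (y0 = 0,
y_max = 1), so the fitted parameter count is two per model.

The estimators follow the scikit-learn protocol: ``fit(t, y)`` stores
fitted attributes with a trailing underscore and ``predict(t)`` evaluates
the fitted curve. ``fit_gompertz`` / ``fit_dose_response`` /
``fit_logit_linear`` are thin wrappers that accept a
:class:`~devkinetics.data_io.NormalizedCurve` and return a
:class:`PrimaryFitResult` row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from ._exceptions import DegenerateCurveError, FitConvergenceError
from .data_io import NormalizedCurve

__all__ = [
    "gompertz_predict",
    "gompertz_general",
    "gompertz_tmid",
    "gompertz_lag_from_tmid",
    "dose_response_predict",
    "logit_transform",
    "goodness_of_fit",
    "GompertzGrowth",
    "DoseResponseGrowth",
    "LogitLinearGrowth",
    "PrimaryFitResult",
    "fit_gompertz",
    "fit_dose_response",
    "fit_logit_linear",
]

_E = np.e
# offset between t_mid and the lag: (1 - ln ln 2) / (e * s_dvp)
_TMID_NUM = 1.0 - np.log(np.log(2.0))


@dataclass
class PrimaryFitResult:
    """One fitted primary model for one treatment curve."""

    model: str
    s_dvp: float
    t_mid: float
    lam: float | None  # lag time, Gompertz only
    sse: float
    r2: float | None
    nrmse: float
    n_points: int
    concentration: float | None = None
    response: str = "pupae"


def gompertz_predict(t, s_dvp, lam):
    """Normalized Gompertz curve ``exp(-exp(s_dvp * e * (lam - t) + 1))``.

    ``s_dvp`` is the maximum slope (attained where y = 1/e) and ``lam`` the
    lag time: the tangent at the inflection point crosses y = 0 at t = lam.
    Defined for all real t, increasing from 0 to 1.
    """
    if s_dvp <= 0:
        raise ValueError("s_dvp must be positive")
    t = np.asarray(t, dtype=float)
    return np.exp(-np.exp(s_dvp * _E * (lam - t) + 1.0))


def gompertz_general(t, s_dvp, lam, y0=0.0, ymax=1.0):
    """Four-parameter Gompertz curve running from ``y0`` to ``ymax``.

    Generalization retained for completeness; the analysis pipeline always
    works on normalized curves where ``y0 = 0`` and ``ymax = 1``, reducing
    to :func:`gompertz_predict`.
    """
    span = ymax - y0
    return y0 + span * np.exp(-np.exp(s_dvp / span * _E * (lam - t) + 1.0))


def gompertz_tmid(s_dvp, lam):
    """Closed-form time at which the Gompertz curve reaches 0.5.

    Setting y(t) = 1/2 and solving gives
    ``t_mid = lam + (1 - ln ln 2) / (e * s_dvp)``.
    """
    if s_dvp <= 0:
        raise ValueError("s_dvp must be positive")
    return lam + _TMID_NUM / (_E * s_dvp)


def gompertz_lag_from_tmid(s_dvp, t_mid):
    """Inverse of :func:`gompertz_tmid`: the lag implied by (s_dvp, t_mid)."""
    if s_dvp <= 0:
        raise ValueError("s_dvp must be positive")
    return t_mid - _TMID_NUM / (_E * s_dvp)


def dose_response_predict(t, s_dvp, t_mid):
    """Log-time logistic ``1 / (1 + 10**(-s_dvp * (log10 t - log10 t_mid)))``.

    The pharmacological dose–response form with time as the "dose": a
    logistic in log10(t), centred at t_mid where y = 0.5 exactly. ``s_dvp``
    is the dimensionless steepness per decade of time.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("dose-response curve is defined for t > 0 only")
    if t_mid <= 0 or s_dvp <= 0:
        raise ValueError("s_dvp and t_mid must be positive")
    return 1.0 / (1.0 + 10.0 ** (-s_dvp * (np.log10(t) - np.log10(t_mid))))


def logit_transform(curve: NormalizedCurve):
    """Logit-linearize a normalized curve: ``ln(y / (1 - y))`` per point.

    Points with y = 0 or y = 1 have no finite logit and are excluded;
    their count is returned so downstream reporting can surface it.

    Returns
    -------
    t : ndarray
        Times of the transformable points.
    y_logit : ndarray
        Logit values at those times.
    n_excluded : int
        Number of boundary points dropped.
    """
    y = np.asarray(curve.y, dtype=float)
    keep = (y > 0.0) & (y < 1.0)
    n_excluded = int(np.size(y) - np.count_nonzero(keep))
    t = np.asarray(curve.times, dtype=float)[keep]
    y_logit = np.log(y[keep] / (1.0 - y[keep]))
    if t.size < 2:
        raise DegenerateCurveError(
            f"curve at {curve.concentration} M has {t.size} interior point(s) "
            f"after excluding {n_excluded} boundary point(s); cannot regress"
        )
    return t, y_logit, n_excluded


def goodness_of_fit(observed, predicted, k=None):
    """SSE, R² and normalized RMSE of a fit.

    ``nrmse = 100 * sqrt(SSE / n) / mean(observed)`` — RMSE as a percentage
    of the observed mean. ``k`` (parameter count) is accepted for interface
    symmetry with result records but is not used by these three statistics.
    R² is reported as None with a warning when the observations are all
    equal (the total sum of squares vanishes).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must share a length >= 2")
    sse = float(np.sum((obs - pred) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        warnings.warn("observed values are constant; R^2 undefined", stacklevel=2)
        r2 = None
    else:
        r2 = 1.0 - sse / sst
    nrmse = 100.0 * np.sqrt(sse / obs.size) / obs.mean()
    return sse, r2, float(nrmse)


def _as_1d_times(X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError("t must be a 1-d array (or a single-column 2-d array)")
    return X


def _check_interior(y, where):
    if not np.any((y > 0.0) & (y < 1.0)):
        raise DegenerateCurveError(
            f"{where}: curve has no interior point (all y in {{0, 1}})"
        )


class GompertzGrowth(RegressorMixin, BaseEstimator):
    """Gompertz developmental curve fitted by bounded nonlinear least squares.

    Parameters
    ----------
    ftol : float
        Convergence tolerance on the cost (SSE/2) passed to the trust-region
        solver.
    max_nfev : int or None
        Evaluation budget for the solver.

    Attributes
    ----------
    s_dvp_ : float
        Maximum developmental rate (1/h).
    lag_ : float
        Lag time lambda (h).
    t_mid_ : float
        Mean developmental time from the closed form
        ``lag_ + (1 - ln ln 2)/(e * s_dvp_)``.
    sse_, r2_, nrmse_ : float
        Goodness-of-fit diagnostics on the training curve.
    """

    _N_PARAMS = 2

    def __init__(self, ftol=1e-12, max_nfev=None):
        self.ftol = ftol
        self.max_nfev = max_nfev

    def fit(self, X, y):
        t = _as_1d_times(X)
        y = np.asarray(y, dtype=float)
        if t.size < 4:
            raise ValueError("Gompertz fit needs at least 4 points")
        _check_interior(y, "Gompertz fit")
        order = np.argsort(t)
        t, y = t[order], y[order]

        # lag init: last time still at y == 0 (first time if the curve never is)
        zeros = np.nonzero(y == 0.0)[0]
        lam0 = t[zeros[-1]] if zeros.size else t[0]
        slopes = np.diff(y) / np.diff(t)
        s0 = max(float(slopes.max()), 1e-4)

        def resid(p):
            s, lam = p
            return np.exp(-np.exp(s * _E * (lam - t) + 1.0)) - y

        sol = least_squares(
            resid,
            x0=[s0, lam0],
            bounds=([1e-6, 0.0], [np.inf, t.max()]),
            method="trf",
            ftol=self.ftol,
            xtol=1e-12,
            gtol=1e-12,
            max_nfev=self.max_nfev,
        )
        if not sol.success:
            raise FitConvergenceError(
                f"Gompertz fit did not converge: {sol.message}", best_params=sol.x
            )
        self.s_dvp_, self.lag_ = float(sol.x[0]), float(sol.x[1])
        self.t_mid_ = float(gompertz_tmid(self.s_dvp_, self.lag_))
        self.n_points_ = t.size
        self.sse_, self.r2_, self.nrmse_ = goodness_of_fit(y, self.predict(t))
        return self

    def predict(self, X):
        t = _as_1d_times(X)
        return gompertz_predict(t, self.s_dvp_, self.lag_)


class DoseResponseGrowth(RegressorMixin, BaseEstimator):
    """Log-time logistic ("dose–response") curve fitted by least squares.

    Attributes
    ----------
    s_dvp_ : float
        Dimensionless steepness per decade of log10 time.
    t_mid_ : float
        Time at which the fitted curve crosses 0.5 (h).
    """

    _N_PARAMS = 2

    def __init__(self, ftol=1e-12, max_nfev=None):
        self.ftol = ftol
        self.max_nfev = max_nfev

    def fit(self, X, y):
        t = _as_1d_times(X)
        y = np.asarray(y, dtype=float)
        # log10(t) is undefined at t <= 0; such points sit at the flat
        # start of a developmental curve and are excluded from the fit
        pos = t > 0
        self.n_excluded_ = int(t.size - np.count_nonzero(pos))
        t, y = t[pos], y[pos]
        if t.size < 3:
            raise ValueError("dose-response fit needs at least 3 points with t > 0")
        _check_interior(y, "dose-response fit")
        order = np.argsort(t)
        t, y = t[order], y[order]

        tm0 = float(np.interp(0.5, y, t)) if y[0] < 0.5 < y[-1] else float(np.median(t))
        slopes = np.diff(y) / np.diff(t)
        # slope at midpoint of the logistic in log10 t is s*ln(10)/(4*t_mid)
        s0 = max(float(slopes.max()) * 4.0 * tm0 / np.log(10.0), 0.5)

        logt = np.log10(t)

        def resid(p):
            s, log_tm = p
            return 1.0 / (1.0 + 10.0 ** (-s * (logt - log_tm))) - y

        sol = least_squares(
            resid,
            x0=[s0, np.log10(tm0)],
            bounds=([1e-6, np.log10(t.min()) - 2.0], [np.inf, np.log10(t.max()) + 2.0]),
            method="trf",
            ftol=self.ftol,
            xtol=1e-12,
            gtol=1e-12,
            max_nfev=self.max_nfev,
        )
        if not sol.success:
            raise FitConvergenceError(
                f"dose-response fit did not converge: {sol.message}", best_params=sol.x
            )
        self.s_dvp_ = float(sol.x[0])
        self.t_mid_ = float(10.0 ** sol.x[1])
        self.n_points_ = t.size
        self.sse_, self.r2_, self.nrmse_ = goodness_of_fit(y, self.predict(t))
        return self

    def predict(self, X):
        t = _as_1d_times(X)
        return dose_response_predict(t, self.s_dvp_, self.t_mid_)


class LogitLinearGrowth(RegressorMixin, BaseEstimator):
    """Logit linearization: OLS of ln(y/(1-y)) against time.

    The fitted line ``y_logit = a*t + b`` yields ``s_dvp_ = a`` (slope,
    1/h) and ``t_mid_ = -b/a`` (x-intercept, where y crosses 0.5).
    Boundary points (y = 0 or 1) are excluded; ``n_excluded_`` records how
    many. Diagnostics are computed on the logit scale.
    """

    _N_PARAMS = 2

    def fit(self, X, y):
        t = _as_1d_times(X)
        y = np.asarray(y, dtype=float)
        curve_like = _LogitInput(t, y)
        tt, yl, n_excl = logit_transform(curve_like)
        return self.fit_transformed(tt, yl, n_excluded=n_excl)

    def fit_transformed(self, t, y_logit, *, n_excluded=0):
        """Fit directly on already logit-transformed points."""
        t = _as_1d_times(t)
        y_logit = np.asarray(y_logit, dtype=float)
        if t.size < 2 or np.unique(t).size < 2:
            raise ValueError("logit regression needs >= 2 points with distinct t")
        a, b = np.polyfit(t, y_logit, 1)
        if a <= 0:
            raise DegenerateCurveError(
                "logit slope is non-positive: curve does not develop over time"
            )
        self.s_dvp_ = float(a)
        self.intercept_ = float(b)
        self.t_mid_ = float(-b / a)
        self.n_excluded_ = int(n_excluded)
        self.n_points_ = t.size
        self.sse_, self.r2_, self.nrmse_ = goodness_of_fit(y_logit, a * t + b)
        return self

    def predict(self, X):
        """Predicted normalized response (back-transformed from the logit line)."""
        t = _as_1d_times(X)
        z = self.s_dvp_ * t + self.intercept_
        return 1.0 / (1.0 + np.exp(-z))


class _LogitInput:
    """Duck-typed minimal curve for logit_transform on raw arrays."""

    def __init__(self, times, y):
        self.times = times
        self.y = y
        self.concentration = float("nan")


def _result_from(est, model, curve: NormalizedCurve, lam=None) -> PrimaryFitResult:
    return PrimaryFitResult(
        model=model,
        s_dvp=est.s_dvp_,
        t_mid=est.t_mid_,
        lam=lam,
        sse=est.sse_,
        r2=est.r2_,
        nrmse=est.nrmse_,
        n_points=est.n_points_,
        concentration=curve.concentration,
        response=curve.response,
    )


def fit_gompertz(curve: NormalizedCurve) -> PrimaryFitResult:
    """Fit the Gompertz model to a normalized curve."""
    est = GompertzGrowth().fit(curve.times, curve.y)
    return _result_from(est, "gompertz", curve, lam=est.lag_)


def fit_dose_response(curve: NormalizedCurve) -> PrimaryFitResult:
    """Fit the dose–response (log-time logistic) model to a normalized curve."""
    est = DoseResponseGrowth().fit(curve.times, curve.y)
    return _result_from(est, "dose_response", curve)


def fit_logit_linear(curve_or_points) -> PrimaryFitResult:
    """Fit the logit linearization.

    Accepts either a :class:`NormalizedCurve` or a pre-transformed
    ``(t, y_logit)`` pair.
    """
    if isinstance(curve_or_points, NormalizedCurve):
        curve = curve_or_points
        est = LogitLinearGrowth().fit(curve.times, curve.y)
        return _result_from(est, "logit", curve)
    t, y_logit = curve_or_points
    est = LogitLinearGrowth().fit_transformed(t, y_logit)
    return PrimaryFitResult(
        model="logit",
        s_dvp=est.s_dvp_,
        t_mid=est.t_mid_,
        lam=None,
        sse=est.sse_,
        r2=est.r2_,
        nrmse=est.nrmse_,
        n_points=est.n_points_,
    )
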