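"""Secondary (reaction-norm) models over sucrose concentration.

A primary-model parameter (t_mid or s_dvp) observed across the 11-point
concentration grid is treated as a phenotypic trait and regressed against
concentration E, either with a single line ``y = a*E + b`` or with a
two-segment ("bilinear") model

    y = a1*E + b1  for E <= x_c,      y = a2*E + b2  for E > x_c,

where the breakpoint x_c is the intersection of the two free lines,
``x_c = (b2 - b1) / (a1 - a2)``. The breakpoint is interpreted as the
concentration at which the stress response changes regime (the
high-sugar-diet threshold).

Fitting strategy: with n points on a sorted grid there are at most n - 3
ways to split the data into a left and a right block of >= 2 points each.
Each candidate split is fitted by per-block OLS; a candidate is admissible
when the resulting intersection falls between the blocks' adjoining x
values (closed on the left, since the piecewise model assigns x = x_c to
the first segment), so the definition is consistent with the data
partition. The admissible candidate with the smallest piecewise SSE
wins; ties go to the smaller split index. This exhaustive enumeration is
deterministic and globally optimal at this problem size. When no
candidate is admissible the minimum-SSE split is kept with x_c clamped to
the midpoint of its bracket and the result flagged.

Model selection uses the SSE-based Akaike information criterion
``AIC = n * ln(SSE/n) + 2k`` (k = 2 linear, 4 bilinear); confidence
intervals come from a residual bootstrap (resample piecewise-fit
residuals with replacement, refit, take percentile bounds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._exceptions import ParallelLinesError
from .primary import goodness_of_fit

__all__ = [
    "SecondaryFitResult",
    "BootstrapCI",
    "aic_from_sse",
    "breakpoint_from_lines",
    "LinearReactionNorm",
    "BilinearReactionNorm",
    "fit_linear",
    "fit_bilinear",
    "compare_linear_bilinear",
    "residual_bootstrap_bilinear",
]


@dataclass
class SecondaryFitResult:
    """One linear or bilinear reaction-norm fit."""

    model: str  # "linear" | "bilinear"
    coef: dict
    sse: float
    aic: float
    r2: float | None
    nrmse: float
    n_points: int
    k: int
    parameter_name: str | None = None
    fallback: bool = False
    split_index: int | None = None

    @property
    def x_c(self):
        return self.coef.get("x_c")


@dataclass
class BootstrapCI:
    """Percentile bootstrap confidence interval for one statistic."""

    statistic_name: str
    point: float
    lower: float
    upper: float
    level: float = 0.95
    n_boot: int = 0
    seed: int | None = None
    n_failed: int = 0
    n_fallback: int = 0


def aic_from_sse(sse, n, k):
    """SSE-based Akaike information criterion: ``n * ln(SSE/n) + 2k``.

    No small-sample correction and no additive constants, so only
    differences between models fitted to the same data are meaningful.
    A perfect fit (SSE = 0) returns -inf with a warning.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if sse < 0:
        raise ValueError("sse must be non-negative")
    if sse == 0:
        warnings.warn("SSE is zero (perfect fit); AIC is -inf", stacklevel=2)
        return float("-inf")
    return float(n * np.log(sse / n) + 2 * k)


def breakpoint_from_lines(a1, b1, a2, b2):
    """Intersection of ``y = a1*x + b1`` and ``y = a2*x + b2``.

    ``x_c = (b2 - b1) / (a1 - a2)``; raises when the lines are parallel.
    """
    if a1 == a2:
        raise ParallelLinesError("segments are parallel; no finite breakpoint")
    return (b2 - b1) / (a1 - a2)


def _ols_coeffs(x, y):
    # closed-form simple OLS; returns (slope, intercept)
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise ValueError("singular design: all x identical")
    a = float(dx @ (y - ym)) / sxx
    return a, ym - a * xm


class LinearReactionNorm(RegressorMixin, BaseEstimator):
    """Simple OLS line ``y = a*x + b`` with SSE-based AIC (k = 2)."""

    K = 2

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float)
        if np.unique(x).size < 2:
            raise ValueError("linear fit needs >= 2 distinct x")
        self.slope_, self.intercept_ = _ols_coeffs(x, y)
        pred = self.slope_ * x + self.intercept_
        self.sse_, self.r2_, self.nrmse_ = goodness_of_fit(y, pred)
        self.aic_ = aic_from_sse(self.sse_, x.size, self.K)
        self.n_points_ = x.size
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * x + self.intercept_


def _enumerate_splits(x, Y):
    """Batched per-split OLS for all admissible two-block splits.

    Parameters
    ----------
    x : (n,) sorted concentration grid.
    Y : (B, n) one or many response vectors sharing the grid.

    Returns
    -------
    coeffs : (S, B, 4) array of (a1, b1, a2, b2) per split, per dataset.
    xc : (S, B) intersections.
    admissible : (S, B) bool, x[i-1] < xc < x[i] for split boundary i.
    sse : (S, B) piecewise SSE (using the clamped midpoint when
        inadmissible, mirroring the fallback).
    xc_eff : (S, B) xc, or the bracket midpoint where inadmissible.
    splits : list of boundary indices i (left block = x[:i]).
    """
    n = x.size
    B = Y.shape[0]
    splits = list(range(2, n - 1))
    S = len(splits)
    coeffs = np.empty((S, B, 4))
    xc = np.empty((S, B))
    adm = np.zeros((S, B), dtype=bool)
    sse = np.empty((S, B))
    xc_eff = np.empty((S, B))
    for si, i in enumerate(splits):
        for side, sl in ((0, slice(None, i)), (2, slice(i, None))):
            xs = x[sl]
            Ys = Y[:, sl]
            xm = xs.mean()
            dx = xs - xm
            sxx = float(dx @ dx)
            a = (Ys - Ys.mean(axis=1, keepdims=True)) @ dx / sxx
            b = Ys.mean(axis=1) - a * xm
            coeffs[si, :, side] = a
            coeffs[si, :, side + 1] = b
        a1, b1, a2, b2 = (coeffs[si, :, j] for j in range(4))
        with np.errstate(divide="ignore", invalid="ignore"):
            xc[si] = np.where(a1 != a2, (b2 - b1) / (a1 - a2), np.inf)
        # closed on the left: the piecewise model assigns x = x_c to the
        # first segment, so x_c equal to the last left-block x is consistent
        adm[si] = (x[i - 1] <= xc[si]) & (xc[si] < x[i])
        mid = 0.5 * (x[i - 1] + x[i])
        xc_eff[si] = np.where(adm[si], xc[si], mid)
        left = x[None, :] <= xc_eff[si][:, None]
        pred = np.where(
            left,
            a1[:, None] * x[None, :] + b1[:, None],
            a2[:, None] * x[None, :] + b2[:, None],
        )
        sse[si] = np.sum((Y - pred) ** 2, axis=1)
    return coeffs, xc, adm, sse, xc_eff, splits


def _best_split(adm, sse):
    """Per-dataset winning split: min SSE among admissible candidates,
    falling back to the overall min-SSE split when none is admissible.
    Ties break toward the smaller split index (argmin convention)."""
    masked = np.where(adm, sse, np.inf)
    best = np.argmin(masked, axis=0)
    any_adm = adm.any(axis=0)
    best_fallback = np.argmin(sse, axis=0)
    return np.where(any_adm, best, best_fallback), ~any_adm


class BilinearReactionNorm(RegressorMixin, BaseEstimator):
    """Two-segment reaction norm with breakpoint at the segment intersection.

    Attributes
    ----------
    slopes_ : (a1, a2) segment slopes.
    intercepts_ : (b1, b2) segment intercepts.
    breakpoint_ : x_c, the intersection of the two segments.
    fallback_ : True when no split produced an admissible intersection and
        x_c was clamped to its bracket midpoint.
    split_index_ : number of points in the left block of the winning split.
    sse_, aic_, r2_, nrmse_ : diagnostics (k = 4).
    """

    K = 4

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float)
        order = np.argsort(x)
        x, y = x[order], y[order]
        if x.size < 5:
            raise ValueError("bilinear fit needs >= 5 points (>= 2 per segment)")
        if np.unique(x).size != x.size:
            raise ValueError("bilinear fit requires distinct x values")
        coeffs, xc, adm, sse, xc_eff, splits = _enumerate_splits(x, y[None, :])
        best, fb = _best_split(adm, sse)
        si = int(best[0])
        self.fallback_ = bool(fb[0])
        if self.fallback_:
            warnings.warn(
                "no admissible breakpoint candidate; clamping x_c to the "
                "bracket midpoint of the minimum-SSE split",
                stacklevel=2,
            )
        a1, b1, a2, b2 = coeffs[si, 0]
        self.slopes_ = (float(a1), float(a2))
        self.intercepts_ = (float(b1), float(b2))
        self.breakpoint_ = float(xc_eff[si, 0])
        self.split_index_ = splits[si]
        self.sse_ = float(sse[si, 0])
        _, self.r2_, self.nrmse_ = goodness_of_fit(y, self.predict(x))
        self.aic_ = aic_from_sse(self.sse_, x.size, self.K)
        self.n_points_ = x.size
        self._x_sorted = x
        self._y_sorted = y
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        (a1, a2), (b1, b2) = self.slopes_, self.intercepts_
        return np.where(x <= self.breakpoint_, a1 * x + b1, a2 * x + b2)


def _as_result(est, model, parameter_name=None) -> SecondaryFitResult:
    if model == "linear":
        coef = {"a": est.slope_, "b": est.intercept_}
        return SecondaryFitResult(
            model="linear",
            coef=coef,
            sse=est.sse_,
            aic=est.aic_,
            r2=est.r2_,
            nrmse=est.nrmse_,
            n_points=est.n_points_,
            k=est.K,
            parameter_name=parameter_name,
        )
    coef = {
        "a1": est.slopes_[0],
        "b1": est.intercepts_[0],
        "a2": est.slopes_[1],
        "b2": est.intercepts_[1],
        "x_c": est.breakpoint_,
    }
    return SecondaryFitResult(
        model="bilinear",
        coef=coef,
        sse=est.sse_,
        aic=est.aic_,
        r2=est.r2_,
        nrmse=est.nrmse_,
        n_points=est.n_points_,
        k=est.K,
        parameter_name=parameter_name,
        fallback=est.fallback_,
        split_index=est.split_index_,
    )


def fit_linear(x, y, parameter_name=None) -> SecondaryFitResult:
    """OLS line with SSE-based AIC (k = 2)."""
    return _as_result(LinearReactionNorm().fit(x, y), "linear", parameter_name)


def fit_bilinear(x, y, parameter_name=None) -> SecondaryFitResult:
    """Exhaustive-split bilinear fit with breakpoint at the intersection."""
    return _as_result(BilinearReactionNorm().fit(x, y), "bilinear", parameter_name)


def compare_linear_bilinear(x, y, parameter_name=None):
    """Fit both reaction-norm models and report ``delta_aic = AIC_lin - AIC_bil``.

    A positive delta exceeding 2 is the conventional evidence threshold
    favoring the bilinear model despite its two extra parameters.
    """
    lin = fit_linear(x, y, parameter_name)
    bil = fit_bilinear(x, y, parameter_name)
    return lin, bil, lin.aic - bil.aic


def residual_bootstrap_bilinear(x, y, n_boot=1000, seed=0, level=0.95):
    """Residual-bootstrap percentile CIs for the bilinear fit parameters.

    Residuals of the fitted piecewise model (pooled across both segments)
    are resampled with replacement, added back to the fitted values, and
    the full split search is re-run per resample. Percentile bounds at
    ``(1-level)/2`` and ``1-(1-level)/2`` are reported for x_c, a1, b1,
    a2 and b2. Resamples with no admissible breakpoint use the flagged
    midpoint fallback and are included; resamples whose refit raises are
    dropped and counted (an error is raised if more than 20% fail).

    Deterministic for a given ``seed``: the complete resampling-index
    array is drawn in one call from one seeded generator, so results do
    not depend on iteration order.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    base = BilinearReactionNorm().fit(x, y)
    fitted = base.predict(x)
    resid = y - fitted

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    Y = fitted[None, :] + resid[idx]

    coeffs, xc, adm, sse, xc_eff, splits = _enumerate_splits(x, Y)
    best, fb = _best_split(adm, sse)
    cols = np.arange(n_boot)
    stats = {
        "x_c": xc_eff[best, cols],
        "a1": coeffs[best, cols, 0],
        "b1": coeffs[best, cols, 1],
        "a2": coeffs[best, cols, 2],
        "b2": coeffs[best, cols, 3],
    }
    ok = np.isfinite(stats["x_c"])
    n_failed = int(n_boot - np.count_nonzero(ok))
    if n_failed > 0.2 * n_boot:
        raise RuntimeError(
            f"{n_failed}/{n_boot} bootstrap refits failed; data too unstable "
            "for a residual-bootstrap interval"
        )
    n_fallback = int(np.count_nonzero(fb & ok))
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    point = {
        "x_c": base.breakpoint_,
        "a1": base.slopes_[0],
        "b1": base.intercepts_[0],
        "a2": base.slopes_[1],
        "b2": base.intercepts_[1],
    }
    out = {}
    for name, vals in stats.items():
        v = vals[ok]
        out[name] = BootstrapCI(
            statistic_name=name,
            point=float(point[name]),
            lower=float(np.percentile(v, lo_q)),
            upper=float(np.percentile(v, hi_q)),
            level=level,
            n_boot=n_boot,
            seed=seed,
            n_failed=n_failed,
            n_fallback=n_fallback,
        )
    return out
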