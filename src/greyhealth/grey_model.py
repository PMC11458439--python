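"""GM(1,1) grey forecasting: accumulation, least-squares fit, restoration and
model diagnostics.

The model fits an exponential trend to the accumulated (cumulative-sum) series
X(1) of a short positive series X(0).  With background values
``z(k) = (X(1)(k) + X(1)(k-1)) / 2`` the grey differential equation is
linearized as ``X(0)(k) = -a z(k) + u`` and (a, u) estimated by ordinary least
squares over k = 2..N.  The cumulative solution is

    X̂(1)(t) = (X(0)(1) - u/a) e^{-a (t-1)} + u/a,

so growth corresponds to a < 0; the reported ``rate`` is ``-a``, matching the
positive exponents of published fitted equations.  Restored (original-scale)
values are first differences of X̂(1), a geometric sequence with annual factor
``e^{-a}`` from t >= 2.

Adequacy is judged by the mean absolute relative in-sample error (residual
test, pass threshold 0.2) and the posterior-difference test: C = S2/S1 where
S1, S2 are the population standard deviations of the data and of the
residuals, and p is the fraction of residuals within 0.6745 * S1 of their
mean.  Both statistics are evaluated over the full window t = 1..N.  Grades
follow the conventional four-level scale (Excellent: C <= 0.35 and p >= 0.95;
Good: C <= 0.5, p >= 0.8; Qualified: C <= 0.65, p >= 0.7; else Unqualified).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .timeseries_io import MIN_FIT_POINTS, YearSeries

__all__ = [
    "GM11Design",
    "GM11Fit",
    "DiagnosticReport",
    "ago",
    "build_design",
    "fit_gm11",
    "predict_cumulative",
    "restore",
    "forecast",
    "residual_test",
    "posterior_test",
]

#: |a| below this is treated as the degenerate (linear-limit) model.
DEGENERATE_A = 1e-12

#: Residual-test pass threshold on the mean absolute relative error.
RESIDUAL_PASS = 0.2

#: Half-width multiplier of the small-error band, in data standard deviations.
SMALL_ERROR_BAND = 0.6745

GRADES = (
    ("Excellent", 0.35, 0.95),
    ("Good", 0.50, 0.80),
    ("Qualified", 0.65, 0.70),
)


@dataclass
class GM11Design:
    """Least-squares design: rows of B are (-z(k), 1), Yn is X(0)(2..N)."""

    B: np.ndarray
    Yn: np.ndarray


@dataclass
class GM11Fit:
    """Fitted GM(1,1) parameters plus in-sample reconstruction."""

    a: float
    u: float
    x0_first: float
    source: YearSeries
    fitted_cumulative: np.ndarray
    restored: np.ndarray
    residuals: np.ndarray

    @property
    def rate(self) -> float:
        """Positive exponent of the fitted equation (= -a for a growing series)."""
        return -self.a

    @property
    def coefficient(self) -> float:
        """Multiplier of the exponential term, ``X(0)(1) - u/a``."""
        return self.x0_first - self.u / self.a

    @property
    def offset(self) -> float:
        """Additive constant of the cumulative solution, ``u/a``."""
        return self.u / self.a

    @property
    def growth_factor(self) -> float:
        """Annual ratio of consecutive restored values, ``e^(-a)``."""
        return float(np.exp(-self.a))


@dataclass
class DiagnosticReport:
    rel_errors: np.ndarray
    mean_rel_error: float
    S1: float
    S2: float
    C: float
    p: float
    grade: str
    residual_test_pass: bool


def ago(series: YearSeries) -> np.ndarray:
    """Accumulated generating operation: X(1)(k) = sum of X(0)(1..k)."""
    return np.cumsum(series.values)


def build_design(cumulative: np.ndarray, original: YearSeries) -> GM11Design:
    """Assemble B and Yn from the cumulative and original sequences."""
    n = len(original)
    if n < MIN_FIT_POINTS:
        raise ValueError(
            f"GM(1,1) needs at least {MIN_FIT_POINTS} points, got {n}"
        )
    x1 = np.asarray(cumulative, dtype=float)
    z = (x1[1:] + x1[:-1]) / 2.0
    B = np.column_stack([-z, np.ones(n - 1)])
    return GM11Design(B=B, Yn=original.values[1:].copy())


def _class_ratio_check(x0: np.ndarray) -> None:
    # Quasi-smoothness applicability band for the class ratios x0(k-1)/x0(k).
    n = len(x0)
    lo, hi = np.exp(-2.0 / (n + 1)), np.exp(2.0 / (n + 1))
    sigma = x0[:-1] / x0[1:]
    if np.any(sigma < lo) | np.any(sigma > hi):
        warnings.warn(
            "class ratios leave the quasi-smoothness band "
            f"[{lo:.4f}, {hi:.4f}]; GM(1,1) may fit poorly",
            stacklevel=3,
        )


def fit_gm11(series: YearSeries) -> GM11Fit:
    """Fit GM(1,1) to a positive series of at least four points.

    (a, u) is the OLS solution of Yn ~ B (a, u)^T via numpy's least-squares
    solver; the fitted cumulative and restored sequences are populated over
    the sample window t = 1..N.
    """
    x0 = series.values
    _class_ratio_check(x0)
    design = build_design(ago(series), series)
    (a, u), *_ = np.linalg.lstsq(design.B, design.Yn, rcond=None)
    n = len(x0)
    t = np.arange(1, n + 1)
    fitted_cum = _cumulative(float(a), float(u), x0[0], t)
    restored = np.empty(n)
    restored[0] = x0[0]
    restored[1:] = np.diff(fitted_cum)
    return GM11Fit(
        a=float(a),
        u=float(u),
        x0_first=float(x0[0]),
        source=series,
        fitted_cumulative=fitted_cum,
        restored=restored,
        residuals=x0 - restored,
    )


def _cumulative(a: float, u: float, x0_first: float, t: np.ndarray) -> np.ndarray:
    if abs(a) < DEGENERATE_A:
        # analytic a -> 0 limit: linear accumulation, constant restored value u
        out = x0_first + u * (t - 1)
    else:
        out = (x0_first - u / a) * np.exp(-a * (t - 1)) + u / a
    # anchor t=1 exactly at the first observation (the formula only gets
    # there up to roundoff)
    return np.where(t == 1, x0_first, out)


def predict_cumulative(fit: GM11Fit, t) -> np.ndarray | float:
    """Evaluate the cumulative solution X̂(1) at index t (t=1 is the first
    sample year and returns X(0)(1) exactly)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 1):
        raise ValueError("time index t must be >= 1")
    out = _cumulative(fit.a, fit.u, fit.x0_first, t_arr)
    return float(out) if np.isscalar(t) else out


def restore(fit: GM11Fit, t) -> np.ndarray | float:
    """Original-scale value at index t: X(0)(1) at t=1, else the first
    difference of the cumulative solution."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 1):
        raise ValueError("time index t must be >= 1")
    vals = predict_cumulative(fit, t_arr) - _cumulative(
        fit.a, fit.u, fit.x0_first, t_arr - 1
    )
    vals = np.where(t_arr == 1, fit.x0_first, vals)
    return float(vals[0]) if np.isscalar(t) else vals


def forecast(fit: GM11Fit, horizon: int) -> YearSeries:
    """Out-of-sample restored values for t = N+1 .. N+horizon, year-labelled
    by extending the source calendar."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    n = len(fit.source)
    t = np.arange(n + 1, n + horizon + 1)
    last_year = fit.source.years[-1]
    years = [last_year + h for h in range(1, horizon + 1)]
    return YearSeries(f"{fit.source.name}_forecast", years, restore(fit, t))


def residual_test(fit: GM11Fit) -> tuple[np.ndarray, float, bool]:
    """Per-year absolute relative errors, their mean, and the pass flag."""
    x0 = fit.source.values
    if np.any(x0 == 0):
        raise ValueError("relative errors undefined for zero observations")
    rel = np.abs(fit.residuals) / x0
    mean = float(rel.mean())
    return rel, mean, mean <= RESIDUAL_PASS


def posterior_test(fit: GM11Fit) -> DiagnosticReport:
    """Posterior-difference diagnostics (C, p) and the model grade."""
    x0 = fit.source.values
    eps = fit.residuals
    S1 = float(np.std(x0))
    if S1 == 0:
        raise ValueError("degenerate constant series: S1 is zero")
    S2 = float(np.std(eps))
    C = S2 / S1
    p = float(np.mean(np.abs(eps - eps.mean()) < SMALL_ERROR_BAND * S1))
    grade = "Unqualified"
    for name, c_max, p_min in GRADES:
        if C <= c_max and p >= p_min:
            grade = name
            break
    rel, mean_rel, passed = residual_test(fit)
    return DiagnosticReport(
        rel_errors=rel,
        mean_rel_error=mean_rel,
        S1=S1,
        S2=S2,
        C=C,
        p=p,
        grade=grade,
        residual_test_pass=passed,
    )
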