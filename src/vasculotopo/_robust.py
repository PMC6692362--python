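"""Power-law fitting helpers shared across topology and community metrics.

All exponent estimates in this package are slopes of straight-line fits on
log10-log10 coordinates, either ordinary least squares (degree distribution
tails) or iteratively reweighted least squares with Tukey bisquare weights
(per-node / per-community scatter, where heavy-tailed residuals are the norm).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning


@dataclass(frozen=True)
class FitResult:
    """Outcome of a log-log straight-line fit.

    ``exponent`` is the slope (sign as fitted: decaying relations such as
    P(k) ~ k^-gamma are reported with the positive convention by the calling
    code). ``ok`` is False when the support was too thin to fit.
    """

    exponent: float
    intercept: float
    stderr: float
    r_squared: float
    n_support: int
    ok: bool = True
    support_fraction: float = float("nan")  # share of eligible points fitted

    def __bool__(self) -> bool:  # truthiness == fit validity
        return self.ok


def _failed(n: int) -> FitResult:
    return FitResult(np.nan, np.nan, np.nan, np.nan, n, ok=False)


def loglog_lsq(x, y, min_support: int = 3) -> FitResult:
    """Ordinary least squares of log10(y) on log10(x).

    Points with non-positive x or y are dropped (zero frequencies carry no
    information on log axes).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = (x > 0) & (y > 0)
    x, y = np.log10(x[keep]), np.log10(y[keep])
    if x.size < min_support or np.unique(x).size < min_support:
        return _failed(int(x.size))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(x.size - 2, 1)
    sxx = float(((x - x.mean()) ** 2).sum())
    stderr = float(np.sqrt(ss_res / dof / sxx)) if sxx > 0 else np.nan
    return FitResult(float(slope), float(intercept), stderr, r2, int(x.size))


def robust_loglog_fit(x, y, min_support: int = 5) -> FitResult:
    """Bisquare-weighted (IRLS) straight-line fit on log10-log10 axes."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = (x > 0) & (y > 0)
    x, y = np.log10(x[keep]), np.log10(y[keep])
    if x.size >= min_support and np.unique(x).size == 1 and np.unique(y).size == 1:
        # degenerate but consistent: a constant relation has zero slope
        return FitResult(0.0, float(y[0]), 0.0, 1.0, int(x.size))
    if x.size < min_support or np.unique(x).size < 2:
        return _failed(int(x.size))
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        # perfect fits on synthetic data drive the IRLS scale to zero
        warnings.simplefilter("ignore", ConvergenceWarning)
        fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight()).fit()
    slope = float(fit.params[1])
    intercept = float(fit.params[0])
    stderr = float(fit.bse[1])
    yhat = fit.fittedvalues
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(((y - yhat) ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return FitResult(slope, intercept, stderr, r2, int(x.size))
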