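"""Biomarker-vs-pseudo-time curve fitting.

Two fits mirror standard progression-curve practice: an ordinary cubic
polynomial for the scatter trend, and a four-parameter logistic onset model

    y(t) = lower + (upper - lower) / (1 + exp(-rate * (t - midpoint)))

fitted by nonlinear least squares with multi-start initialization, reporting
a pseudo-R^2 of 1 - SSE/SST.  The fitted midpoints order regions by onset
along pseudo-time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit


@dataclass
class LogisticFit:
    lower: float = np.nan
    upper: float = np.nan
    midpoint: float = np.nan
    rate: float = np.nan
    pseudo_r2: float = np.nan
    converged: bool = False
    note: str = ""


def logistic4(t, lower, upper, midpoint, rate):
    return lower + (upper - lower) * expit(rate * (t - midpoint))


def fit_logistic_curve(t, y) -> LogisticFit:
    """Least-squares 4-parameter logistic fit of y against pseudo-time t.

    Multi-start: midpoint initialized at the t quartiles, rate sign from the
    t-y correlation.  Non-convergence is reported (converged=False, note),
    never silent.  A constant y is rejected with a flat-signal note.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be 1-D arrays of equal length")
    if len(t) < 8:
        raise ValueError("need at least 8 points")
    if t.min() < 0 or t.max() > 100:
        raise ValueError("t must lie within [0, 100]")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst <= 1e-20 * max(1.0, float(np.abs(y).max()) ** 2):
        return LogisticFit(converged=False, note="flat signal: constant y, fit rejected")

    t_span = max(t.max() - t.min(), 1e-9)
    corr_sign = 1.0 if np.corrcoef(t, y)[0, 1] >= 0 else -1.0
    rate0 = corr_sign * 4.0 / t_span
    y_lo, y_hi = float(np.percentile(y, 5)), float(np.percentile(y, 95))
    if corr_sign < 0:
        y_lo, y_hi = y_hi, y_lo

    # identifiability guards: the midpoint is only meaningful inside the
    # observed pseudo-time window, and the asymptotes are tied to the observed
    # response range (as in dose-response practice); a transition truncated at
    # the window edge would otherwise drive midpoint and plateaus to absurd
    # extrapolated values
    y_rng = max(float(y.max() - y.min()), 1e-9)
    lo_b = [y.min() - 0.1 * y_rng, y.min() - 0.1 * y_rng, float(t.min()), -5.0]
    hi_b = [y.max() + 0.1 * y_rng, y.max() + 0.1 * y_rng, float(t.max()), 5.0]

    best = None
    for q in (25.0, 50.0, 75.0):
        p0 = [y_lo, y_hi, float(np.percentile(t, q)), rate0]
        p0 = [float(np.clip(v, lo, hi)) for v, lo, hi in zip(p0, lo_b, hi_b)]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(logistic4, t, y, p0=p0,
                                    bounds=(lo_b, hi_b), maxfev=20000)
        except RuntimeError:
            continue
        sse = float(((y - logistic4(t, *popt)) ** 2).sum())
        if np.isfinite(sse) and (best is None or sse < best[0]):
            best = (sse, popt)
    if best is None:
        return LogisticFit(converged=False, note="nonlinear least squares did not converge")
    sse, (lo, up, mid, rate) = best
    if up < lo:  # equivalent reparameterization with positive span
        lo, up, rate = up, lo, -rate
    return LogisticFit(lower=float(lo), upper=float(up), midpoint=float(mid),
                       rate=float(rate), pseudo_r2=float(1.0 - sse / sst),
                       converged=True)


@dataclass
class CubicFit:
    coefficients: np.ndarray = field(default_factory=lambda: np.zeros(4))  # ascending
    rss: float = np.nan

    def predict(self, t):
        return np.polynomial.polynomial.polyval(np.asarray(t, dtype=float),
                                                self.coefficients)


def fit_cubic(t, y) -> CubicFit:
    """Ordinary least-squares degree-3 polynomial fit."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 points")
    if len(np.unique(t)) < 4:
        raise ValueError("need at least 4 distinct t values (rank-deficient design)")
    # numpy's Polynomial.fit works on a scaled domain for conditioning
    poly = np.polynomial.Polynomial.fit(t, y, deg=3).convert()
    coefs = np.zeros(4)
    coefs[:len(poly.coef)] = poly.coef
    rss = float(((y - np.polynomial.polynomial.polyval(t, coefs)) ** 2).sum())
    return CubicFit(coefficients=coefs, rss=rss)


def onset_ordering(fits: dict) -> list[str]:
    """Order series names ascending by fitted logistic midpoint.

    Non-converged fits are excluded with a warning; midpoint ties break
    alphabetically.
    """
    usable = {}
    for name, fit in fits.items():
        if not fit.converged:
            warnings.warn(f"excluding non-converged fit for {name!r} ({fit.note})")
            continue
        usable[name] = fit.midpoint
    return sorted(usable, key=lambda n: (usable[n], n))
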