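"""Regime-shift detection: sequential t-test break points and ARIMA forecasts.

:func:`stars_detect` implements the sequential t-test analysis of regime
shifts (STARS): a candidate shift is declared when a value departs from the
current regime mean by more than the critical difference implied by a
two-sided t-test at level ``alpha`` between two regimes of ``cutoff``
points, and is confirmed only if the regime-shift index - a cumulative
Huber-weighted sum of normalised exceedances over the following ``cutoff``
points - stays positive.  Regime means are Huber-weighted throughout, so
single outliers neither trigger nor drag a regime.  An optional AR(1)
prewhitening step removes red-noise autocorrelation before testing, since
lag-one persistence inflates apparent mean shifts.

:func:`fit_forecast` is thin plumbing around statsmodels' ARIMA: it picks
the differencing order with an augmented Dickey-Fuller test, selects
(p, q) by AIC over a small grid, and returns point forecasts with 95%
prediction intervals beyond a chosen split date - the tool used to ask
whether post-transition observations fall outside what the pre-transition
series predicts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["BreakpointResult", "ForecastResult", "stars_detect", "fit_forecast"]


def huber_mean(
    x: np.ndarray, scale: float, huber: float = 1.0, n_iter: int = 10
) -> float:
    """Huber-weighted mean: weight 1 within ``huber`` scale units, 1/|z| beyond.

    With ``huber -> inf`` every weight is 1 and the ordinary mean is
    recovered.
    """
    x = np.asarray(x, dtype=float)
    if scale <= 0 or not np.isfinite(huber):
        return float(np.mean(x))
    m = float(np.mean(x))
    for _ in range(n_iter):
        z = np.abs(x - m) / scale
        w = np.where(z <= huber, 1.0, np.where(z > 0, huber / np.maximum(z, 1e-12), 1.0))
        new = float(np.sum(w * x) / np.sum(w))
        if abs(new - m) < 1e-12:
            break
        m = new
    return m


def _ar1_coefficient(x: np.ndarray, m: int = 10) -> float:
    """Shift-robust AR(1) coefficient via subsampling.

    A lag-one autocorrelation computed on the whole series is badly
    inflated by the very mean shifts the detector is looking for.  Instead
    the coefficient is the average of bias-corrected (Marriott-Pope)
    lag-one estimates over consecutive blocks of ``m`` points: a sustained
    shift contaminates only the block containing it, while each block is
    internally quasi-stationary.  Negative estimates are clipped to zero
    (prewhitening is only needed against red noise).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < m or m < 5:
        return 0.0
    vals = []
    for start in range(0, len(x) - m + 1, m):
        block = x[start : start + m]
        bc = block - block.mean()
        denom = float(np.sum(bc**2))
        if denom <= 0:
            continue
        r1 = float(np.sum(bc[1:] * bc[:-1]) / denom)
        vals.append((r1 * (m - 1) + 1.0) / (m - 4))
    if len(vals) < 2:
        # a single block cannot be cross-checked against its neighbours and
        # may sit astride the very shift being sought; skip prewhitening
        return 0.0
    if len(vals) >= 3:
        # a block astride a mean shift inflates its estimate; drop the largest
        vals = sorted(vals)[:-1]
    return float(np.clip(np.mean(vals), 0.0, 0.95))


@dataclass
class BreakpointResult:
    """Detected regime shifts on a dated series.

    ``breaks`` are indices of the first point of each new regime (strictly
    increasing); ``break_dates`` the corresponding dates; ``regime_means``
    one Huber-weighted mean per regime (one more than breaks); ``rsi`` the
    regime-shift index that confirmed each break; ``ar1`` the prewhitening
    coefficient actually used (0 when prewhitening was off or unnecessary).
    """

    breaks: list[int]
    break_dates: list[float]
    regime_means: list[float]
    rsi: list[float]
    ar1: float = 0.0
    step_means: np.ndarray | None = field(default=None, repr=False)


def _stars_core(
    z: np.ndarray, alpha: float, cutoff: int, huber: float
) -> tuple[list[int], list[float]]:
    """Sequential detection on a (possibly prewhitened) series."""
    n = len(z)
    lng = cutoff
    # critical difference between two regime means of `cutoff` points, using
    # the average within-window variance as the common variance estimate
    win_vars = [np.var(z[i : i + lng], ddof=1) for i in range(n - lng + 1)]
    sigma2 = float(np.mean(win_vars))
    sigma = np.sqrt(sigma2) if sigma2 > 0 else 0.0
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df=2 * lng - 2)
    diff = t_crit * np.sqrt(2.0 * sigma2 / lng)

    breaks: list[int] = []
    rsi_values: list[float] = []
    regime_start = 0
    mean = huber_mean(z[:lng], sigma, huber)
    j = lng
    while j < n:
        dev = z[j] - mean
        if abs(dev) > diff and diff > 0:
            direction = np.sign(dev)
            level = mean + direction * diff
            # confirmation: cumulative Huber-weighted regime-shift index over
            # the next `cutoff` points (truncated at the series end) must
            # never dip below zero
            rsi = 0.0
            confirmed = True
            for i in range(j, min(j + lng, n)):
                zdev = direction * (z[i] - level)
                w = 1.0
                if sigma > 0:
                    zz = abs(z[i] - level) / sigma
                    if zz > huber and np.isfinite(huber):
                        w = huber / zz
                rsi += w * zdev / (lng * sigma if sigma > 0 else 1.0)
                if rsi < 0:
                    confirmed = False
                    break
            if confirmed:
                breaks.append(j)
                rsi_values.append(rsi)
                regime_start = j
                mean = huber_mean(z[j : j + lng], sigma, huber)
                j += 1
                continue
        # no confirmed shift: absorb the point into the current regime (the
        # Huber weight keeps an unconfirmed excursion from dragging the mean)
        mean = huber_mean(z[regime_start : j + 1], sigma, huber)
        j += 1
    return breaks, rsi_values


def stars_detect(
    values: np.ndarray,
    dates: np.ndarray | None = None,
    alpha: float = 0.05,
    cutoff: int = 5,
    huber: float = 1.0,
    prewhiten: bool = True,
) -> BreakpointResult:
    """Sequential t-test regime-shift detection.

    Parameters follow the standard STARS settings: significance level
    ``alpha``, minimum regime length ``cutoff`` (a shift must be sustained
    through at least this many points), and ``huber`` weight parameter for
    outlier down-weighting.  ``prewhiten`` removes an estimated AR(1)
    component before testing.  Regime means are reported on the original
    scale regardless of prewhitening.
    """
    x = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    n = len(x)
    if n <= 2 * cutoff:
        raise ValueError(f"series of {n} points too short for cutoff {cutoff}")
    if dates is None:
        dates_arr = np.arange(n, dtype=float)
    else:
        dates_arr = np.asarray(dates, dtype=float)
        if len(dates_arr) != n:
            raise ValueError("dates length must match values")

    phi = _ar1_coefficient(x) if prewhiten else 0.0
    if phi > 0.05:
        z = np.empty(n)
        z[0] = x[0] * (1.0 - phi)
        z[1:] = x[1:] - phi * x[:-1]
    else:
        phi = 0.0
        z = x

    breaks, rsi_values = _stars_core(z, alpha, cutoff, huber)

    # regime means on the original scale
    edges = [0] + breaks + [n]
    scale = float(np.std(x, ddof=1))
    regime_means = [
        huber_mean(x[a:b], scale, huber) for a, b in zip(edges[:-1], edges[1:])
    ]
    step = np.empty(n)
    for mean_val, a, b in zip(regime_means, edges[:-1], edges[1:]):
        step[a:b] = mean_val
    return BreakpointResult(
        breaks=breaks,
        break_dates=[float(dates_arr[b]) for b in breaks],
        regime_means=regime_means,
        rsi=rsi_values,
        ar1=phi,
        step_means=step,
    )


@dataclass
class ForecastResult:
    """ARIMA(p, d, q) forecast with 95% prediction intervals."""

    order: tuple[int, int, int]
    forecast: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    aic: float

    def __post_init__(self) -> None:
        if np.any(self.lower > self.forecast) or np.any(self.upper < self.forecast):
            raise ValueError("prediction interval must contain the point forecast")

    def exceedance(self, actual: np.ndarray) -> float:
        """Fraction of observed values outside the 95% prediction interval.

        A large exceedance on post-split data is consistent with a
        transition to a state the pre-split model cannot explain.
        """
        a = np.asarray(actual, dtype=float)
        k = min(len(a), len(self.forecast))
        if k == 0:
            return 0.0
        out = (a[:k] < self.lower[:k]) | (a[:k] > self.upper[:k])
        return float(np.mean(out))


def fit_forecast(
    values: np.ndarray,
    dates: np.ndarray | None = None,
    split: float | int | None = None,
    horizon: int = 10,
    max_p: int = 2,
    max_q: int = 2,
) -> ForecastResult:
    """Order-selected ARIMA forecast beyond a split point.

    The pre-split segment (by date when ``dates`` given, else by index;
    ``None`` uses the whole series) must hold at least 10 points.  The
    differencing order d is 0 when an augmented Dickey-Fuller test rejects
    a unit root at the 5% level, else 1; (p, q) are then chosen by AIC over
    a small grid.  Delegates the fits to statsmodels.
    """
    from statsmodels.tools.sm_exceptions import ConvergenceWarning
    from statsmodels.tsa.arima.model import ARIMA
    from statsmodels.tsa.stattools import adfuller

    x = np.asarray(values, dtype=float)
    if dates is not None:
        dates = np.asarray(dates, dtype=float)
        if len(dates) != len(x):
            raise ValueError("dates length must match values")
    if split is None:
        train = x
    elif dates is not None:
        train = x[dates <= float(split)]
    else:
        train = x[: int(split)]
    if len(train) < 10:
        raise ValueError(f"pre-split segment has {len(train)} < 10 points")

    try:
        adf_p = adfuller(train, autolag="AIC")[1]
    except Exception:
        adf_p = 1.0
    d = 0 if adf_p < 0.05 else 1

    best: tuple[float, tuple[int, int, int], object] | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        warnings.simplefilter("ignore", category=UserWarning)
        for p in range(max_p + 1):
            for q in range(max_q + 1):
                try:
                    fit = ARIMA(train, order=(p, d, q)).fit()
                except Exception:
                    continue
                if best is None or fit.aic < best[0]:
                    best = (fit.aic, (p, d, q), fit)
    if best is None:
        raise RuntimeError("every candidate ARIMA fit failed (non-stationary input?)")
    aic, order, fit = best
    pred = fit.get_forecast(steps=horizon)
    ci = pred.conf_int(alpha=0.05)
    ci = np.asarray(ci, dtype=float)
    return ForecastResult(
        order=order,
        forecast=np.asarray(pred.predicted_mean, dtype=float),
        lower=ci[:, 0],
        upper=ci[:, 1],
        aic=float(aic),
    )
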