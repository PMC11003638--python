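"""Similarity metrics and group statistics.

Rolling Pearson correlation in short overlapping windows (values attached at
the window start), fixed-latency amplitude extraction, a sign-flip paired
permutation test, and the one-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import ValidationError
from .geometry import EvokedPotential


@dataclass
class RollingCorrSeries:
    """Windowed Pearson correlations; NaN marks zero-variance windows."""

    anchor_times: np.ndarray  # ms, window start per value
    values: np.ndarray  # Pearson r, NaN where undefined
    window: float  # ms
    step: float  # ms

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return np.nan
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def rolling_correlation(
    a: np.ndarray, b: np.ndarray, times: np.ndarray, window: float, step: float
) -> RollingCorrSeries:
    """Pearson r of ``a`` vs ``b`` in [t, t + window) sliding by ``step``.

    Both traces share the (uniform) time axis ``times``.  Each value is
    attached at the window start; windows extending past the trace end are
    omitted.  Zero-variance windows yield NaN, never an exception.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    times = np.asarray(times, dtype=float)
    if a.shape != b.shape or a.shape != times.shape:
        raise ValidationError("traces and time axis must share one shape")
    dt = times[1] - times[0]
    wlen = int(round(window / dt))
    if wlen < 3:
        raise ValidationError("window must span at least 3 samples")
    slen = max(1, int(round(step / dt)))
    anchors, values = [], []
    start = 0
    while start + wlen <= times.size:
        sl = slice(start, start + wlen)
        anchors.append(times[start])
        values.append(_pearson(a[sl], b[sl]))
        start += slen
    return RollingCorrSeries(
        anchor_times=np.asarray(anchors),
        values=np.asarray(values),
        window=window,
        step=step,
    )


def rolling_correlation_multi(
    a: np.ndarray, b: np.ndarray, times: np.ndarray, window: float, step: float
) -> RollingCorrSeries:
    """Rolling Pearson correlation of two multichannel arrays.

    ``a`` and ``b`` are (channels, T); each window pools all channels and
    window samples into one Pearson computation, so spatial structure
    contributes to the correlation alongside the temporal course.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    times = np.asarray(times, dtype=float)
    if a.shape != b.shape or a.shape[1] != times.size:
        raise ValidationError("arrays must share shape (channels, n_times)")
    dt = times[1] - times[0]
    wlen = int(round(window / dt))
    if wlen < 3:
        raise ValidationError("window must span at least 3 samples")
    slen = max(1, int(round(step / dt)))
    anchors, values = [], []
    start = 0
    while start + wlen <= times.size:
        sl = slice(start, start + wlen)
        anchors.append(times[start])
        values.append(_pearson(a[:, sl].ravel(), b[:, sl].ravel()))
        start += slen
    return RollingCorrSeries(
        anchor_times=np.asarray(anchors),
        values=np.asarray(values),
        window=window,
        step=step,
    )


def amplitude_at(ep: EvokedPotential, channel, t: float) -> float:
    """Potential (mV) of ``channel`` at the sample nearest to ``t`` ms.

    Ties between two equally near samples resolve toward the earlier one.
    """
    if t < ep.times[0] or t > ep.times[-1]:
        raise ValidationError(f"t={t} ms outside the EP time range")
    idx = int(np.argmin(np.abs(ep.times - t)))  # argmin -> first, i.e. earlier
    return float(ep.trace(channel)[idx])


def paired_permutation_test(
    x, y, n_perm: int = 10000, seed: int | None = None, alternative: str = "two-sided"
) -> float:
    """Sign-flip permutation test on paired differences; statistic mean(x - y).

    When 2^n <= n_perm all sign patterns are enumerated and the p-value is
    exact; otherwise ``n_perm`` random sign flips are drawn and the add-one
    estimator p = (1 + hits) / (1 + n_perm) is used, so p > 0 always.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValidationError("x and y must be equal-length 1-D arrays with n >= 2")
    d = x - y
    n = d.size
    t_obs = d.mean()

    def _extreme(t_null: np.ndarray) -> np.ndarray:
        if alternative == "two-sided":
            return np.abs(t_null) >= abs(t_obs) - 1e-12 * max(abs(t_obs), 1.0)
        if alternative == "greater":
            return t_null >= t_obs - 1e-12 * max(abs(t_obs), 1.0)
        if alternative == "less":
            return t_null <= t_obs + 1e-12 * max(abs(t_obs), 1.0)
        raise ValidationError(f"unknown alternative {alternative!r}")

    if 2**n <= n_perm:
        signs = np.array(
            [[1 if (k >> i) & 1 else -1 for i in range(n)] for k in range(2**n)]
        )
        t_null = (signs * d).mean(axis=1)
        return float(np.count_nonzero(_extreme(t_null)) / 2**n)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_null = (signs * d).mean(axis=1)
    return float((1 + np.count_nonzero(_extreme(t_null))) / (1 + n_perm))


def one_sample_t(x, mu0: float = 0.0) -> tuple[float, float]:
    """One-sample t statistic against ``mu0`` with two-sided p (df = n - 1)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("x must be a 1-D array with n >= 2")
    if np.ptp(x) == 0.0:
        raise ValidationError("one-sample t-test undefined for zero-variance data")
    res = sps.ttest_1samp(x, popmean=mu0)
    return float(res.statistic), float(res.pvalue)


def group_rolling_correlation(series_list) -> RollingCorrSeries:
    """Average rolling-correlation series across subjects.

    Undefined (NaN) windows are excluded from the mean per anchor; anchors
    undefined in every subject stay NaN.
    """
    if not series_list:
        raise ValidationError("need at least one series")
    anchors = series_list[0].anchor_times
    for s in series_list[1:]:
        if not np.allclose(s.anchor_times, anchors):
            raise ValidationError("series must share anchor times")
    stacked = np.vstack([s.values for s in series_list])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stacked, axis=0)
    return RollingCorrSeries(
        anchor_times=anchors,
        values=mean,
        window=series_list[0].window,
        step=series_list[0].step,
    )
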