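"""Temporal cross-correlation of marker and geometry dynamics.

Rates of change are taken over ~25 s baselines (avoiding correlated
localization error), z-scored, and cross-correlated with the unbiased
estimator (lag-k sum divided by N - |k|). The temporal lag between two
markers is the centroid of the contiguous positive-correlation region
containing the global maximum, which is robust to peak discretization at
coarse frame intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import displacement_rate

__all__ = [
    "XcorrResult",
    "rate_of_change",
    "normalized_xcorr",
    "average_xcorr",
    "lag_from_peak_centroid",
    "intensity_area_xcorr",
]


@dataclass
class XcorrResult:
    lags_s: np.ndarray
    corr: np.ndarray
    n_series: int = 1
    sem: np.ndarray | None = None

    @property
    def peak_lag_s(self) -> float:
        return float(self.lags_s[int(np.argmax(self.corr))])


def rate_of_change(series: np.ndarray, frame_interval: float,
                   window_s: float = 25.0) -> np.ndarray:
    """Finite-difference rate over ~25 s, in units per second."""
    return displacement_rate(series, frame_interval, window_s, per_minute=False)


def normalized_xcorr(a: np.ndarray, b: np.ndarray, frame_interval: float,
                     max_lag_s: float = 60.0) -> XcorrResult:
    """Unbiased cross-correlation of z-scored series.

    corr(k) = sum_t a(t) b(t + k) / (N - |k|); positive lag means ``b``
    lags behind ``a`` (b shifted later matches a). Requires both series
    finite on a common support; sd-zero series are rejected.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = len(a)
    max_lag = int(round(max_lag_s / frame_interval))
    if n < 2 * max_lag:
        raise ValueError("overlap shorter than twice the maximum lag")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance series")
    a = (a - a.mean()) / np.std(a)
    b = (b - b.mean()) / np.std(b)
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.empty(len(lags))
    for i, k in enumerate(lags):
        if k >= 0:
            corr[i] = np.dot(a[: n - k], b[k:]) / (n - k)
        else:
            corr[i] = np.dot(a[-k:], b[: n + k]) / (n + k)
    return XcorrResult(lags_s=lags * frame_interval, corr=corr)


def average_xcorr(results: list[XcorrResult]) -> XcorrResult:
    """Equal-weight average of per-pair correlation functions (population
    averaging over vertices/cells, not pooled concatenation)."""
    if not results:
        raise ValueError("no correlation functions to average")
    lags = results[0].lags_s
    mat = np.vstack([r.corr for r in results])
    sem = mat.std(axis=0) / np.sqrt(len(results)) if len(results) > 1 else None
    return XcorrResult(lags_s=lags, corr=mat.mean(axis=0),
                       n_series=len(results), sem=sem)


def lag_from_peak_centroid(result: XcorrResult) -> float:
    """Lag estimate: centroid of the contiguous positive region containing
    the global maximum. NaN (undefined) when no positive region exists."""
    c = result.corr
    k = int(np.argmax(c))
    if c[k] <= 0:
        return np.nan
    lo = k
    while lo > 0 and c[lo - 1] > 0:
        lo -= 1
    hi = k
    while hi < len(c) - 1 and c[hi + 1] > 0:
        hi += 1
    w = c[lo:hi + 1]
    return float(np.sum(result.lags_s[lo:hi + 1] * w) / np.sum(w))


def intensity_area_xcorr(
    ratio_traces: dict[int, np.ndarray],
    area_traces: dict[int, np.ndarray],
    vertex_cells: dict[int, list[int]],
    frame_interval: float,
    window_s: float = 25.0,
    max_lag_s: float = 60.0,
) -> XcorrResult:
    """Cross-correlation of vertex intensity-ratio rate vs owning-cell area
    rate, averaged over vertex-cell assignments.

    Negative zero-lag correlation means intensity rises while area falls
    (recruitment during contraction).
    """
    results = []
    for v, ratio in ratio_traces.items():
        for c in vertex_cells.get(v, []):
            if c not in area_traces:
                continue
            ra = rate_of_change(ratio, frame_interval, window_s)
            rb = rate_of_change(area_traces[c], frame_interval, window_s)
            try:
                results.append(normalized_xcorr(ra, rb, frame_interval, max_lag_s))
            except ValueError:
                continue
    return average_xcorr(results)
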