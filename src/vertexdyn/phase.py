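"""Instantaneous phase and amplitude of cell-area oscillations.

The area series is detrended by subtracting a long-timescale Gaussian
filtered copy (sigma = 180 s), smoothed with a third-order Savitzky-Golay
filter of ~45 s frame size, and embedded in the plane spanned by the signal
and its frequency-normalized derivative. The instantaneous phase is the
angle of the trajectory about the center of the local osculating circle
(algebraic circle fits over a sliding half-period window); the circle radius
is the instantaneous amplitude. This construction tolerates non-zero and
slowly varying signal means better than the plain analytic (Hilbert) signal,
which is kept as a cross-checking fallback.

Phase convention: 0 deg at area minima, +-180 deg at maxima; -180..0 is the
contraction (peak-to-trough) half-cycle, 0..180 the expansion half-cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "PhaseTrace",
    "detrend",
    "smooth",
    "sg_window_frames",
    "dominant_angular_frequency",
    "instantaneous_phase_amplitude",
    "phase_from_area",
    "segment_cycles",
]


@dataclass
class PhaseTrace:
    """Phase/amplitude series for one cell."""

    phase_deg: np.ndarray        # wrapped to (-180, 180]
    unwrapped_deg: np.ndarray
    amplitude: np.ndarray        # osculating radius, signal units
    detrended: np.ndarray
    smoothed: np.ndarray
    frame_interval: float
    cycle: np.ndarray | None = None  # integer cycle index per frame
    valid: np.ndarray | None = None

    def __post_init__(self):
        if self.cycle is None:
            self.cycle = np.floor((self.unwrapped_deg + 180.0) / 360.0).astype(int)
        if self.valid is None:
            self.valid = np.ones(len(self.phase_deg), dtype=bool)


def detrend(series: np.ndarray, frame_interval: float,
            sigma_s: float = 180.0) -> np.ndarray:
    """Subtract a long-timescale Gaussian-filtered baseline (sigma in seconds).

    A linear fit is removed before filtering and folded into the baseline, so
    steady growth/shrinkage trends are removed fully even near the series
    ends, where a reflected Gaussian filter alone would flatten them.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 2 * sigma_s / frame_interval:
        raise ValueError(
            f"series too short to detrend: need >= {2 * sigma_s / frame_interval:.0f} frames"
        )
    t = np.arange(len(x), dtype=float)
    lin = np.polyval(np.polyfit(t, x, 1), t)
    return (x - lin) - ndimage.gaussian_filter1d(x - lin, sigma_s / frame_interval,
                                                 mode="reflect")


def sg_window_frames(frame_interval: float, window_s: float = 45.0) -> int:
    """Odd frame count nearest to ``window_s`` seconds."""
    n = max(int(round(window_s / frame_interval)), 5)
    return n if n % 2 == 1 else n + 1


def smooth(series: np.ndarray, frame_interval: float, window_s: float = 45.0,
           order: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing (order 3, ~45 s window): cubics pass through."""
    x = np.asarray(series, dtype=float)
    win = sg_window_frames(frame_interval, window_s)
    if win > len(x):
        raise ValueError("Savitzky-Golay window exceeds series length")
    return signal.savgol_filter(x, win, order)


def dominant_angular_frequency(series: np.ndarray, frame_interval: float) -> float:
    """Angular frequency (rad/s) of the dominant nonzero spectral peak."""
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x * np.hanning(len(x))))
    freqs = np.fft.rfftfreq(len(x), d=frame_interval)
    spec[0] = 0.0
    k = int(np.argmax(spec))
    if spec[k] == 0 or freqs[k] == 0:
        raise ValueError("no oscillation detected (flat spectrum)")
    f = freqs[k]
    if 1 <= k < len(spec) - 1 and spec[k - 1] > 0 and spec[k + 1] > 0:
        # parabolic refinement of the peak on the log spectrum
        a, b, c = np.log(spec[k - 1:k + 2])
        denom = a - 2 * b + c
        if denom < 0:
            f = f + 0.5 * (a - c) / denom * (freqs[1] - freqs[0])
    return 2 * np.pi * f


def _kasa_circle(x: np.ndarray, y: np.ndarray):
    """Algebraic (Kasa) circle fit; returns (cx, cy, r)."""
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x ** 2 + y ** 2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r = np.sqrt(max(sol[2] + cx ** 2 + cy ** 2, 0.0))
    return cx, cy, r


def instantaneous_phase_amplitude(
    series: np.ndarray,
    frame_interval: float,
    method: str = "osculating",
    presmoothed: bool = True,
) -> PhaseTrace:
    """Phase trace of a detrended (and normally smoothed) oscillating series.

    method 'osculating' : angle about the center of local circle fits to the
                          (s, s_dot/omega) embedding; amplitude = radius.
    method 'hilbert'    : analytic-signal protophase, shifted to the same
                          convention; amplitude = analytic envelope.
    """
    s = np.asarray(series, dtype=float)
    if not presmoothed:
        s = smooth(s, frame_interval)
    omega = dominant_angular_frequency(s, frame_interval)
    n = len(s)
    if omega * n * frame_interval < 2 * np.pi:
        raise ValueError("series shorter than one oscillation")
    if method == "hilbert":
        z = signal.hilbert(s - s.mean())
        phase = np.degrees(np.angle(z)) - 180.0
        phase = (phase + 180.0) % 360.0 - 180.0
        unwrapped = np.degrees(np.unwrap(np.radians(phase)))
        amp = np.abs(z)
        return PhaseTrace(phase, unwrapped, amp, s, s, frame_interval)
    win = sg_window_frames(frame_interval)
    ds = signal.savgol_filter(s, win, 3, deriv=1, delta=frame_interval)
    if not (np.any(ds > 0) and np.any(ds < 0)):
        raise ValueError("monotone signal: phase undefined")
    y = ds / omega
    # local osculating-circle centers over a sliding half-period window
    half = max(int(round(np.pi / (omega * frame_interval))), 3)
    cx = np.empty(n)
    cy = np.empty(n)
    rad = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        xs, ys = s[lo:hi], y[lo:hi]
        if np.ptp(xs) < 1e-12 * max(abs(s).max(), 1.0) and np.ptp(ys) < 1e-12:
            raise ValueError("degenerate embedding: phase undefined")
        cx[i], cy[i], rad[i] = _kasa_circle(xs, ys)
    phase = np.degrees(np.arctan2(y - cy, -(s - cx)))
    phase = (phase + 180.0) % 360.0 - 180.0
    unwrapped = np.degrees(np.unwrap(np.radians(phase)))
    return PhaseTrace(phase, unwrapped, rad, s, s, frame_interval)


def phase_from_area(area: np.ndarray, frame_interval: float,
                    method: str = "osculating",
                    detrend_sigma_s: float = 180.0,
                    sg_window_s: float = 45.0) -> PhaseTrace:
    """Full pipeline: detrend -> Savitzky-Golay smooth -> instantaneous phase."""
    d = detrend(area, frame_interval, detrend_sigma_s)
    sm = smooth(d, frame_interval, sg_window_s)
    tr = instantaneous_phase_amplitude(sm, frame_interval, method=method)
    tr.detrended = d
    return tr


def segment_cycles(trace: PhaseTrace, jump_tol_deg: float = 180.0):
    """Complete-cycle intervals, delimited at upward crossings of -180 deg.

    Returns (cycles, mask): ``cycles`` is a list of (start, stop) frame
    indices (stop exclusive) covering complete 360-deg cycles; ``mask`` marks
    frames rejected for phase jumps larger than ``jump_tol_deg`` in one frame
    (tracking artifacts), which also veto the cycles containing them.
    """
    u = trace.unwrapped_deg
    n = len(u)
    mask = np.ones(n, dtype=bool)
    jumps = np.abs(np.diff(u)) > jump_tol_deg
    bad = np.flatnonzero(jumps)
    for b in bad:
        mask[b] = mask[b + 1] = False
    k = np.floor((u + 180.0) / 360.0).astype(int)
    cycles = []
    starts = np.flatnonzero(np.diff(k) >= 1) + 1
    for a, b in zip(starts[:-1], starts[1:]):
        if mask[a:b].all() and k[b - 1] == k[a]:
            cycles.append((int(a), int(b)))
    return cycles, mask
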