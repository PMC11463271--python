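"""Fiber-photometry processing with isosbestic correction.

A session pairs a calcium-dependent channel (465 nm GCaMP excitation) with a
calcium-independent isosbestic channel (405 nm) that shares the motion and
bleaching artifacts.  The correction fits the 465 signal on the 405 signal by
ordinary least squares over the whole session, subtracts the fitted trace,
and expresses the residual relative to its session median:

    net = F465_raw - F405_fitted
    dF/F% = 100 * (net - median(net)) / median(net)

After median subtraction the denominator median(net) is itself close to zero
for well-corrected sessions, so it is guarded: when |median(net)| falls below
``floor_frac * median(F465)`` the session median of the raw 465 channel is
used as the denominator instead and the trace is flagged.  The guard keeps
the formula intact in the regime where the net signal rides on a positive
offset and defines the degenerate case.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import signal as sps
from scipy import stats

from .behavior import EpochSet

__all__ = [
    "PhotometrySession",
    "DffTrace",
    "fit_isosbestic",
    "compute_dff",
    "epoch_means",
    "align_to_events",
]


@dataclass
class PhotometrySession:
    """Paired 465/405 traces with sampling rate and optional TTL event times."""

    t: np.ndarray
    f465: np.ndarray
    f405: np.ndarray
    fs: float
    events: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f465 = np.asarray(self.f465, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        if not (len(self.t) == len(self.f465) == len(self.f405)):
            raise ValueError("t, f465 and f405 must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.events is not None:
            self.events = np.asarray(self.events, dtype=float)
            if len(self.t) and (
                np.any(self.events < self.t[0]) or np.any(self.events > self.t[-1])
            ):
                raise ValueError("events must lie within the recording span")


@dataclass
class DffTrace:
    """Session dF/F in percent, with the intermediates of the correction."""

    t: np.ndarray
    dff: np.ndarray  # percent
    net: np.ndarray  # 465_raw - 405_fitted
    net_median: float
    denominator: float
    slope: float
    intercept: float
    fs: float
    denominator_guarded: bool = False


def fit_isosbestic(
    f465: np.ndarray, f405: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """OLS fit of the isosbestic channel to the signal channel.

    Returns (slope, intercept, f405_fitted) where
    ``f405_fitted = slope * f405 + intercept`` minimizes the squared error to
    ``f465``.  Raises for fewer than two samples or a constant 405 channel.
    """
    f465 = np.asarray(f465, dtype=float)
    f405 = np.asarray(f405, dtype=float)
    if len(f465) < 2:
        raise ValueError("need at least two samples to fit")
    if np.ptp(f405) == 0:
        raise ValueError("isosbestic channel is constant; fit undefined")
    res = stats.linregress(f405, f465)
    fitted = res.slope * f405 + res.intercept
    return float(res.slope), float(res.intercept), fitted


def _lowpass(x: np.ndarray, fs: float, corner: float, order: int = 2) -> np.ndarray:
    if corner >= fs / 2:
        return x  # corner at or above Nyquist: nothing to remove
    sos = sps.butter(order, corner, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def compute_dff(
    session: PhotometrySession,
    lowpass_hz: float | None = 15.0,
    floor_frac: float = 0.01,
) -> DffTrace:
    """Isosbestic-corrected dF/F in percent for a whole session.

    Both channels are optionally low-pass conditioned (2nd-order Butterworth,
    default 15 Hz corner, mirroring the acquisition chain) before the session-
    wide OLS fit.  ``floor_frac`` sets the denominator guard relative to the
    median of the raw 465 channel.
    """
    f465, f405 = session.f465, session.f405
    if lowpass_hz is not None:
        f465 = _lowpass(f465, session.fs, lowpass_hz)
        f405 = _lowpass(f405, session.fs, lowpass_hz)
    slope, intercept, fitted = fit_isosbestic(f465, f405)
    net = f465 - fitted
    net_median = float(np.median(net))
    scale = float(np.median(session.f465))
    guarded = False
    denom = net_median
    if abs(denom) < floor_frac * abs(scale) or denom <= 0:
        denom = scale
        guarded = True
    if denom <= 0 or abs(denom) < 1e-12:
        raise ValueError("dF/F denominator is non-positive even after guarding")
    dff = 100.0 * (net - net_median) / denom
    return DffTrace(
        t=session.t,
        dff=dff,
        net=net,
        net_median=net_median,
        denominator=float(denom),
        slope=slope,
        intercept=intercept,
        fs=session.fs,
        denominator_guarded=guarded,
    )


def epoch_means(dff: DffTrace, epochs: EpochSet) -> dict[str, float]:
    """Arithmetic mean dF/F% within each labeled epoch."""
    out: dict[str, float] = {}
    for ep in epochs:
        mask = (dff.t >= ep.t_start) & (dff.t < ep.t_end)
        if not mask.any():
            raise ValueError(f"epoch {ep.label!r} contains no samples")
        out[ep.label] = float(dff.dff[mask].mean())
    return out


def align_to_events(
    dff: DffTrace,
    events: np.ndarray,
    pre_s: float,
    post_s: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event-aligned dF/F segments, re-baselined to the pre-event window.

    Returns ``(window_t, trials, mean_trace)`` where ``trials`` is a
    (n_events, n_window) matrix of dF/F segments with each row's pre-event
    mean subtracted, and ``mean_trace`` is the column average.  Events whose
    window would extend beyond the session are dropped with a warning; zero
    retained events raise.
    """
    events = np.asarray(events, dtype=float)
    n_pre = int(round(pre_s * dff.fs))
    n_post = int(round(post_s * dff.fs))
    if n_pre < 1 or n_post < 1:
        raise ValueError("pre_s and post_s must each cover at least one sample")
    t0 = dff.t[0]
    rows = []
    dropped = 0
    for ev in events:
        i = int(round((ev - t0) * dff.fs))
        if i - n_pre < 0 or i + n_post > len(dff.dff):
            dropped += 1
            continue
        seg = dff.dff[i - n_pre : i + n_post].astype(float)
        rows.append(seg - seg[:n_pre].mean())
    if dropped:
        warnings.warn(f"{dropped} events dropped: window exceeds session")
    if not rows:
        raise ValueError("no events retained after windowing")
    trials = np.vstack(rows)
    window_t = (np.arange(-n_pre, n_post)) / dff.fs
    return window_t, trials, trials.mean(axis=0)
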