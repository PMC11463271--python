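"""ROI-trace quantification for in vitro fluorescence assays.

Hand-drawn regions of interest yield one mean-intensity trace per cell plus a
background ROI.  After frame-wise background subtraction, each trace is
normalized to its baseline mean F0:

    dF/F0(t) = (F(t) - F0) / F0,   F0 = mean of F over the baseline window.

The quantity is sign-free: a calcium indicator rises (positive dF/F0) while a
chloride-quench indicator such as MQAE falls (negative dF/F0).  Per-cell peak
(largest excursion irrespective of when it occurs) and windowed trapezoidal
AUC complete the readouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as _stats

__all__ = ["RoiTraceSet", "dff0", "peak_dff0", "auc", "group_summary"]


@dataclass
class RoiTraceSet:
    """Per-ROI intensity traces with a shared background trace.

    ``data`` holds columns ``t``, one column per ROI, and ``background``;
    ``baseline_window`` is the (t0, t1) span (seconds) over which F0 is taken,
    typically everything before stimulus onset.
    """

    data: pd.DataFrame
    baseline_window: tuple[float, float]

    def __post_init__(self) -> None:
        if "t" not in self.data.columns:
            raise ValueError("trace data must contain a 't' column")
        t = self.data["t"].to_numpy(float)
        t0, t1 = self.baseline_window
        if not (t[0] - 1e-9 <= t0 < t1 <= t[-1] + 1e-9):
            raise ValueError("baseline_window must lie within the time span")

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy(float)

    @property
    def roi_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("t", "background")]

    def background(self) -> np.ndarray:
        if "background" in self.data.columns:
            return self.data["background"].to_numpy(float)
        return np.zeros(len(self.data))


def dff0(traces: RoiTraceSet) -> tuple[pd.DataFrame, list[str]]:
    """Background-subtracted, baseline-normalized traces.

    Returns ``(df, excluded)``: a DataFrame with ``t`` plus one dF/F0 column
    per retained ROI, and the names of ROIs excluded because their baseline
    mean was non-positive after background subtraction.
    """
    t = traces.t
    bg = traces.background()
    t0, t1 = traces.baseline_window
    base_mask = (t >= t0) & (t < t1)
    if not base_mask.any():
        raise ValueError("baseline window contains no samples")
    out = {"t": t}
    excluded: list[str] = []
    for name in traces.roi_names:
        f = traces.data[name].to_numpy(float) - bg
        f0 = f[base_mask].mean()
        if not np.isfinite(f0) or f0 <= 0:
            excluded.append(name)
            continue
        out[name] = (f - f0) / f0
    return pd.DataFrame(out), excluded


def peak_dff0(dff: pd.DataFrame, mode: str = "rise") -> pd.DataFrame:
    """Per-ROI peak dF/F0 and its time, irrespective of when it occurs.

    ``mode='rise'`` takes the maximum; ``mode='quench'`` takes the sample of
    largest magnitude (signed value returned).  Ties resolve to the earliest
    time.
    """
    if mode not in ("rise", "quench"):
        raise ValueError("mode must be 'rise' or 'quench'")
    t = dff["t"].to_numpy(float)
    rows = []
    for name in [c for c in dff.columns if c != "t"]:
        y = dff[name].to_numpy(float)
        if np.all(np.isnan(y)):
            raise ValueError(f"ROI {name!r} has no finite samples")
        score = np.abs(y) if mode == "quench" else y
        idx = int(np.nanargmax(score))  # argmax returns the first maximum
        rows.append({"roi": name, "peak": float(y[idx]), "t_peak": float(t[idx])})
    return pd.DataFrame(rows)


def auc(dff: pd.DataFrame, window: tuple[float, float]) -> pd.Series:
    """Signed trapezoidal area of each dF/F0 trace over ``window`` seconds.

    Window endpoints need not be sample times: trace values there are linearly
    interpolated, which makes the integral exactly additive over abutting
    windows.  The default assay window for magnet exposure is (48, 180) s.
    """
    t = dff["t"].to_numpy(float)
    t0, t1 = float(window[0]), float(window[1])
    if t0 >= t1:
        raise ValueError("window must satisfy t0 < t1")
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValueError("window lies outside the trace span")
    inner = t[(t > t0) & (t < t1)]
    grid = np.concatenate([[t0], inner, [t1]])
    out = {}
    for name in [c for c in dff.columns if c != "t"]:
        y = np.interp(grid, t, dff[name].to_numpy(float))
        out[name] = float(np.trapezoid(y, grid))
    return pd.Series(out, name="auc")


def group_summary(
    values: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    test: str = "auto",
) -> pd.DataFrame:
    """Per-group mean, SD, SEM and n, with a comparison test attached.

    Two groups are compared with Welch's t test; three or more with one-way
    ANOVA plus Tukey's HSD (``df.attrs['test']`` carries the result).
    ``test='none'`` skips the comparison.
    """
    df = pd.DataFrame({"value": np.asarray(values, float), "group": np.asarray(labels)})
    if df["group"].nunique() < 2:
        raise ValueError("need at least two groups")
    if (df.groupby("group")["value"].count() == 0).any():
        raise ValueError("empty group")
    summary = (
        df.groupby("group")["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    summary["sem"] = summary["sd"] / np.sqrt(summary["n"])
    if test != "none":
        groups = [g["value"].to_numpy() for _, g in df.groupby("group")]
        if len(groups) == 2:
            t, dof, p = _stats.welch_t(groups[0], groups[1])
            summary.attrs["test"] = {"name": "welch_t", "t": t, "df": dof, "p": p}
        else:
            summary.attrs["test"] = _stats.anova_tukey(groups)
    return summary
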