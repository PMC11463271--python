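"""Magnetic field maps and field-conditioned behavior analysis.

A gaussmeter field map is a rectangular grid of flux density (mT) over the
behavioral arena.  Tracked positions are mapped to local field strength by
bilinear interpolation, and behavior (occupancy, freezing) is accumulated in
field-strength bins — the analysis used to locate the ~180 mT threshold for
field-induced freezing within a 100-270 mT titration gradient.

Regime labels follow the field-source definitions: a "high" static field
spans 0.5-1.3 T and a "low" one 0.1-0.27 T.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .behavior import FreezeBout, KeypointTrack

__all__ = [
    "FieldGrid",
    "field_at",
    "bin_behavior_by_field",
    "classify_regime",
    "HIGH_DMF_RANGE_MT",
    "LOW_DMF_RANGE_MT",
]

#: static-field regime definitions in mT
HIGH_DMF_RANGE_MT = (500.0, 1300.0)
LOW_DMF_RANGE_MT = (100.0, 270.0)


@dataclass
class FieldGrid:
    """Rectangular grid of field strength.

    x, y are strictly increasing node coordinates (cm); B has shape
    (len(x), len(y)) in mT, all values non-negative.
    """

    x: np.ndarray
    y: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1:
            raise ValueError("x and y must be 1-D node arrays")
        if np.any(np.diff(self.x) <= 0) or np.any(np.diff(self.y) <= 0):
            raise ValueError("grid nodes must be strictly increasing")
        if self.B.shape != (len(self.x), len(self.y)):
            raise ValueError(
                f"B shape {self.B.shape} does not match grid "
                f"({len(self.x)}, {len(self.y)})"
            )
        if np.any(self.B < 0):
            raise ValueError("field strength must be non-negative")
        self._interp = RegularGridInterpolator(
            (self.x, self.y), self.B, method="linear", bounds_error=True
        )

    def at(self, x: float | np.ndarray, y: float | np.ndarray) -> float | np.ndarray:
        """Bilinear interpolation of field strength at (x, y); exact at
        nodes.  Out-of-hull queries raise (no extrapolation)."""
        pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
        out = self._interp(pts)
        return float(out[0]) if np.isscalar(x) and np.isscalar(y) else out

    @property
    def range_mT(self) -> tuple[float, float]:
        return float(self.B.min()), float(self.B.max())


def field_at(grid: FieldGrid, x, y):
    """Functional alias for :meth:`FieldGrid.at`."""
    return grid.at(x, y)


def bin_behavior_by_field(
    track: KeypointTrack,
    grid: FieldGrid,
    bouts: Sequence[FreezeBout],
    bin_edges: Sequence[float],
) -> pd.DataFrame:
    """Accumulate occupancy and freezing time per field-strength bin.

    Each sample of the (resampled) track contributes one sample period of
    occupancy to the bin of the field at its center keypoint; samples falling
    inside a freeze bout (``t_start <= t < t_end``) contribute the same period
    to that bin's freezing time.  Bins are half-open ``[low, high)`` with the
    last bin closed, so an edge at 180 mT puts "at or above 180 mT" samples in
    the upper bin.  Samples with a missing center or outside the grid hull are
    tallied as missing, and bin occupancy + missing time equals the track
    duration exactly.

    Returns a DataFrame with columns ``B_low, B_high, occupancy_s,
    freezing_s, freezing_rate`` and attrs ``missing_s``.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be a strictly increasing 1-D sequence")
    t = track.t
    dt = track.dt
    xy = track.xy("center")
    in_bout = np.zeros(len(t), dtype=bool)
    for b in bouts:
        in_bout |= (t >= b.t_start) & (t < b.t_end)

    n_bins = len(edges) - 1
    occupancy = np.zeros(n_bins)
    freezing = np.zeros(n_bins)
    missing = 0.0
    for i in range(len(t)):
        if not np.all(np.isfinite(xy[i])):
            missing += dt
            continue
        try:
            b = grid.at(float(xy[i, 0]), float(xy[i, 1]))
        except ValueError:
            missing += dt
            continue
        idx = np.searchsorted(edges, b, side="right") - 1
        if idx == n_bins and b == edges[-1]:
            idx = n_bins - 1  # close the last bin
        if idx < 0 or idx >= n_bins:
            missing += dt
            continue
        occupancy[idx] += dt
        if in_bout[i]:
            freezing[idx] += dt

    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occupancy > 0, freezing / occupancy, 0.0)
    out = pd.DataFrame(
        {
            "B_low": edges[:-1],
            "B_high": edges[1:],
            "occupancy_s": occupancy,
            "freezing_s": freezing,
            "freezing_rate": rate,
        }
    )
    out.attrs["missing_s"] = missing
    return out


def classify_regime(B_range: tuple[float, float]) -> str:
    """Label a field-strength range (mT) as 'high', 'low', or 'none'.

    'high' covers 500-1300 mT and 'low' 100-270 mT; a range must fall
    entirely within a regime's span to earn its label.
    """
    lo, hi = float(B_range[0]), float(B_range[1])
    if lo > hi:
        raise ValueError("reversed field range")
    if HIGH_DMF_RANGE_MT[0] <= lo and hi <= HIGH_DMF_RANGE_MT[1]:
        return "high"
    if LOW_DMF_RANGE_MT[0] <= lo and hi <= LOW_DMF_RANGE_MT[1]:
        return "low"
    return "none"
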