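"""Trajectory-derived behavior metrics for open-field and rotometer assays.

The substrate is a multi-keypoint track (nose, center, fore/hind paws, tail)
sampled on a uniform time grid, as exported by video tracking software.  The
metrics mirror the readouts used to phenotype striatal indirect-pathway
activation: freezing of gait, ambulation time, distance traveled, activity
percentage, change of location, and (for hemiparkinsonian rotation assays)
signed rotation counts.

Freezing of gait is defined as a continuous period of at least 1 s with no
change of spatial position of the head, center, or extremities.  "No change"
is operationalized with a per-step displacement tolerance ``eps`` because real
tracking data always jitters; the tolerance is a parameter, not part of the
definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KEYPOINTS",
    "KeypointTrack",
    "Epoch",
    "EpochSet",
    "FreezeBout",
    "FreezeParams",
    "BehaviorSummary",
    "ANALYSIS_RATE",
    "resample_track",
    "detect_freezing",
    "ambulation_metrics",
    "count_rotations",
    "percent_change_rotations",
    "segment_epochs",
    "change_of_location",
    "behavior_summary",
]

#: canonical keypoint names, in column order
KEYPOINTS = ("nose", "center", "forepaws", "hindpaws", "tail")

#: analysis sampling rate in Hz.  Tracks recorded at 5 Hz are thinned by
#: taking every second frame, yielding 150 positions per minute.
ANALYSIS_RATE = 2.5


def track_columns(keypoints: Sequence[str] = KEYPOINTS) -> list[str]:
    cols = ["t"]
    for kp in keypoints:
        cols += [f"{kp}_x", f"{kp}_y"]
    return cols


@dataclass
class KeypointTrack:
    """Time-stamped arena coordinates for a named set of keypoints.

    Parameters
    ----------
    data
        DataFrame with a ``t`` column (seconds, strictly increasing, uniform
        grid) and ``<keypoint>_x`` / ``<keypoint>_y`` columns in cm.  Missing
        samples are NaN.
    frame_rate
        Sampling rate of ``data`` in Hz.
    arena_size
        (width, height) of the arena in cm.
    """

    data: pd.DataFrame
    frame_rate: float
    arena_size: tuple[float, float] = (26.5, 26.5)

    def __post_init__(self) -> None:
        if "t" not in self.data.columns:
            raise ValueError("track data must contain a 't' column")
        t = self.data["t"].to_numpy(float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("track timestamps must be strictly increasing")
        if self.frame_rate <= 0 or not np.isfinite(self.frame_rate):
            raise ValueError("frame_rate must be positive and finite")

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy(float)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def keypoints(self) -> list[str]:
        return [c[:-2] for c in self.data.columns if c.endswith("_x")]

    def xy(self, keypoint: str) -> np.ndarray:
        """(n, 2) array of coordinates for one keypoint (NaN where missing)."""
        try:
            return self.data[[f"{keypoint}_x", f"{keypoint}_y"]].to_numpy(float)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"track has no keypoint {keypoint!r}") from exc

    def slice_time(self, t_start: float, t_end: float) -> "KeypointTrack":
        """Sub-track with t in [t_start, t_end); timestamps preserved."""
        mask = (self.t >= t_start) & (self.t < t_end)
        return replace(self, data=self.data.loc[mask].reset_index(drop=True))


@dataclass(frozen=True)
class Epoch:
    label: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError(f"epoch {self.label!r}: t_end must exceed t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


class EpochSet:
    """Ordered, non-overlapping labeled intervals, e.g. pre-DMF/DMF/post-DMF."""

    def __init__(self, epochs: Iterable[Epoch | tuple[str, float, float]]):
        parsed = [e if isinstance(e, Epoch) else Epoch(*e) for e in epochs]
        parsed.sort(key=lambda e: e.t_start)
        for a, b in zip(parsed, parsed[1:]):
            if b.t_start < a.t_end - 1e-9:
                raise ValueError(f"epochs {a.label!r} and {b.label!r} overlap")
        self.epochs = parsed

    def __iter__(self):
        return iter(self.epochs)

    def __len__(self) -> int:
        return len(self.epochs)

    @classmethod
    def session(cls, labels: Sequence[str], epoch_length: float) -> "EpochSet":
        """Back-to-back equal-length epochs starting at t=0 (e.g. three 300 s
        sessions labeled pre-DMF/DMF/post-DMF)."""
        return cls(
            (lab, i * epoch_length, (i + 1) * epoch_length)
            for i, lab in enumerate(labels)
        )


@dataclass(frozen=True)
class FreezeBout:
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class FreezeParams:
    """Parameters of the freezing-of-gait detector.

    min_duration
        Minimum bout span in seconds (1 s in the source assay definition).
    eps
        Per-step displacement tolerance in cm below which a keypoint counts
        as stationary.  The assay definition says "no change of spatial
        position"; eps absorbs tracking jitter.
    keypoints_required
        Keypoints that must all be stationary for a step to be static.
    """

    min_duration: float = 1.0
    eps: float = 0.5
    keypoints_required: tuple[str, ...] = ("nose", "center", "forepaws", "hindpaws")

    def __post_init__(self) -> None:
        if self.min_duration <= 0:
            raise ValueError("min_duration must be positive")
        if self.eps < 0:
            raise ValueError("eps must be non-negative")


@dataclass
class BehaviorSummary:
    """Per-epoch behavior metrics."""

    label: str
    duration: float
    freezing_time: float
    n_freeze_bouts: int
    ambulation_time: float
    distance: float
    activity_pct: float
    rotations_cw: int = 0
    rotations_ccw: int = 0
    net_contralateral: int = 0

    def as_dict(self) -> dict:
        return {
            "epoch": self.label,
            "duration_s": self.duration,
            "freezing_time_s": self.freezing_time,
            "n_freeze_bouts": self.n_freeze_bouts,
            "ambulation_time_s": self.ambulation_time,
            "distance_cm": self.distance,
            "activity_pct": self.activity_pct,
            "rotations_cw": self.rotations_cw,
            "rotations_ccw": self.rotations_ccw,
            "net_contralateral": self.net_contralateral,
        }


# ---------------------------------------------------------------------------
# resampling


def resample_track(track: KeypointTrack, rate: float = ANALYSIS_RATE) -> KeypointTrack:
    """Thin a track to the analysis rate by frame decimation.

    A 5 Hz recording is reduced to 2.5 Hz by keeping every second frame
    (150 positions per minute).  Timestamps of the retained frames are
    preserved.  Tracks already at the analysis rate pass through unchanged.
    """
    if track.n_samples == 0:
        return track
    t = track.t
    if len(t) > 2:
        steps = np.diff(t)
        if np.max(np.abs(steps - steps.mean())) > 0.05 * steps.mean():
            raise ValueError("track time grid is not uniform")
    if abs(track.frame_rate - rate) < 1e-9:
        return track
    stride_f = track.frame_rate / rate
    stride = int(round(stride_f))
    if stride < 1 or abs(stride_f - stride) > 1e-6:
        raise ValueError(
            f"frame_rate {track.frame_rate} Hz is not an integer multiple of "
            f"the analysis rate {rate} Hz"
        )
    data = track.data.iloc[::stride].reset_index(drop=True)
    return replace(track, data=data, frame_rate=rate)


# ---------------------------------------------------------------------------
# freezing


def _static_steps(track: KeypointTrack, params: FreezeParams) -> np.ndarray:
    """Boolean array over the n-1 inter-sample steps.

    A step is static iff every required keypoint moved at most ``eps`` cm and
    none of the required coordinates is missing (missing -> non-static; this
    is deliberately conservative so tracker dropouts cannot inflate freezing).
    """
    n = track.n_samples
    if n < 2:
        return np.zeros(0, dtype=bool)
    static = np.ones(n - 1, dtype=bool)
    any_valid = False
    for kp in params.keypoints_required:
        xy = track.xy(kp)
        if not np.all(np.isnan(xy)):
            any_valid = True
        disp = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        ok = np.isfinite(disp) & (disp <= params.eps)
        static &= ok
    if not any_valid:
        raise ValueError("all required keypoints are entirely missing")
    return static


def detect_freezing(
    track: KeypointTrack, params: FreezeParams | None = None
) -> tuple[list[FreezeBout], float]:
    """Detect freezing-of-gait bouts on a resampled track.

    Maximal runs of static steps whose span reaches ``min_duration`` become
    bouts.  A run of k static steps over samples i..i+k spans
    ``[t[i], t[i+k])``.  Returns the bouts and the total freezing time.
    """
    params = params or FreezeParams()
    static = _static_steps(track, params)
    t = track.t
    dt = track.dt
    bouts: list[FreezeBout] = []
    i = 0
    n = len(static)
    while i < n:
        if static[i]:
            j = i
            while j + 1 < n and static[j + 1]:
                j += 1
            t_start = t[i]
            # a run reaching the end of the recording covers the final sample
            t_end = t[-1] + dt if j == n - 1 else t[j] + dt
            if t_end - t_start >= params.min_duration - 1e-9:
                bouts.append(FreezeBout(t_start, t_end))
            i = j + 1
        else:
            i += 1
    total = float(sum(b.duration for b in bouts))
    return bouts, total


# ---------------------------------------------------------------------------
# ambulation


def ambulation_metrics(
    track: KeypointTrack, speed_threshold: float = 2.0
) -> dict[str, float]:
    """Distance, ambulation time and activity percentage from the center point.

    A step is "active" iff the center speed exceeds ``speed_threshold`` cm/s.
    Steps with a missing center are excluded from both the numerator and the
    denominator of the activity percentage.
    """
    xy = track.xy("center")
    if track.n_samples < 2:
        return {"ambulation_time": 0.0, "distance": 0.0, "activity_pct": 0.0}
    disp = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    valid = np.isfinite(disp)
    if valid.size and (1 - valid.mean()) > 0.20:
        warnings.warn(
            f"{100 * (1 - valid.mean()):.0f}% of center steps are missing",
            stacklevel=2,
        )
    dt = track.dt
    speed = disp[valid] / dt
    active = speed > speed_threshold
    valid_time = valid.sum() * dt
    ambulation_time = float(active.sum() * dt)
    distance = float(disp[valid].sum())
    activity_pct = float(100.0 * ambulation_time / valid_time) if valid_time else 0.0
    return {
        "ambulation_time": ambulation_time,
        "distance": distance,
        "activity_pct": activity_pct,
    }


# ---------------------------------------------------------------------------
# rotations


def _heading(track: KeypointTrack, min_axis: float = 1e-6) -> np.ndarray:
    """Unwrapped heading (rad) of the center->nose body axis.

    Frames with a degenerate (near zero-length or missing) axis carry the
    previous heading forward, so they contribute no rotation.
    """
    vec = track.xy("nose") - track.xy("center")
    norm = np.linalg.norm(vec, axis=1)
    bad = ~np.isfinite(norm) | (norm < min_axis)
    if bad.all():
        raise ValueError("no valid center->nose axis in track")
    if bad.any():
        warnings.warn(
            f"{bad.sum()} frames with degenerate body axis skipped", stacklevel=3
        )
    ang = np.arctan2(vec[:, 1], vec[:, 0])
    ang[bad] = np.nan
    # forward/backward fill NaNs so increments across gaps are zero
    s = pd.Series(ang).ffill().bfill().to_numpy()
    return np.unwrap(s)


def count_rotations(
    track: KeypointTrack, mode: str = "full", lesion_side: str | None = None
) -> dict[str, int]:
    """Count threshold-crossing rotations of the body axis.

    ``mode='quarter'`` counts every accumulated 90 deg of turning in one
    direction (the open-field ">90 deg" metric); ``mode='full'`` counts full
    360 deg rotations (the rotometer metric).  The accumulator resets after
    each count and whenever the turning direction reverses past the origin.

    Counterclockwise is the positive mathematical direction in arena
    coordinates (x rightward, y upward).  With a declared ``lesion_side``,
    ``net_contralateral`` counts rotations away from the lesioned hemisphere:
    clockwise for a left lesion, counterclockwise for a right lesion.
    """
    if mode not in ("quarter", "full"):
        raise ValueError("mode must be 'quarter' or 'full'")
    threshold = np.pi / 2 if mode == "quarter" else 2 * np.pi
    heading = _heading(track)
    ccw, cw = _threshold_crossings(np.diff(heading), threshold)
    out = {"rotations_cw": cw, "rotations_ccw": ccw, "net": ccw - cw}
    if lesion_side is not None:
        if lesion_side not in ("left", "right"):
            raise ValueError("lesion_side must be 'left' or 'right'")
        contra, ipsi = (cw, ccw) if lesion_side == "left" else (ccw, cw)
        out["net_contralateral"] = contra - ipsi
    return out


def _threshold_crossings(increments: np.ndarray, threshold: float) -> tuple[int, int]:
    """Count +/- threshold crossings of the cumulative sum, resetting to zero
    after each count.  Returns (ccw_counts, cw_counts)."""
    acc = 0.0
    ccw = cw = 0
    for d in increments:
        if not np.isfinite(d):
            continue
        acc += d
        while acc >= threshold:
            ccw += 1
            acc -= threshold
        while acc <= -threshold:
            cw += 1
            acc += threshold
    return ccw, cw


def percent_change_rotations(pre: float, during: float) -> float:
    """Percent change in rotation counts from the pre-treatment baseline."""
    if pre == 0:
        raise ZeroDivisionError("baseline rotation count is zero; % change undefined")
    return 100.0 * (during - pre) / pre


# ---------------------------------------------------------------------------
# epochs


def segment_epochs(
    track: KeypointTrack, epochs: EpochSet
) -> dict[str, KeypointTrack]:
    """Slice a track into labeled epochs; timestamps are preserved.

    Samples belong to an epoch iff ``t_start <= t < t_end``.  Epochs that
    extend beyond the track span raise.
    """
    if track.n_samples == 0:
        raise ValueError("cannot segment an empty track")
    t = track.t
    span_end = t[-1] + track.dt
    out: dict[str, KeypointTrack] = {}
    for ep in epochs:
        if ep.t_start < t[0] - 1e-9 or ep.t_end > span_end + 1e-9:
            raise ValueError(
                f"epoch {ep.label!r} [{ep.t_start}, {ep.t_end}) outside track span"
            )
        out[ep.label] = track.slice_time(ep.t_start, ep.t_end)
    return out


def change_of_location(track: KeypointTrack) -> pd.DataFrame:
    """Spatial motion along the Y axis (toward the magnet) as a function of
    time: the "change of location" trace."""
    return pd.DataFrame({"t": track.t, "y": track.xy("center")[:, 1]})


# ---------------------------------------------------------------------------
# one-call summary


def behavior_summary(
    track: KeypointTrack,
    epochs: EpochSet,
    freeze_params: FreezeParams | None = None,
    speed_threshold: float = 2.0,
    rotation_mode: str = "quarter",
    lesion_side: str | None = None,
) -> list[BehaviorSummary]:
    """Compute all per-epoch behavior metrics on a (resampled) track."""
    track = resample_track(track)
    freeze_params = freeze_params or FreezeParams()
    summaries = []
    for label, sub in segment_epochs(track, epochs).items():
        ep = next(e for e in epochs if e.label == label)
        bouts, freezing = detect_freezing(sub, freeze_params)
        amb = ambulation_metrics(sub, speed_threshold)
        try:
            rot = count_rotations(sub, rotation_mode, lesion_side)
        except ValueError:
            rot = {"rotations_cw": 0, "rotations_ccw": 0, "net": 0}
        summaries.append(
            BehaviorSummary(
                label=label,
                duration=ep.duration,
                freezing_time=freezing,
                n_freeze_bouts=len(bouts),
                ambulation_time=amb["ambulation_time"],
                distance=amb["distance"],
                activity_pct=amb["activity_pct"],
                rotations_cw=rot["rotations_cw"],
                rotations_ccw=rot["rotations_ccw"],
                net_contralateral=rot.get("net_contralateral", rot["net"]),
            )
        )
    return summaries
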