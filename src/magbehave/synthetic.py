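"""Seeded synthetic-data generators with known ground truth.

Every input modality the pipeline consumes can be emulated here: two-state
(ambulate/freeze) locomotion tracks, dual-channel fiber-photometry sessions,
gaussmeter-style magnetic field maps, per-ROI fluorescence traces, PET uptake
tables, and three-channel cell images.  Each generator is a pure function of
its parameter set (including the seed) and returns the realized ground truth
alongside the data, so every downstream stage can be tested for parameter
recovery without external recordings.

The generators target the statistical structure of the real recordings (bout
dynamics, shared photometry artifacts, field decay with distance from the
magnet face, disk-shaped somata), not the underlying biophysics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import KEYPOINTS, KeypointTrack, track_columns
from .fieldmap import FieldGrid
from .photometry import PhotometrySession

__all__ = [
    "TrackSynthParams",
    "PhotometrySynthParams",
    "FieldSynthParams",
    "RoiSynthParams",
    "PetSynthParams",
    "CellImageSynthParams",
    "generate_track",
    "generate_photometry",
    "generate_field_grid",
    "generate_roi_traces",
    "generate_pet_table",
    "generate_cell_image",
]

#: rigid body-frame displacement of each keypoint from the center (cm),
#: x forward (toward the nose), y leftward
DEFAULT_KEYPOINT_OFFSETS: dict[str, tuple[float, float]] = {
    "nose": (3.5, 0.0),
    "center": (0.0, 0.0),
    "forepaws": (1.5, 0.8),
    "hindpaws": (-1.5, -0.8),
    "tail": (-4.0, 0.0),
}


# ---------------------------------------------------------------------------
# locomotion tracks


@dataclass(frozen=True)
class TrackSynthParams:
    """Two-state (ambulate/freeze) locomotion generator parameters.

    The animal alternates between an ambulation state (correlated random walk
    at ``mean_ambulation_speed``) and a freeze state (all keypoints static up
    to tracking jitter).  Dwell times are gamma-distributed with shape
    ``dwell_shape``; means are set so the long-run freeze time fraction equals
    ``freeze_fraction``.  ``field_threshold_mT`` (with a grid) gates freeze
    *entry* on local field strength, emulating the field-strength-dependent
    freezing used in the low-field titration assay.
    """

    duration: float = 300.0
    frame_rate: float = 5.0
    arena_size: tuple[float, float] = (26.5, 26.5)
    freeze_fraction: float = 0.3
    mean_freeze_bout: float = 12.0
    dwell_shape: float = 3.0
    mean_ambulation_speed: float = 8.0
    turn_sd: float = 0.6  # rad per frame, heading random walk
    keypoint_offsets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_KEYPOINT_OFFSETS)
    )
    jitter_sd: float = 0.05
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.freeze_fraction <= 1.0):
            raise ValueError("freeze_fraction must lie in [0, 1]")
        if not (np.isfinite(self.duration) and self.duration > 0):
            raise ValueError("duration must be positive and finite")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")


def _dwell(rng: np.random.Generator, mean: float, shape: float) -> float:
    return float(rng.gamma(shape, mean / shape))


def generate_track(
    params: TrackSynthParams,
    field_grid: FieldGrid | None = None,
    field_threshold_mT: float | None = None,
) -> tuple[KeypointTrack, list[tuple[float, float]]]:
    """Simulate a locomotion track; returns (track, realized freeze intervals).

    Without field coupling, state dwell times are drawn from gamma
    distributions whose means realize ``freeze_fraction``.  With
    ``field_grid`` and ``field_threshold_mT``, freeze entry is hazard-gated:
    while ambulating, the freeze hazard is nonzero only where the local field
    at the center point is at or above the threshold, so freezing ground
    truth accrues exclusively in supra-threshold territory.

    Freeze intervals are reported in continuous time, clipped to
    ``[0, duration]``, and never overlap.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration * p.frame_rate))
    dt = 1.0 / p.frame_rate
    t = np.arange(n) * dt

    if p.freeze_fraction >= 1.0:
        mean_amb = 0.0
    elif p.freeze_fraction <= 0.0:
        mean_amb = np.inf
    else:
        mean_amb = p.mean_freeze_bout * (1.0 - p.freeze_fraction) / p.freeze_fraction

    gated = field_grid is not None and field_threshold_mT is not None
    # per-frame freeze-entry hazard for the gated mode
    entry_p = dt / mean_amb if np.isfinite(mean_amb) and mean_amb > 0 else 0.0

    w, h = p.arena_size
    pos = np.array([rng.uniform(0.2 * w, 0.8 * w), rng.uniform(0.2 * h, 0.8 * h)])
    heading = rng.uniform(-np.pi, np.pi)

    center = np.empty((n, 2))
    headings = np.empty(n)
    frozen = np.zeros(n, dtype=bool)

    state_frozen = False
    if not gated and p.freeze_fraction > 0:
        state_frozen = rng.uniform() < p.freeze_fraction
    state_left = (
        _dwell(rng, p.mean_freeze_bout, p.dwell_shape)
        if state_frozen
        else (_dwell(rng, mean_amb, p.dwell_shape) if np.isfinite(mean_amb) else np.inf)
    )

    for i in range(n):
        if not gated:
            while state_left <= 0:
                state_frozen = not state_frozen
                state_left += (
                    _dwell(rng, p.mean_freeze_bout, p.dwell_shape)
                    if state_frozen
                    else (
                        _dwell(rng, mean_amb, p.dwell_shape)
                        if np.isfinite(mean_amb)
                        else np.inf
                    )
                )
        else:
            if state_frozen:
                if state_left <= 0:
                    state_frozen = False
            else:
                try:
                    b = field_grid.at(pos[0], pos[1])
                except ValueError:
                    b = 0.0
                if b >= field_threshold_mT and rng.uniform() < entry_p:
                    state_frozen = True
                    state_left = _dwell(rng, p.mean_freeze_bout, p.dwell_shape)

        frozen[i] = state_frozen
        center[i] = pos
        headings[i] = heading

        if state_frozen:
            state_left -= dt
        else:
            heading += rng.normal(0.0, p.turn_sd)
            step = p.mean_ambulation_speed * dt
            nxt = pos + step * np.array([np.cos(heading), np.sin(heading)])
            # reflect off arena walls
            for k, lim in enumerate((w, h)):
                if nxt[k] < 0:
                    nxt[k] = -nxt[k]
                    heading = np.pi - heading if k == 0 else -heading
                elif nxt[k] > lim:
                    nxt[k] = 2 * lim - nxt[k]
                    heading = np.pi - heading if k == 0 else -heading
            pos = nxt
            if not gated:
                state_left -= dt

    intervals = _bool_to_intervals(frozen, dt, p.duration)

    cols: dict[str, np.ndarray] = {"t": t}
    rot = np.stack(
        [
            np.stack([np.cos(headings), -np.sin(headings)], axis=1),
            np.stack([np.sin(headings), np.cos(headings)], axis=1),
        ],
        axis=1,
    )  # (n, 2, 2) body->arena rotation
    for kp in KEYPOINTS:
        off = np.asarray(p.keypoint_offsets.get(kp, (0.0, 0.0)))
        xy = center + rot @ off
        xy = xy + rng.normal(0.0, p.jitter_sd, size=xy.shape)
        cols[f"{kp}_x"] = xy[:, 0]
        cols[f"{kp}_y"] = xy[:, 1]
    data = pd.DataFrame(cols, columns=track_columns())

    if p.dropout_rate > 0:
        # dropouts come in short runs, as in real tracker exports
        miss = np.zeros(n, dtype=bool)
        i = 0
        while i < n:
            if rng.uniform() < p.dropout_rate / 3.0:
                run = rng.integers(1, 4)
                miss[i : i + run] = True
                i += run
            else:
                i += 1
        data.loc[miss, [c for c in data.columns if c != "t"]] = np.nan

    track = KeypointTrack(data=data, frame_rate=p.frame_rate, arena_size=p.arena_size)
    return track, intervals


def _bool_to_intervals(
    flags: np.ndarray, dt: float, duration: float
) -> list[tuple[float, float]]:
    """Convert a per-frame boolean state into [start, end) intervals.

    Frame i covers [i*dt, (i+1)*dt); the final interval is clipped to
    ``duration``.
    """
    intervals: list[tuple[float, float]] = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i * dt
        elif not f and start is not None:
            intervals.append((start, i * dt))
            start = None
    if start is not None:
        intervals.append((start, min(len(flags) * dt, duration)))
    return intervals


# ---------------------------------------------------------------------------
# fiber photometry


@dataclass(frozen=True)
class PhotometrySynthParams:
    """Dual-channel photometry generator parameters.

    The 465 nm channel carries baseline x bleach decay, a shared slow motion
    artifact, a train of calcium-transient kernels, and white noise.  The
    405 nm isosbestic channel carries ``iso_gain`` times the shared components
    (bleach + artifact) plus its own noise, but no transients — exactly the
    structure the isosbestic linear-fit correction assumes.

    No artifact or noise magnitudes are published for these recordings; the
    defaults (artifact ~5% of baseline, noise ~0.3%) are stated assumptions.
    """

    duration: float = 240.0
    fs: float = 100.0
    baseline: float = 100.0
    bleach_tau: float = 2000.0
    n_transients: int = 12
    transient_amplitude: float = 5.0
    transient_rise: float = 0.5
    transient_decay: float = 2.5
    artifact_amplitude: float = 8.0
    artifact_timescale: float = 10.0
    iso_gain: float = 0.8
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_transients < 0:
            raise ValueError("n_transients must be non-negative")
        if not (self.transient_decay > self.transient_rise > 0):
            raise ValueError("require transient_decay > transient_rise > 0")


def transient_kernel(
    t: np.ndarray, rise: float, decay: float, amplitude: float = 1.0
) -> np.ndarray:
    """Difference-of-exponentials calcium transient, normalized to peak
    ``amplitude``; zero for t < 0."""
    tp = np.maximum(t, 0.0)
    k = np.where(t >= 0, np.exp(-tp / decay) - np.exp(-tp / rise), 0.0)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    return amplitude * k / peak


@dataclass
class PhotometryGroundTruth:
    transient_times: np.ndarray
    transient_amplitudes: np.ndarray
    artifact: np.ndarray
    bleach: np.ndarray


def generate_photometry(
    params: PhotometrySynthParams,
    transient_times: Sequence[float] | None = None,
    events: Sequence[float] | None = None,
) -> tuple[PhotometrySession, PhotometryGroundTruth]:
    """Simulate a dual-channel session; returns (session, ground truth).

    ``transient_times`` overrides the random placement (e.g. to lock
    transients to TTL events); ``events`` populates the session's TTL times.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration * p.fs))
    t = np.arange(n) / p.fs

    bleach = p.baseline * np.exp(-t / p.bleach_tau)

    # smooth shared artifact: random-phase sum of slow sinusoids
    artifact = np.zeros(n)
    if p.artifact_amplitude > 0:
        for _ in range(4):
            f = rng.uniform(0.3, 1.5) / p.artifact_timescale
            artifact += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        artifact *= p.artifact_amplitude / max(np.max(np.abs(artifact)), 1e-12)

    if transient_times is None:
        lo, hi = 0.05 * p.duration, 0.95 * p.duration
        times = np.sort(rng.uniform(lo, hi, size=p.n_transients))
    else:
        times = np.sort(np.asarray(transient_times, dtype=float))
    amps = np.full(len(times), p.transient_amplitude)

    transients = np.zeros(n)
    for t0, a in zip(times, amps):
        transients += transient_kernel(t - t0, p.transient_rise, p.transient_decay, a)

    shared = bleach + artifact
    f465 = shared + transients + rng.normal(0.0, p.noise_sd, n)
    f405 = p.iso_gain * shared + rng.normal(0.0, p.noise_sd, n)

    session = PhotometrySession(
        t=t,
        f465=f465,
        f405=f405,
        fs=p.fs,
        events=np.asarray(events, dtype=float) if events is not None else None,
    )
    truth = PhotometryGroundTruth(
        transient_times=times,
        transient_amplitudes=amps,
        artifact=artifact,
        bleach=bleach,
    )
    return session, truth


# ---------------------------------------------------------------------------
# magnetic field grids


@dataclass(frozen=True)
class FieldSynthParams:
    """Gaussmeter-style field map over the arena.

    The field is uniform across x and decays exponentially with distance from
    the magnet-proximal edge (taken as y = arena height).  Either
    ``decay_length`` or ``distal_mT`` fixes the decay; giving ``distal_mT``
    chooses the decay length so the distal edge (y = 0) sits exactly at that
    value, e.g. a 100-270 mT low-field titration map.
    """

    arena_size: tuple[float, float] = (26.5, 26.5)
    grid_spacing: float = 2.65
    peak_mT: float = 270.0
    decay_length: float | None = None
    distal_mT: float | None = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_mT < 0:
            raise ValueError("peak_mT must be non-negative")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.grid_spacing > min(self.arena_size):
            raise ValueError("grid_spacing larger than the arena")
        if self.decay_length is None and self.distal_mT is None:
            raise ValueError("give decay_length or distal_mT")
        if self.distal_mT is not None and self.peak_mT > 0:
            if not (0 < self.distal_mT <= self.peak_mT):
                raise ValueError("distal_mT must lie in (0, peak_mT]")


def generate_field_grid(params: FieldSynthParams) -> FieldGrid:
    """Build a rectangular field map; monotone non-increasing away from the
    magnet-proximal edge by construction, values >= 0."""
    p = params
    w, h = p.arena_size
    x = np.arange(0.0, w + 1e-9, p.grid_spacing)
    y = np.arange(0.0, h + 1e-9, p.grid_spacing)
    if x[-1] < w:
        x = np.append(x, w)
    if y[-1] < h:
        y = np.append(y, h)
    if p.peak_mT == 0:
        B = np.zeros((len(x), len(y)))
        return FieldGrid(x=x, y=y, B=B)
    if p.decay_length is not None:
        lam = p.decay_length
    else:
        ratio = p.peak_mT / p.distal_mT
        lam = np.inf if ratio == 1.0 else h / np.log(ratio)
    dist = h - y  # distance from the proximal edge
    profile = p.peak_mT * np.exp(-dist / lam) if np.isfinite(lam) else np.full_like(
        dist, p.peak_mT
    )
    B = np.tile(profile, (len(x), 1))
    return FieldGrid(x=x, y=y, B=B)


# ---------------------------------------------------------------------------
# ROI fluorescence traces


@dataclass(frozen=True)
class RoiSynthParams:
    """Per-ROI fluorescence traces for the in vitro assays.

    ``response`` sets the plateau Delta F/F0 of responding ROIs after stimulus
    onset (negative emulates a chloride-quench assay); responders ramp to the
    plateau with time constant ``response_tau``.
    """

    duration: float = 180.0
    fs: float = 1.0 / 6.0  # one frame every 6 s, as in slow imaging
    n_rois: int = 20
    baseline_f: float = 100.0
    background_f: float = 20.0
    stimulus_onset: float = 48.0
    response: float = 0.3
    responder_fraction: float = 1.0
    response_tau: float = 20.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if not (0 <= self.responder_fraction <= 1):
            raise ValueError("responder_fraction must lie in [0, 1]")


def generate_roi_traces(params: RoiSynthParams):
    """Returns (RoiTraceSet, ground-truth dict of per-ROI plateau response)."""
    from .roi import RoiTraceSet  # local import to avoid cycle

    p = params
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration * p.fs)) + 1
    t = np.arange(n) / p.fs
    n_resp = int(round(p.n_rois * p.responder_fraction))
    data: dict[str, np.ndarray] = {"t": t}
    truth: dict[str, float] = {}
    ramp = np.where(
        t >= p.stimulus_onset,
        1.0 - np.exp(-(t - p.stimulus_onset) / p.response_tau),
        0.0,
    )
    for i in range(p.n_rois):
        resp = p.response if i < n_resp else 0.0
        f0 = p.baseline_f * rng.uniform(0.8, 1.2)
        trace = p.background_f + f0 * (1.0 + resp * ramp)
        trace = trace + rng.normal(0.0, p.noise_sd, n)
        name = f"roi_{i:03d}"
        data[name] = trace
        truth[name] = resp
    data["background"] = p.background_f + rng.normal(0.0, p.noise_sd, n)
    traces = RoiTraceSet(
        data=pd.DataFrame(data), baseline_window=(0.0, p.stimulus_onset)
    )
    return traces, truth


# ---------------------------------------------------------------------------
# PET uptake tables


@dataclass(frozen=True)
class PetSynthParams:
    """Cohort of paired baseline/DMF PET measurements with known contrast.

    ``striatal_gain`` is the multiplicative DMF-over-baseline change in
    striatal uptake for the treated group (1.0 for controls); cerebellar
    uptake is condition-independent, as in a reference region.
    """

    n_animals: int = 8
    dose_MBq: float = 18.5  # ~500 uCi
    residual_MBq: float = 0.5
    weight_g: float = 25.0
    cerebellum_conc: float = 0.8  # MBq/ml
    striatum_ratio: float = 1.2  # striatum/cerebellum at baseline
    striatal_gain: float = 1.14
    noise_cv: float = 0.03
    seed: int = 0


def generate_pet_table(params: PetSynthParams) -> pd.DataFrame:
    """Long-form table: one row per animal x condition, in the input dialect
    of the PET quantification module."""
    p = params
    rng = np.random.default_rng(p.seed)
    rows = []
    for i in range(p.n_animals):
        base_cb = p.cerebellum_conc * rng.uniform(0.9, 1.1)
        base_st = base_cb * p.striatum_ratio
        for cond, gain in (("baseline", 1.0), ("DMF", p.striatal_gain)):
            noise = lambda: 1.0 + rng.normal(0.0, p.noise_cv)
            rows.append(
                {
                    "animal": f"m{i:02d}",
                    "condition": cond,
                    "c_striatum_L": base_st * gain * noise(),
                    "c_striatum_R": base_st * gain * noise(),
                    "c_cerebellum": base_cb * noise(),
                    "dose_initial_MBq": p.dose_MBq * rng.uniform(0.95, 1.05),
                    "dose_residual_MBq": p.residual_MBq * rng.uniform(0.8, 1.2),
                    "weight_g": p.weight_g * rng.uniform(0.9, 1.1),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cell images


@dataclass(frozen=True)
class CellImageSynthParams:
    """Three-channel (marker, c-fos, DAPI) synthetic section image.

    Somata are disks of ``cell_radius`` px; every cell appears in the marker
    and DAPI channels and ``round(n * positive_fraction)`` of them also in the
    c-fos channel.  Centers are placed by rejection sampling with a minimum
    separation so that blurring cannot merge neighbors.
    """

    image_size: tuple[int, int] = (512, 512)
    n_marker_cells: int = 50
    positive_fraction: float = 0.25
    cell_radius: int = 6
    min_separation: float | None = None  # default: 2*radius + 8 px
    foreground: int = 200
    background: int = 10
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.positive_fraction <= 1):
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.cell_radius < 2:
            raise ValueError("cell_radius must be at least 2 px")


@dataclass
class CellImageGroundTruth:
    centers: np.ndarray  # (n, 2) row, col
    positive: np.ndarray  # boolean, c-fos positive cells


def generate_cell_image(
    params: CellImageSynthParams,
) -> tuple[np.ndarray, CellImageGroundTruth]:
    """Returns (image stack (3, H, W) uint8 in order marker/cfos/dapi,
    ground truth).  Raises if the requested cells cannot be packed."""
    p = params
    rng = np.random.default_rng(p.seed)
    h, w = p.image_size
    sep = p.min_separation if p.min_separation is not None else 2 * p.cell_radius + 8
    margin = p.cell_radius + 2

    area_per_cell = np.pi * (sep / 2) ** 2
    if p.n_marker_cells * area_per_cell > 2.0 * (h - 2 * margin) * (w - 2 * margin):
        raise ValueError("impossible packing: too many cells for the image area")

    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < p.n_marker_cells:
        attempts += 1
        if attempts > 20000:
            raise ValueError("impossible packing: placement did not converge")
        r = rng.integers(margin, h - margin)
        c = rng.integers(margin, w - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= sep**2 for r0, c0 in centers):
            centers.append((int(r), int(c)))
    centers_arr = np.array(centers, dtype=int).reshape(-1, 2)

    n_pos = int(round(p.n_marker_cells * p.positive_fraction))
    positive = np.zeros(p.n_marker_cells, dtype=bool)
    if n_pos:
        positive[rng.choice(p.n_marker_cells, size=n_pos, replace=False)] = True

    yy, xx = np.mgrid[0:h, 0:w]

    def paint(mask_centers: np.ndarray, radius: float) -> np.ndarray:
        img = np.full((h, w), float(p.background))
        for r0, c0 in mask_centers:
            disk = (yy - r0) ** 2 + (xx - c0) ** 2 <= radius**2
            img[disk] = p.foreground
        return img

    marker = paint(centers_arr, p.cell_radius)
    cfos = paint(centers_arr[positive], p.cell_radius)
    dapi = paint(centers_arr, max(2, int(round(0.7 * p.cell_radius))))

    stack = np.stack([marker, cfos, dapi])
    if p.noise_sd > 0:
        stack = stack + rng.normal(0.0, p.noise_sd, stack.shape)
    stack = np.clip(np.round(stack), 0, 255).astype(np.uint8)
    return stack, CellImageGroundTruth(centers=centers_arr, positive=positive)
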