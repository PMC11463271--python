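"""Trajectory metrics: resampling arithmetic, freezing detection against a
brute-force oracle, ambulation closed forms, rotation counting, epochs."""

import numpy as np
import pandas as pd
import pytest

from magbehave import synthetic as syn
from magbehave.behavior import (
    Epoch,
    EpochSet,
    FreezeParams,
    KeypointTrack,
    ambulation_metrics,
    behavior_summary,
    count_rotations,
    detect_freezing,
    percent_change_rotations,
    resample_track,
    segment_epochs,
)

from conftest import make_track


# ---------------------------------------------------------------------------
# oracles


def brute_force_freezing(track, params: FreezeParams):
    """Independent scan: evaluate the static predicate step by step with
    explicit loops, then emit maximal runs meeting the duration threshold."""
    t = track.t
    dt = track.dt
    n = len(t)
    static = []
    for i in range(n - 1):
        ok = True
        for kp in params.keypoints_required:
            xy = track.xy(kp)
            dx = xy[i + 1, 0] - xy[i, 0]
            dy = xy[i + 1, 1] - xy[i, 1]
            d = (dx * dx + dy * dy) ** 0.5
            if not np.isfinite(d) or d > params.eps:
                ok = False
                break
        static.append(ok)
    bouts = []
    i = 0
    while i < len(static):
        if static[i]:
            j = i
            while j + 1 < len(static) and static[j + 1]:
                j += 1
            end = t[-1] + dt if j == len(static) - 1 else t[j] + dt
            if end - t[i] >= params.min_duration - 1e-9:
                bouts.append((t[i], end))
            i = j + 1
        else:
            i += 1
    return bouts


def brute_force_rotations(heading_series, threshold):
    acc, ccw, cw = 0.0, 0, 0
    for d in np.diff(np.unwrap(heading_series)):
        acc += d
        while acc >= threshold:
            ccw += 1
            acc -= threshold
        while acc <= -threshold:
            cw += 1
            acc += threshold
    return ccw, cw


# ---------------------------------------------------------------------------
# resampling


@pytest.mark.parametrize("seconds,expected", [(60, 150), (120, 300)])
def test_resample_five_hz_gives_150_samples_per_minute(seconds, expected):
    xy = np.zeros((seconds * 5, 2))
    track = make_track(xy, frame_rate=5.0)
    out = resample_track(track)
    assert out.n_samples == expected
    assert out.frame_rate == 2.5
    # timestamps are those of the retained frames
    assert np.allclose(out.t, track.t[::2])


def test_resample_passthrough_and_empty():
    track = make_track(np.zeros((10, 2)), frame_rate=2.5)
    assert resample_track(track) is track
    empty = KeypointTrack(
        data=track.data.iloc[:0].reset_index(drop=True), frame_rate=5.0
    )
    assert resample_track(empty).n_samples == 0


def test_resample_rejects_non_uniform_grid():
    track = make_track(np.zeros((20, 2)), frame_rate=5.0)
    data = track.data.copy()
    data.loc[10, "t"] += 0.15
    with pytest.raises(ValueError, match="uniform"):
        resample_track(KeypointTrack(data=data, frame_rate=5.0))


# ---------------------------------------------------------------------------
# freezing


def test_static_track_is_one_full_bout(static_track):
    bouts, total = detect_freezing(static_track, FreezeParams(eps=0.0))
    assert len(bouts) == 1
    assert total == pytest.approx(60.0)


def test_constant_velocity_track_has_no_bouts():
    # 5 cm/s at 2.5 Hz -> 2 cm per step, far above eps = 0.5
    xy = np.column_stack([np.arange(150) * 2.0, np.zeros(150)])
    track = make_track(xy)
    bouts, total = detect_freezing(track, FreezeParams(eps=0.5))
    assert bouts == [] and total == 0.0


def test_known_bouts_recovered_within_one_step():
    # static on [10, 13) and [40, 41.6), moving elsewhere
    rng = np.random.default_rng(0)
    n, dt = 150, 0.4
    t = np.arange(n) * dt
    xy = np.zeros((n, 2))
    pos = np.array([5.0, 5.0])
    for i in range(n):
        xy[i] = pos
        frozen = (10 <= t[i] < 13) or (40 <= t[i] < 41.6)
        if not frozen:
            pos = pos + rng.normal(0, 1.5, 2)
    track = make_track(xy)
    bouts, _ = detect_freezing(track, FreezeParams(eps=0.5))
    assert len(bouts) == 2
    for (ts, te), (gs, ge) in zip([(b.t_start, b.t_end) for b in bouts], [(10, 13), (40, 41.6)]):
        assert abs(ts - gs) <= dt + 1e-9
        assert abs(te - ge) <= dt + 1e-9


def test_detector_matches_brute_force_on_synthetic_tracks():
    params = FreezeParams()
    for seed in range(20):
        track, _ = syn.generate_track(
            syn.TrackSynthParams(duration=60, freeze_fraction=0.4, seed=seed)
        )
        r = resample_track(track)
        bouts, _ = detect_freezing(r, params)
        expected = brute_force_freezing(r, params)
        assert [(b.t_start, b.t_end) for b in bouts] == pytest.approx(expected)


def test_missing_keypoint_steps_are_non_static(static_track):
    data = static_track.data.copy()
    data.loc[70:75, "nose_x"] = np.nan  # mid-track dropout splits the bout
    track = KeypointTrack(data=data, frame_rate=2.5)
    bouts, total = detect_freezing(track, FreezeParams(eps=0.1))
    assert len(bouts) == 2
    assert total < 60.0


def test_all_missing_track_raises(static_track):
    data = static_track.data.copy()
    for c in data.columns:
        if c != "t":
            data[c] = np.nan
    with pytest.raises(ValueError, match="missing"):
        detect_freezing(KeypointTrack(data=data, frame_rate=2.5), FreezeParams())


# ---------------------------------------------------------------------------
# ambulation


def test_static_track_ambulation_zero(static_track):
    m = ambulation_metrics(static_track)
    assert m == {"ambulation_time": 0.0, "distance": 0.0, "activity_pct": 0.0}


def test_straight_line_distance_closed_form():
    # 10 cm/s for 60 s -> 600 cm, fully active
    xy = np.column_stack([np.arange(151) * 4.0, np.zeros(151)])
    m = ambulation_metrics(make_track(xy), speed_threshold=2.0)
    assert m["distance"] == pytest.approx(600.0)
    assert m["activity_pct"] == pytest.approx(100.0)
    assert m["ambulation_time"] == pytest.approx(60.0)


def test_ambulation_time_matches_generator_dwell():
    track, freezes = syn.generate_track(
        syn.TrackSynthParams(duration=120, freeze_fraction=0.5, jitter_sd=0.0, seed=3)
    )
    r = resample_track(track)
    m = ambulation_metrics(r, speed_threshold=2.0)
    true_amb = 120 - sum(b - a for a, b in freezes)
    # boundary quantization: one resampled step per state switch
    assert abs(m["ambulation_time"] - true_amb) <= (2 * len(freezes) + 1) * r.dt


def test_isometry_invariance():
    track, _ = syn.generate_track(
        syn.TrackSynthParams(duration=60, freeze_fraction=0.3, seed=7)
    )
    r = resample_track(track)
    theta = 0.7
    c, s = np.cos(theta), np.sin(theta)
    data = r.data.copy()
    for col in data.columns:
        if col == "t":
            continue
    xs = [c_ for c_ in data.columns if c_.endswith("_x")]
    for xcol in xs:
        ycol = xcol[:-2] + "_y"
        x, y = data[xcol].to_numpy(), data[ycol].to_numpy()
        data[xcol] = c * x - s * y + 50.0
        data[ycol] = s * x + c * y - 20.0
    moved = KeypointTrack(data=data, frame_rate=r.frame_rate)
    p = FreezeParams()
    assert detect_freezing(moved, p)[1] == pytest.approx(detect_freezing(r, p)[1])
    m0, m1 = ambulation_metrics(r), ambulation_metrics(moved)
    assert m1["distance"] == pytest.approx(m0["distance"])
    assert m1["activity_pct"] == pytest.approx(m0["activity_pct"])


# ---------------------------------------------------------------------------
# rotations


def test_spin_closed_forms():
    # 90 deg/s ccw for 60 s at 2.5 Hz
    n = 151
    heading = np.deg2rad(90) * np.arange(n) / 2.5
    track = make_track(np.tile([13.0, 13.0], (n, 1)), heading=heading)
    full = count_rotations(track, mode="full")
    assert full == {"rotations_cw": 0, "rotations_ccw": 15, "net": 15}
    quarter = count_rotations(track, mode="quarter")
    assert quarter["rotations_ccw"] == 60
    assert quarter["rotations_cw"] == 0


def test_reflection_swaps_cw_ccw():
    rng = np.random.default_rng(5)
    heading = np.cumsum(rng.normal(0, 0.5, 200))
    track = make_track(np.tile([13.0, 13.0], (200, 1)), heading=heading)
    mirrored = make_track(np.tile([13.0, 13.0], (200, 1)), heading=-heading)
    a = count_rotations(track, mode="quarter")
    b = count_rotations(mirrored, mode="quarter")
    assert a["rotations_cw"] == b["rotations_ccw"]
    assert a["rotations_ccw"] == b["rotations_cw"]


@pytest.mark.parametrize("mode", ["quarter", "full"])
def test_random_walk_matches_brute_force(mode):
    threshold = np.pi / 2 if mode == "quarter" else 2 * np.pi
    for seed in range(10):
        rng = np.random.default_rng(seed)
        heading = np.cumsum(rng.normal(0, 0.8, 300))
        track = make_track(np.tile([13.0, 13.0], (300, 1)), heading=heading)
        got = count_rotations(track, mode=mode)
        ccw, cw = brute_force_rotations(heading, threshold)
        assert (got["rotations_ccw"], got["rotations_cw"]) == (ccw, cw)


def test_lesion_side_sets_contralateral_sign():
    heading = -np.deg2rad(90) * np.arange(100) / 2.5  # clockwise spin
    track = make_track(np.tile([13.0, 13.0], (100, 1)), heading=heading)
    left = count_rotations(track, mode="full", lesion_side="left")
    right = count_rotations(track, mode="full", lesion_side="right")
    assert left["net_contralateral"] == left["rotations_cw"]
    assert right["net_contralateral"] == -right["rotations_cw"]


def test_percent_change_rotations():
    assert percent_change_rotations(100, 53) == pytest.approx(-47.0)
    assert percent_change_rotations(100, 100) == 0.0
    with pytest.raises(ZeroDivisionError):
        percent_change_rotations(0, 10)
    vals = [(120, 60), (80, 50), (200, 90)]
    group = [percent_change_rotations(p, d) for p, d in vals]
    assert np.mean(group) == pytest.approx(
        np.mean([100 * (d - p) / p for p, d in vals])
    )


# ---------------------------------------------------------------------------
# epochs


def test_epoch_slices_partition_track(static_track):
    epochs = EpochSet.session(["pre", "during", "post"], 20.0)
    parts = segment_epochs(static_track, epochs)
    assert sum(p.n_samples for p in parts.values()) == static_track.n_samples
    # random epochs: per-epoch counts equal per-sample membership
    eps = EpochSet([("a", 3.1, 11.7), ("b", 15.0, 42.2)])
    parts = segment_epochs(static_track, eps)
    t = static_track.t
    for ep in eps:
        assert parts[ep.label].n_samples == int(
            np.sum((t >= ep.t_start) & (t < ep.t_end))
        )


def test_epoch_outside_span_raises(static_track):
    with pytest.raises(ValueError, match="outside"):
        segment_epochs(static_track, EpochSet([("x", 50.0, 70.0)]))
    with pytest.raises(ValueError, match="overlap"):
        EpochSet([("a", 0, 10), ("b", 5, 15)])


def test_behavior_summary_conservation():
    track, _ = syn.generate_track(
        syn.TrackSynthParams(duration=180, freeze_fraction=0.4, seed=11)
    )
    epochs = EpochSet.session(["pre-DMF", "DMF", "post-DMF"], 60.0)
    for s in behavior_summary(track, epochs):
        assert s.freezing_time + s.ambulation_time <= s.duration + 1e-9
        assert 0.0 <= s.activity_pct <= 100.0
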