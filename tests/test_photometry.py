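"""Isosbestic fit, dF/F normalization, epoch means, event alignment."""

import numpy as np
import pytest

from magbehave import synthetic as syn
from magbehave.behavior import EpochSet
from magbehave.photometry import (
    PhotometrySession,
    align_to_events,
    compute_dff,
    epoch_means,
    fit_isosbestic,
)


def ols_normal_equations(x, y):
    """Closed-form OLS oracle: solve X'X b = X'y directly."""
    X = np.column_stack([x, np.ones_like(x)])
    slope, intercept = np.linalg.solve(X.T @ X, X.T @ y)
    return slope, intercept


def make_session(f465, f405, fs=100.0, events=None):
    t = np.arange(len(f465)) / fs
    return PhotometrySession(t=t, f465=f465, f405=f405, fs=fs, events=events)


# ---------------------------------------------------------------------------
# fit


def test_exact_linear_fit():
    f405 = np.linspace(1, 10, 200)
    f465 = 2.0 * f405 + 1.0
    slope, intercept, fitted = fit_isosbestic(f465, f405)
    assert slope == pytest.approx(2.0)
    assert intercept == pytest.approx(1.0)
    assert np.allclose(fitted, f465)


def test_independent_channels_give_near_zero_slope():
    rng = np.random.default_rng(0)
    f405 = rng.normal(10, 1, 20000)
    f465 = rng.normal(10, 1, 20000)
    slope, _, _ = fit_isosbestic(f465, f405)
    assert abs(slope) < 0.05


def test_fit_matches_normal_equation_oracle():
    rng = np.random.default_rng(1)
    for _ in range(10):
        f405 = rng.normal(50, 5, 500)
        f465 = rng.normal(50, 5, 500)
        slope, intercept, _ = fit_isosbestic(f465, f405)
        s2, i2 = ols_normal_equations(f405, f465)
        assert slope == pytest.approx(s2, abs=1e-10)
        assert intercept == pytest.approx(i2, abs=1e-10)


def test_constant_isosbestic_raises():
    with pytest.raises(ValueError, match="constant"):
        fit_isosbestic(np.arange(10.0), np.ones(10))


# ---------------------------------------------------------------------------
# dF/F


def test_constant_net_gives_zero_dff():
    # f465 carries a positive offset over a scaled f405: net is constant
    f405 = np.linspace(20, 30, 500)
    f465 = 1.5 * f405 + 10.0
    trace = compute_dff(make_session(f465, f405), lowpass_hz=None)
    assert np.allclose(trace.dff, 0.0, atol=1e-9)


def test_dff_median_is_zero_by_construction():
    session, _ = syn.generate_photometry(syn.PhotometrySynthParams(seed=3))
    trace = compute_dff(session)
    assert np.median(trace.dff) == pytest.approx(0.0, abs=1e-9)


def test_artifact_rejected_from_dff():
    p = syn.PhotometrySynthParams(n_transients=0, seed=4)
    session, truth = syn.generate_photometry(p)
    trace = compute_dff(session)
    corr_raw = np.corrcoef(session.f465, truth.artifact)[0, 1]
    corr_dff = np.corrcoef(trace.dff, truth.artifact)[0, 1]
    assert abs(corr_raw) > 0.5
    assert abs(corr_dff) < 0.1


def test_transient_peaks_recovered_at_injected_times():
    p = syn.PhotometrySynthParams(
        n_transients=6, transient_amplitude=8.0, noise_sd=0.05, seed=5
    )
    session, truth = syn.generate_photometry(p)
    trace = compute_dff(session)
    for t0 in truth.transient_times:
        # local dff peak within one kernel rise of the injected time
        t_peak_expected = t0 + 0.5 * np.log(5.0)  # kernel argmax offset
        w = (trace.t > t0 - 1.0) & (trace.t < t0 + 3.0)
        t_found = trace.t[w][np.argmax(trace.dff[w])]
        assert abs(t_found - t_peak_expected) < 0.5


def test_common_rescaling_invariance():
    p = syn.PhotometrySynthParams(n_transients=0, noise_sd=0.0, seed=6)
    session, _ = syn.generate_photometry(p)
    scaled = PhotometrySession(
        t=session.t, f465=3.0 * session.f465, f405=3.0 * session.f405, fs=session.fs
    )
    a = compute_dff(session)
    b = compute_dff(scaled)
    assert np.allclose(a.dff, b.dff, atol=1e-6)


# ---------------------------------------------------------------------------
# epoch means


def test_epoch_means_closed_forms():
    fs = 50.0
    n = int(90 * fs)
    t = np.arange(n) / fs
    dff = np.where(t >= 30.0, 5.0, 0.0)
    dff = np.where(t >= 60.0, 0.0, dff)
    trace = compute_dff(
        make_session(np.ones(n) * 10 + 0.0, np.linspace(1, 2, n), fs=fs),
        lowpass_hz=None,
    )
    # overwrite with a step function to isolate epoch averaging
    trace.dff = dff
    means = epoch_means(trace, EpochSet.session(["pre", "DMF", "post"], 30.0))
    assert means["pre"] == pytest.approx(0.0)
    assert means["DMF"] == pytest.approx(5.0)
    assert means["post"] == pytest.approx(0.0)
    with pytest.raises(ValueError, match="no samples"):
        epoch_means(trace, EpochSet([("late", 500.0, 600.0)]))


def test_epoch_means_match_per_sample_average():
    session, _ = syn.generate_photometry(syn.PhotometrySynthParams(seed=7))
    trace = compute_dff(session)
    eps = EpochSet([("a", 10.0, 55.5), ("b", 100.0, 201.0)])
    means = epoch_means(trace, eps)
    for ep in eps:
        mask = (trace.t >= ep.t_start) & (trace.t < ep.t_end)
        assert means[ep.label] == pytest.approx(trace.dff[mask].mean())


# ---------------------------------------------------------------------------
# event alignment


def test_single_event_zero_trace():
    trace = compute_dff(
        make_session(np.linspace(10, 11, 1000) * 2 + 3, np.linspace(10, 11, 1000)),
        lowpass_hz=None,
    )
    trace.dff = np.zeros_like(trace.dff)
    _, trials, mean = align_to_events(trace, np.array([5.0]), pre_s=1, post_s=2)
    assert trials.shape[0] == 1
    assert np.allclose(mean, 0.0)


def test_identical_events_mean_equals_single_row():
    session, _ = syn.generate_photometry(syn.PhotometrySynthParams(seed=8))
    trace = compute_dff(session)
    events = np.full(10, 120.0)
    _, trials, mean = align_to_events(trace, events, pre_s=2, post_s=5)
    assert np.allclose(mean, trials[0])


def test_out_of_session_events_dropped_and_empty_raises():
    session, _ = syn.generate_photometry(
        syn.PhotometrySynthParams(duration=60, seed=9)
    )
    trace = compute_dff(session)
    with pytest.warns(UserWarning, match="dropped"):
        _, trials, _ = align_to_events(
            trace, np.array([0.5, 30.0]), pre_s=2, post_s=5
        )
    assert trials.shape[0] == 1
    with pytest.raises(ValueError, match="retained"):
        align_to_events(trace, np.array([0.5]), pre_s=2, post_s=5)


def test_event_locked_amplitude_recovery():
    """Mean event-aligned response recovers the injected kernel amplitude."""
    p = syn.PhotometrySynthParams(
        duration=520.0, transient_amplitude=6.0, noise_sd=0.3, seed=10
    )
    events = np.arange(50) * 10.0 + 10.0
    session, truth = syn.generate_photometry(
        p, transient_times=events, events=events
    )
    trace = compute_dff(session)
    _, _, mean = align_to_events(trace, events, pre_s=2.0, post_s=6.0)
    recovered = mean.max() / 100.0 * trace.denominator
    assert recovered == pytest.approx(6.0, rel=0.1)
    # mean trace shape correlates with the injected kernel
    tt = np.arange(len(mean)) / p.fs - 2.0
    kernel = syn.transient_kernel(tt, p.transient_rise, p.transient_decay, 1.0)
    assert np.corrcoef(mean, kernel)[0, 1] > 0.95
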