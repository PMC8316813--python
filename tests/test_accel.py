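"""Unit and property tests for accelerometry processing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from troopsim import accel as acc
from troopsim.core import AccelSeries

FS = 12


def _gait_signal(rng, f_hz=2.0, duration=600, amplitude=3.0, noise=0.2):
    t = np.arange(duration * FS) / FS
    return 9.81 + amplitude * np.sin(2 * np.pi * f_hz * t) + rng.normal(
        0, noise, len(t))


def _add_spikes(x, rng, n=40, magnitude=10.0):
    idx = np.sort(rng.choice(np.arange(1, len(x) - 1), size=n, replace=False))
    idx = idx[np.concatenate([[True], np.diff(idx) > 2 * 24 + 1])]
    x = x.copy()
    x[idx] += magnitude * np.std(x) * rng.choice([-1, 1], len(idx))
    return x, idx


# ---------------------------------------------------------------------------
# Hampel filter

def test_hampel_recall_and_false_rate_on_gait():
    rng = np.random.default_rng(0)
    clean = _gait_signal(rng, duration=1200)
    spiked, idx = _add_spikes(clean, rng, n=60)
    out, mask = acc.hampel_filter(spiked, return_mask=True)
    recall = np.isin(idx, np.flatnonzero(mask)).mean()
    assert recall >= 0.95
    false = np.setdiff1d(np.flatnonzero(mask), idx)
    assert len(false) / len(spiked) < 0.01
    # replaced values are pulled back to the local signal scale
    assert np.all(np.abs(out[idx] - clean[idx]) < np.abs(spiked[idx] - clean[idx]))


def test_hampel_false_rate_on_stationary_noise():
    rng = np.random.default_rng(1)
    x = 9.81 + rng.normal(0, 0.2, 20000)
    _, mask = acc.hampel_filter(x, return_mask=True)
    assert mask.mean() < 0.01


def test_hampel_idempotent_on_despiked_gait():
    rng = np.random.default_rng(2)
    spiked, _ = _add_spikes(_gait_signal(rng), rng)
    once = acc.hampel_filter(spiked)
    twice = acc.hampel_filter(once)
    assert np.array_equal(once, twice)


def test_hampel_second_pass_bounded_on_noise():
    # on pure noise a second pass may re-flag a few samples (the first pass
    # shrinks the local MAD) but never more than the false-alarm budget
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 20000)
    once = acc.hampel_filter(x)
    twice = acc.hampel_filter(once)
    assert np.mean(once != twice) < 0.01


def test_hampel_preserves_nans_and_warns_when_short():
    rng = np.random.default_rng(4)
    x = _gait_signal(rng, duration=60)
    x[100:200] = np.nan
    out, mask = acc.hampel_filter(x, return_mask=True)
    assert np.isnan(out[100:200]).all()
    assert not mask[100:200].any()
    with pytest.warns(UserWarning):
        acc.hampel_filter(np.ones(10))


def test_hampel_rejects_bad_params():
    with pytest.raises(ValueError):
        acc.hampel_filter(np.ones(100), half_window=0)
    with pytest.raises(ValueError):
        acc.hampel_filter(np.ones(100), n_mad=0)


def test_despike_filters_all_axes():
    rng = np.random.default_rng(5)
    h, idx = _add_spikes(_gait_signal(rng), rng, n=20)
    t = np.arange(len(h)) / FS
    s = AccelSeries(t, h.copy(), h.copy(), h.copy())
    clean = acc.despike(s)
    for axis in (clean.surge, clean.sway, clean.heave):
        assert np.max(np.abs(axis[idx])) < np.max(np.abs(h[idx]))


# ---------------------------------------------------------------------------
# stride frequency

@pytest.mark.parametrize("f_true", [1.0, 1.5, 2.0, 2.5, 3.0])
def test_stride_frequency_sweep(f_true):
    rng = np.random.default_rng(int(f_true * 10))
    h = _gait_signal(rng, f_hz=f_true, duration=300)
    est = acc.estimate_stride_frequency(h)
    med = np.nanmedian(est["stride_hz"])
    assert abs(med - f_true) <= 0.1


def test_stride_frequency_nan_on_noise():
    rng = np.random.default_rng(8)
    h = 9.81 + rng.normal(0, 0.2, 300 * FS)
    est = acc.estimate_stride_frequency(h)
    assert np.isnan(est["stride_hz"]).all()


def test_peak_detection_counts():
    rng = np.random.default_rng(9)
    h = _gait_signal(rng, f_hz=2.0, duration=100)
    peaks = acc.detect_gait_peaks(h)
    # one peak per stride cycle
    assert abs(len(peaks) - 200) <= 2
    # refined peak times are strictly increasing and respect min separation
    assert np.all(np.diff(peaks) > 0.2)


# ---------------------------------------------------------------------------
# VeDBA

def test_vedba_gravity_only_near_zero():
    n = 600 * FS
    heave = np.full(n, 9.81)
    zeros = np.zeros(n)
    sample, second = acc.compute_vedba(zeros, zeros, heave)
    assert np.nanmax(sample) == pytest.approx(0.0, abs=1e-12)
    assert np.nanmax(second) == pytest.approx(0.0, abs=1e-12)


def test_vedba_sine_closed_form():
    # mean |A sin| = 2A/pi; tested at an incommensurate frequency so the
    # 12 Hz sampling equidistributes the phase
    A, f = 3.0, 1.9
    t = np.arange(600 * FS) / FS
    heave = 9.81 + A * np.sin(2 * np.pi * f * t)
    zeros = np.zeros(len(t))
    _, second = acc.compute_vedba(zeros, zeros, heave)
    expected = 2 * A / np.pi
    assert np.nanmean(second[2:-2]) == pytest.approx(expected, rel=0.05)


@given(scale=hst.floats(0.5, 3.0))
@settings(max_examples=20, deadline=None)
def test_vedba_scales_linearly(scale):
    rng = np.random.default_rng(12)
    t = np.arange(60 * FS) / FS
    base = np.sin(2 * np.pi * 2.1 * t)
    zeros = np.zeros(len(t))
    _, v1 = acc.compute_vedba(zeros, zeros, 9.81 + base)
    _, v2 = acc.compute_vedba(zeros, zeros, 9.81 + scale * base)
    assert np.nanmean(v2) == pytest.approx(scale * np.nanmean(v1), rel=1e-6)


# ---------------------------------------------------------------------------
# activity classification

def _labelled_day(seed, duration=1200):
    rng = np.random.default_rng(seed)
    moving = np.zeros(duration, dtype=bool)
    # alternate 120 s stationary / 120 s moving
    for a in range(120, duration, 240):
        moving[a:a + 120] = True
    f_sec = np.where(moving, 2.0, 0.0)
    phase = np.cumsum(np.repeat(f_sec, FS) / FS)
    active = np.repeat(moving, FS)
    n = duration * FS
    heave = 9.81 + 3.0 * np.sin(2 * np.pi * phase) * active + rng.normal(0, 0.2, n)
    surge = 1.2 * np.cos(2 * np.pi * phase) * active + rng.normal(0, 0.2, n)
    sway = 0.75 * np.sin(2 * np.pi * phase + 1) * active + rng.normal(0, 0.2, n)
    series = AccelSeries(np.arange(n) / FS, surge, sway, heave)
    return series, moving


def test_threshold_classifier_accuracy():
    series, truth = _labelled_day(13)
    feats = acc.activity_features(series)
    pred = acc.classify_activity(feats)["moving"].to_numpy()
    assert (pred == truth).mean() >= 0.95


def test_svm_classifier_beats_chance_and_generalises():
    s_train, y_train = _labelled_day(14)
    s_test, y_test = _labelled_day(15)
    clf = acc.train_activity_classifier(acc.activity_features(s_train), y_train)
    pred = acc.classify_activity(acc.activity_features(s_test),
                                 model=clf)["moving"].to_numpy()
    assert (pred == y_test).mean() >= 0.95


def test_gravity_only_classified_stationary():
    rng = np.random.default_rng(16)
    n = 300 * FS
    series = AccelSeries(np.arange(n) / FS, rng.normal(0, 0.2, n),
                         rng.normal(0, 0.2, n), 9.81 + rng.normal(0, 0.2, n))
    pred = acc.classify_activity(acc.activity_features(series))
    assert pred["moving"].mean() < 0.05


def test_classification_flags_missing_seconds():
    series, _ = _labelled_day(17, duration=300)
    series.heave[100 * FS:110 * FS] = np.nan
    series.surge[100 * FS:110 * FS] = np.nan
    series.sway[100 * FS:110 * FS] = np.nan
    feats = acc.activity_features(series)
    pred = acc.classify_activity(feats)
    assert np.isnan(pred["moving"].to_numpy()[100:110]).all()
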