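"""Tests for the synthetic troop / day / accelerometry generator."""

import numpy as np
import pytest

from troopsim import cohesion as coh
from troopsim import synthetic as syn
from troopsim.stats import pearson_corr


# ---------------------------------------------------------------------------
# troop

def test_troop_size_and_leg_range(troop):
    assert len(troop) == 25
    leg = np.array([i.leg_length for i in troop])
    assert leg.min() >= 31.0 and leg.max() <= 51.0


def test_troop_frequency_bounds(troop):
    f = np.array([i.f_char_true for i in troop])
    assert np.all((f > 0.5) & (f < 4.0))


def test_troop_speed_consistent_with_gait(troop):
    for ind in troop:
        v = coh.characteristic_speed(ind.f_char_true, ind.leg_length)
        assert ind.v_char_true == pytest.approx(v)


def test_troop_correlation_calibration():
    # across seeds the mean f/leg correlation matches the -0.53 target
    rs = []
    for seed in range(20):
        t = syn.make_troop(syn.TroopConfig(seed=seed))
        leg = np.array([i.leg_length for i in t])
        f = np.array([i.f_char_true for i in t])
        rs.append(pearson_corr(f, leg)[0])
    assert abs(np.mean(rs) - (-0.53)) < 0.15
    assert all(r < 0 for r in rs)


def test_troop_deterministic():
    t1 = syn.make_troop(syn.TroopConfig(seed=42))
    t2 = syn.make_troop(syn.TroopConfig(seed=42))
    assert [i.leg_length for i in t1] == [i.leg_length for i in t2]


def test_troop_config_validation():
    with pytest.raises(ValueError):
        syn.TroopConfig(n_individuals=0)
    with pytest.raises(ValueError):
        syn.TroopConfig(leg_length_range=(51.0, 31.0))
    with pytest.raises(ValueError):
        syn.TroopConfig(leg_length_mean=20.0)


# ---------------------------------------------------------------------------
# schedule

def test_schedule_alternates_and_fits_daylight():
    sched = syn.make_day_schedule(seed=0, total_duration=12 * 3600)
    assert sched.total_duration <= 12 * 3600
    states = [s.state for s in sched.segments]
    assert all(a != b for a, b in zip(states, states[1:]))
    for s in sched.segments:
        assert s.duration > 0
        if s.state == "travel":
            assert s.heading is not None
            assert np.hypot(*s.heading) == pytest.approx(1.0)


def test_schedule_travel_duration_calibration():
    # pooled travel durations over many schedule draws: mean near 26 min
    durs = []
    for seed in range(40):
        sched = syn.make_day_schedule(seed=seed, total_duration=12 * 3600)
        durs += [s.duration for s in sched.segments
                 if s.state == "travel" and s.duration >= 240]
    assert np.mean(durs) / 60 == pytest.approx(26.0, abs=6.0)


def test_schedule_validation():
    with pytest.raises(ValueError):
        syn.DaySchedule([syn.Segment("stationary", 13 * 3600)])
    with pytest.raises(ValueError):
        syn.DaySchedule([syn.Segment("travel", 600)])  # no heading
    with pytest.raises(ValueError):
        syn.DaySchedule([syn.Segment("stationary", 0)])


# ---------------------------------------------------------------------------
# day simulation

def test_stationary_only_day_centroid_still(troop):
    sched = syn.DaySchedule([syn.Segment("stationary", 1200)],
                            gps_noise_sd=0.0)
    motion = syn.MotionParams(burst_prob=0.0, n_solo_per_individual=0)
    tracks, labels = syn.simulate_day(troop, sched, motion, seed=1)
    centroid = np.nanmean(labels.true_xy, axis=0)
    disp = np.linalg.norm(centroid[-1] - centroid[0])
    assert disp < 1.0
    assert not labels.moving.any()


def test_travel_day_moves_centroid(troop):
    heading = (1.0, 0.0)
    sched = syn.DaySchedule([syn.Segment("travel", 600, "I", heading)],
                            gps_noise_sd=0.0)
    tracks, labels = syn.simulate_day(troop, sched, syn.MotionParams(), seed=2)
    centroid = np.nanmean(labels.true_xy, axis=0)
    dx = centroid[-1] - centroid[0]
    v_mean = np.mean([i.v_char_true for i in troop])
    # pauses reduce but do not redirect travel
    assert dx[0] > 0.3 * v_mean * 600
    assert abs(dx[1]) < 0.1 * abs(dx[0])


def test_solo_windows_have_quiet_groupmates(short_day):
    _, labels, _ = short_day
    assert len(labels.solo_windows) > 0
    for ind, a, b in labels.solo_windows:
        others = np.delete(labels.moving, ind, axis=0)
        assert not others[:, a:b].any()
        assert labels.moving[ind, a:b].mean() > 0.9


def test_every_individual_gets_a_solo_window(short_day):
    _, labels, _ = short_day
    assert {w[0] for w in labels.solo_windows} == set(range(25))


def test_true_stride_matches_speed(short_day, troop):
    _, labels, sched = short_day
    leg = np.array([i.leg_length for i in troop])
    moving = labels.moving
    # f = v / (kappa * leg_m): check on the true positions; the first second
    # of each segment is excluded (positions re-anchor across the boundary)
    boundaries = set(np.cumsum([0] + [s.duration for s in sched.segments]))
    disp = np.linalg.norm(np.diff(labels.true_xy, axis=1), axis=2)
    for i in (0, 12, 24):
        sel = moving[i, 1:].copy()
        sel[[t - 1 for t in boundaries if 1 <= t <= len(sel)]] = False
        if not sel.any():
            continue
        f_from_track = disp[i][sel] / (1.3 * leg[i] / 100)
        assert np.allclose(f_from_track, labels.true_stride[i, 1:][sel],
                           atol=1e-6)


def test_gps_noise_magnitude(short_day):
    tracks, labels, sched = short_day
    resid = tracks.xy - labels.true_xy
    assert np.nanstd(resid) == pytest.approx(sched.gps_noise_sd, rel=0.05)


def test_travel_spread_band_rule_iii(troop):
    # travel under rule III: long-run group spread respects the 1D band
    motion = syn.MotionParams(g=0.05, T=80.0, pause_base=0.0,
                              pause_ahead=0.0, pause_behind=0.0,
                              n_solo_per_individual=0)
    sched = syn.DaySchedule([syn.Segment("travel", 3000, "III", (1.0, 0.0))],
                            gps_noise_sd=0.0)
    _, labels = syn.simulate_day(troop, sched, motion, seed=3)
    x = labels.true_xy[:, :, 0]
    spread = x.max(axis=0) - x.min(axis=0)
    v = np.array([i.v_char_true for i in troop])
    hi = motion.T + (v.max() - v.min()) / motion.g
    post = spread[600:]
    assert np.mean((post >= 0.8 * motion.T) & (post <= hi)) >= 0.95


def test_simulate_day_requires_troop():
    with pytest.raises(ValueError):
        syn.simulate_day([], syn.make_day_schedule(seed=0, total_duration=600))


# ---------------------------------------------------------------------------
# accelerometry synthesis

def test_stationary_accel_is_gravity_plus_noise(troop):
    params = syn.AccelParams()
    xy = np.zeros((600, 2))
    series = syn.synth_accel(xy, troop[0], params, seed=4)
    # no gait excursion: extremes stay at the noise scale (5 sigma over
    # 7200 samples), far below the footfall amplitude
    assert np.nanmax(series.heave) < 9.81 + 5 * params.noise_sd
    assert np.nanmin(series.heave) > 9.81 - 5 * params.noise_sd
    assert np.nanstd(series.heave) == pytest.approx(params.noise_sd, rel=0.1)
    assert len(series.heave) == 600 * 12


def test_moving_accel_oscillates_at_stride(troop):
    params = syn.AccelParams()
    stride = np.full(300, 2.0)
    xy = np.zeros((300, 2))
    series = syn.synth_accel(xy, troop[0], params, seed=5, stride_hz=stride)
    from troopsim.accel import estimate_stride_frequency
    est = estimate_stride_frequency(series.heave)
    assert np.nanmedian(est["stride_hz"]) == pytest.approx(2.0, abs=0.05)


def test_accel_missing_where_gps_missing(troop):
    xy = np.zeros((120, 2))
    xy[30:40] = np.nan
    series = syn.synth_accel(xy, troop[0], syn.AccelParams(), seed=6)
    assert np.isnan(series.heave[30 * 12:40 * 12]).all()
    assert not np.isnan(series.heave[:30 * 12]).any()


def test_inject_artifacts_spikes_and_dropouts(troop):
    xy = np.zeros((1200, 2))
    series = syn.synth_accel(xy, troop[0], syn.AccelParams(), seed=7)
    out, art = syn.inject_artifacts(series, spike_rate=2.0, dropout_rate=0.05,
                                    seed=8)
    idx = art["spikes"]
    assert len(idx) > 0
    # spikes are isolated and large
    assert np.all(np.diff(idx) > 1)
    sd = np.nanstd(series.heave)
    # dropouts may erase some spikes; the surviving ones are large
    visible = idx[~np.isnan(out.heave[idx])]
    assert len(visible) > 0
    assert np.all(np.abs(out.heave[visible] - series.heave[visible]) > 5 * sd)
    lost = np.isnan(out.heave).sum()
    assert lost >= 0.04 * len(out.heave)
    # original untouched
    assert not np.isnan(series.heave).any()


def test_inject_artifacts_validation(troop):
    xy = np.zeros((60, 2))
    series = syn.synth_accel(xy, troop[0], syn.AccelParams(), seed=9)
    with pytest.raises(ValueError):
        syn.inject_artifacts(series, spike_rate=-1.0)
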