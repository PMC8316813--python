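"""Seeded synthetic troops, GPS tracks, accelerometry and ground truth.

Emulates the statistical structure of a GPS + accelerometer biologging study
of a wild olive-baboon troop: ~25 individuals with leg lengths spanning
31-51 cm, characteristic stride frequency negatively correlated with leg
length (target r = -0.53), days alternating stationary periods with
collective travel bouts (mean ~26 min, heavily right-skewed), footfall-
structured heave-axis acceleration at 12 Hz, GPS jitter, collar dropouts
and collar-strike spikes. Every stream is paired with ground-truth labels
so the downstream pipeline is testable without field data.

During travel the troop follows the 1D cohesion engine embedded along the
segment heading, with an intermittent-locomotion (move/pause) layer: the
pause probability is piecewise-constant in the signed separation from the
rest of the group, stepping at +20 m (ahead) and -40 m (behind) by default,
and smaller individuals pause less. During stationary periods individuals
hold position apart from small bursts and scheduled solo-movement windows
in which one animal walks at its characteristic speed while all group-mates
are still -- the windows from which characteristic stride frequency is
estimable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import ACCEL_HZ, GRAVITY, AccelSeries, TrackSet, rng_from_seed
from .cohesion import characteristic_speed


# ---------------------------------------------------------------------------
# troop generation

@dataclass
class Individual:
    id: str
    leg_length: float               # cm
    f_char_true: float              # Hz
    v_char_true: float              # m/s
    age_class: str = "adult"


@dataclass
class TroopConfig:
    """Calibration of the synthetic troop.

    Defaults reproduce the study troop's morphometrics: 25 individuals,
    leg length mean 38 cm on 31-51 cm, and a stride-frequency/leg-length
    correlation of about -0.53 (slope -0.04 Hz/cm with 0.23 Hz residual
    noise against a leg-length s.d. of ~3.6 cm).
    """

    n_individuals: int = 25
    leg_length_mean: float = 38.0
    leg_length_range: tuple = (31.0, 51.0)
    freq_leg_slope: float = -0.04     # Hz per cm, negative
    freq_noise_sd: float = 0.23       # Hz
    f_mean: float = 2.0               # Hz at the mean leg length
    target_corr: float = -0.53
    kappa: float = 1.3                # speed = kappa * f * leg_m
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.leg_length_range
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not lo < hi:
            raise ValueError("empty leg_length_range")
        if not lo <= self.leg_length_mean <= hi:
            raise ValueError("leg_length_mean outside range")


def make_troop(config: TroopConfig | None = None, seed=None) -> list:
    """Draw a troop of individuals; deterministic given the config seed."""
    config = config or TroopConfig()
    rng = rng_from_seed(config.seed if seed is None else seed)
    lo, hi = config.leg_length_range
    frac = (config.leg_length_mean - lo) / (hi - lo)
    conc = 6.0   # beta concentration: keeps the sample inside the range
    leg = lo + (hi - lo) * rng.beta(frac * conc, (1 - frac) * conc,
                                    size=config.n_individuals)
    f = (config.f_mean
         + config.freq_leg_slope * (leg - config.leg_length_mean)
         + rng.normal(0.0, config.freq_noise_sd, size=config.n_individuals))
    f = np.clip(f, 0.5 + 1e-6, 4.0 - 1e-6)
    v = characteristic_speed(f, leg, config.kappa)
    order = np.argsort(leg)
    age = np.full(config.n_individuals, "adult", dtype=object)
    # annotation only: smallest individuals juvenile, mid-sized subadult
    n = config.n_individuals
    age[order[: max(0, round(0.08 * n))]] = "juvenile"
    age[order[max(0, round(0.08 * n)): max(0, round(0.48 * n))]] = "subadult"
    return [
        Individual(f"ind{i:02d}", float(leg[i]), float(f[i]), float(v[i]),
                   str(age[i]))
        for i in range(config.n_individuals)
    ]


# ---------------------------------------------------------------------------
# day schedule

@dataclass
class Segment:
    state: str                       # "stationary" | "travel"
    duration: int                    # s
    rule: str = "I"                  # cohesion rule during travel
    heading: tuple | None = None     # unit vector, travel only


@dataclass
class DaySchedule:
    segments: list
    gps_noise_sd: float = 1.0
    day_start: float = 6.0           # clock hours
    day_end: float = 18.0

    def __post_init__(self):
        total = sum(s.duration for s in self.segments)
        if total > (self.day_end - self.day_start) * 3600 + 1e-9:
            raise ValueError("schedule longer than the daylight window")
        for s in self.segments:
            if s.duration <= 0:
                raise ValueError("segment durations must be positive")
            if s.state == "travel" and s.heading is None:
                raise ValueError("travel segments need a heading")

    @property
    def total_duration(self) -> int:
        return int(sum(s.duration for s in self.segments))


def make_day_schedule(seed=0, total_duration: int | None = None,
                      travel_rule: str = "I",
                      travel_mean: float = 26 * 60.0,
                      travel_sd: float = 19.6 * 60.0,
                      travel_min: float = 240.0,
                      stationary_mean: float = 5400.0,
                      stationary_sd: float = 2700.0,
                      stationary_min: float = 600.0,
                      gps_noise_sd: float = 1.0) -> DaySchedule:
    """Alternating stationary/travel schedule with lognormal durations.

    Travel-bout durations are calibrated to a mean of 26 min with an s.d.
    of ~19.6 min (a strongly right-skewed distribution); stationary gaps are
    sized so a full 12 h day holds roughly six travel bouts and the centroid
    covers ~7 km.
    """
    rng = rng_from_seed(seed)
    total = int(total_duration or 12 * 3600)

    def _lognormal(mean, sd, floor):
        s2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - s2 / 2
        return max(floor, float(rng.lognormal(mu, np.sqrt(s2))))

    segments, elapsed, state = [], 0, "stationary"
    while elapsed < total:
        if state == "stationary":
            dur = _lognormal(stationary_mean, stationary_sd, stationary_min)
            seg = Segment("stationary", int(min(dur, total - elapsed)))
        else:
            dur = _lognormal(travel_mean, travel_sd, travel_min)
            ang = rng.uniform(0, 2 * np.pi)
            seg = Segment("travel", int(min(dur, total - elapsed)), travel_rule,
                          (float(np.cos(ang)), float(np.sin(ang))))
        if seg.duration > 0:
            segments.append(seg)
        elapsed += seg.duration
        state = "travel" if state == "stationary" else "stationary"
    return DaySchedule(segments, gps_noise_sd=gps_noise_sd)


# ---------------------------------------------------------------------------
# day simulation

@dataclass
class MotionParams:
    """Tunable motion model for the synthetic day."""

    speed_noise_sd: float = 0.1      # m/s, per-second travel speed noise
    g: float = 0.05                  # 1/s, cohesion gain (rules II/III)
    T: float = 80.0                  # m, spread threshold (rule III)
    pause_base: float = 0.25         # baseline per-second pause probability
    pause_leg_coef: float = 0.012    # pause prob increase per cm of leg
    pause_ahead: float = 0.7         # pause prob beyond ahead_break
    pause_behind: float = 0.05       # pause prob beyond behind_break
    ahead_break: float = 20.0        # m ahead of rest-of-group
    behind_break: float = -40.0      # m behind rest-of-group
    burst_prob: float = 0.05         # stationary-period burst probability
    burst_speed: float = 0.3         # m/s, stays below the moving threshold
    solo_duration: int = 60          # s per solo-movement window
    n_solo_per_individual: int = 1
    solo_speed_noise: float = 0.05   # m/s
    lateral_sd: float = 4.0          # m, fixed lateral offsets during travel
    kappa: float = 1.3


@dataclass
class TrueLabels:
    """Ground truth aligned with the generated tracks."""

    moving: np.ndarray          # (N, T) bool, per-individual per-second
    group_moving: np.ndarray    # (T,) bool
    true_stride: np.ndarray     # (N, T) Hz, NaN when not moving
    solo_windows: list          # (individual index, start s, end s)
    true_xy: np.ndarray         # (N, T, 2) noise-free positions
    spike_indices: dict = field(default_factory=dict)
    dropout_spans: dict = field(default_factory=dict)


def _allocate_solo_windows(schedule: DaySchedule, n_individuals: int,
                           params: MotionParams, rng) -> list:
    """Non-overlapping solo windows inside stationary segments, round-robin.

    Ensures (capacity permitting) each individual gets its configured number
    of windows; windows never overlap, so during any window every other
    individual is stationary.
    """
    slots = []
    offset = 0
    gap = 10
    for seg in schedule.segments:
        if seg.state == "stationary":
            t = offset + gap
            while t + params.solo_duration + gap <= offset + seg.duration:
                slots.append((t, t + params.solo_duration))
                t += params.solo_duration + gap
        offset += seg.duration
    order = rng.permutation(len(slots))
    windows, counts = [], np.zeros(n_individuals, dtype=int)
    need = params.n_solo_per_individual
    ind_cycle = list(rng.permutation(n_individuals))
    k = 0
    for slot_i in order:
        if counts.min() >= need:
            break
        while counts[ind_cycle[k % n_individuals]] >= need:
            k += 1
        ind = ind_cycle[k % n_individuals]
        k += 1
        counts[ind] += 1
        windows.append((int(ind), *slots[slot_i]))
    return sorted(windows, key=lambda w: w[1])


def _pause_probs(sep, leg_lengths, p: MotionParams):
    base = np.clip(p.pause_base + p.pause_leg_coef * (leg_lengths - 38.0),
                   0.02, 0.9)
    probs = np.where(sep > p.ahead_break, p.pause_ahead,
                     np.where(sep < p.behind_break, p.pause_behind, base))
    return probs


def simulate_day(troop, schedule: DaySchedule, motion: MotionParams | None = None,
                 seed=0):
    """Simulate a troop's day: 1 Hz GPS tracks plus ground-truth labels.

    Returns ``(TrackSet, TrueLabels)``. Observed positions carry isotropic
    Gaussian GPS noise (``schedule.gps_noise_sd``); ``TrueLabels.true_xy``
    holds the noise-free positions.
    """
    if not troop:
        raise ValueError("empty troop")
    motion = motion or MotionParams()
    rng = rng_from_seed(seed)
    n = len(troop)
    leg = np.array([ind.leg_length for ind in troop])
    v_char = np.array([ind.v_char_true for ind in troop])
    total = schedule.total_duration

    xy = np.zeros((n, total, 2))
    moving = np.zeros((n, total), dtype=bool)
    group_moving = np.zeros(total, dtype=bool)
    speed = np.zeros((n, total))

    solo = _allocate_solo_windows(schedule, n, motion, rng)
    solo_by_second = {}
    for ind, a, b in solo:
        for t in range(a, b):
            solo_by_second[t] = ind

    # initial spatial configuration: loose cluster
    cur = rng.normal(0.0, 8.0, size=(n, 2))
    t0 = 0
    for seg in schedule.segments:
        t1 = t0 + seg.duration
        if seg.state == "stationary":
            anchors = cur.copy()
            pos = np.repeat(anchors[:, None, :], seg.duration, axis=1)
            # small random bursts, below the moving threshold
            bursts = rng.random((n, seg.duration)) < motion.burst_prob
            ang = rng.uniform(0, 2 * np.pi, size=(n, seg.duration))
            step = (motion.burst_speed * bursts)[:, :, None] * np.stack(
                [np.cos(ang), np.sin(ang)], axis=-1)
            pos = anchors[:, None, :] + np.cumsum(step, axis=1)
            # solo-movement windows: out-and-back walk at characteristic speed
            for t in range(t0, t1):
                ind = solo_by_second.get(t)
                if ind is None:
                    continue
                rel = t - next(a for i, a, b in solo
                               if i == ind and a <= t < b)
                if rel == 0:
                    solo_heading = rng.uniform(0, 2 * np.pi)
                    solo_u = np.array([np.cos(solo_heading), np.sin(solo_heading)])
                    solo_origin = pos[ind, t - t0 - 1] if t > t0 else anchors[ind]
                half = motion.solo_duration // 2
                sp = max(v_char[ind] + rng.normal(0, motion.solo_speed_noise), 0.05)
                direction = solo_u if rel < half else -solo_u
                prev = pos[ind, t - t0 - 1] if t > t0 else solo_origin
                pos[ind, t - t0:] = prev + direction * sp
                moving[ind, t] = True
                speed[ind, t] = sp
            xy[:, t0:t1] = pos
            cur = pos[:, -1].copy()
        else:  # travel: 1D cohesion engine along the heading, with pauses
            u = np.asarray(seg.heading, dtype=float)
            u = u / np.linalg.norm(u)
            perp = np.array([-u[1], u[0]])
            center = cur.mean(axis=0)
            s = (cur - center) @ u
            lat = (cur - center) @ perp
            lat = lat + rng.normal(0, 0.2, size=n)
            for t in range(t0, t1):
                rest = (s.sum() - s) / max(n - 1, 1)
                sep = s - rest if n > 1 else np.zeros(1)
                p_pause = _pause_probs(sep, leg, motion)
                mv = rng.random(n) >= p_pause
                d = s - s.mean()
                if seg.rule == "I":
                    v_cmd = v_char.copy()
                elif seg.rule == "II":
                    v_cmd = v_char - motion.g * d
                elif seg.rule == "III":
                    spread = s.max() - s.min()
                    v_cmd = v_char - motion.g * d * (spread > motion.T)
                else:
                    raise ValueError(f"unknown rule {seg.rule!r}")
                sp = np.clip(v_cmd + rng.normal(0, motion.speed_noise_sd, n),
                             0.0, None) * mv
                s = s + sp
                xy[:, t] = center + u * s[:, None] + perp * lat[:, None]
                act = sp > 1e-6
                moving[:, t] = act
                speed[:, t] = sp
            group_moving[t0:t1] = True
            cur = xy[:, t1 - 1].copy()
        t0 = t1

    true_stride = np.where(moving, speed / (motion.kappa * leg[:, None] / 100.0),
                           np.nan)
    obs = xy + rng.normal(0.0, schedule.gps_noise_sd, size=xy.shape)
    times = schedule.day_start * 3600.0 + np.arange(total, dtype=float)
    tracks = TrackSet([ind.id for ind in troop], times, obs)
    labels = TrueLabels(moving, group_moving, true_stride, solo, xy)
    return tracks, labels


# ---------------------------------------------------------------------------
# accelerometry synthesis

@dataclass
class AccelParams:
    gravity: float = GRAVITY
    footfall_amplitude: float = 3.0   # m/s^2, heave oscillation amplitude
    noise_sd: float = 0.2             # m/s^2, per-sample sensor noise
    surge_ratio: float = 0.4          # surge amplitude relative to heave
    sway_ratio: float = 0.25
    kappa: float = 1.3
    moving_speed_threshold: float = 0.5   # m/s, used when deriving speed


def synth_accel(track_xy, individual: Individual,
                params: AccelParams | None = None, seed=0,
                stride_hz=None, t_start: float = 0.0) -> AccelSeries:
    """Synthesise 12 Hz tri-axial accelerometry for one individual.

    While moving at stride frequency f the heave axis oscillates
    sinusoidally at f about gravity (one peak per stride cycle); surge and
    sway carry phase-shifted components at reduced amplitude. When
    stationary the signal is gravity plus sensor noise. If `stride_hz`
    (per-second ground truth, NaN when not moving) is not supplied, the
    stride frequency is derived from the per-second track displacement via
    ``f = v / (kappa * leg_m)``. Seconds with missing GPS yield missing
    (NaN) acceleration; no interpolation is performed.
    """
    params = params or AccelParams()
    rng = rng_from_seed(seed)
    xy = np.asarray(track_xy, dtype=float)
    n_sec = len(xy)
    leg_m = individual.leg_length / 100.0
    if stride_hz is None:
        disp = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        v = np.concatenate([disp, disp[-1:]]) if n_sec > 1 else np.zeros(1)
        f_sec = np.where(v > params.moving_speed_threshold,
                         v / (params.kappa * leg_m), 0.0)
    else:
        f_sec = np.nan_to_num(np.asarray(stride_hz, dtype=float), nan=0.0)
    gap_sec = np.isnan(xy).any(axis=1)
    f_sec = np.where(gap_sec, 0.0, f_sec)

    fs = int(ACCEL_HZ)
    f_samp = np.repeat(f_sec, fs)
    phase = np.cumsum(f_samp / fs)
    active = f_samp > 0
    A = params.footfall_amplitude
    noise = rng.normal(0.0, params.noise_sd, size=(3, len(f_samp)))
    heave = params.gravity + A * np.sin(2 * np.pi * phase) * active + noise[0]
    surge = (params.surge_ratio * A * np.cos(2 * np.pi * phase) * active
             + noise[1])
    sway = (params.sway_ratio * A * np.sin(2 * np.pi * phase + np.pi / 3)
            * active + noise[2])
    gap_samp = np.repeat(gap_sec, fs)
    for axis in (heave, surge, sway):
        axis[gap_samp] = np.nan
    times = t_start + np.arange(len(f_samp)) / ACCEL_HZ
    return AccelSeries(times, surge, sway, heave)


def synth_troop_accel(tracks: TrackSet, labels: TrueLabels, troop,
                      params: AccelParams | None = None, seed=0) -> dict:
    """Accelerometry for every individual, driven by the ground-truth labels."""
    rng = rng_from_seed(seed)
    out = {}
    for i, ind in enumerate(troop):
        out[ind.id] = synth_accel(
            tracks.xy[i], ind, params, seed=rng.integers(2**31),
            stride_hz=labels.true_stride[i], t_start=float(tracks.times[0]))
    return out


def inject_artifacts(series: AccelSeries, spike_rate: float = 0.0,
                     spike_magnitude: float = 10.0, dropout_rate: float = 0.0,
                     seed=0):
    """Add collar-strike spikes and collar-dropout gaps to a series.

    Spikes are isolated single-sample excursions of `spike_magnitude` times
    the per-axis signal s.d. (random sign, applied to all three axes);
    their expected count is ``spike_rate`` events per minute. Dropouts are
    contiguous spans of missing (NaN) samples covering approximately
    `dropout_rate` of the record. Returns ``(series, artifacts)`` where
    artifacts maps 'spikes' to an index array and 'dropouts' to
    (start, end) spans.
    """
    if spike_rate < 0 or dropout_rate < 0:
        raise ValueError("rates must be >= 0")
    out = series.copy()
    rng = rng_from_seed(seed)
    n = len(out.times)
    artifacts = {"spikes": np.empty(0, dtype=int), "dropouts": []}
    if spike_rate > 0:
        minutes = n / ACCEL_HZ / 60.0
        k = rng.poisson(spike_rate * minutes)
        if k > 0:
            idx = np.sort(rng.choice(np.arange(1, n - 1), size=min(k, n - 2),
                                     replace=False))
            idx = idx[np.concatenate([[True], np.diff(idx) > 1])]
            for axis in ("surge", "sway", "heave"):
                x = getattr(out, axis)
                sd = np.nanstd(x)
                signs = rng.choice([-1.0, 1.0], size=len(idx))
                x[idx] = x[idx] + signs * spike_magnitude * sd
            artifacts["spikes"] = idx
    if dropout_rate > 0:
        target = int(dropout_rate * n)
        lost = 0
        spans = []
        while lost < target:
            length = max(1, int(rng.exponential(60)))
            start = int(rng.integers(0, max(n - length, 1)))
            spans.append((start, start + length))
            lost += length
        for a, b in spans:
            out.surge[a:b] = np.nan
            out.sway[a:b] = np.nan
            out.heave[a:b] = np.nan
        artifacts["dropouts"] = spans
    return out, artifacts
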