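"""Individual-level movement summaries.

Daily travel distance (after 5 m spatial discretisation to suppress GPS
jitter), daily maximum displacement from the sleeping site, characteristic
stride frequency (gait while moving independently of the group), stride-
frequency deviation, move:pause ratios, nearest-neighbour leg-length
differences, and the move:pause response to separation from the rest of
the group with its breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import TrackSet
from .group import PositionFrames


# ---------------------------------------------------------------------------
# daily summaries

def discretize_track(xy, step: float = 5.0) -> np.ndarray:
    """Greedy spatial thinning: indices of kept points.

    Keeps the first valid fix, then each next fix at least `step` metres
    from the last kept one. Deterministic and order-preserving.
    """
    xy = np.asarray(xy, dtype=float)
    valid = np.flatnonzero(~np.isnan(xy).any(axis=1))
    if valid.size == 0:
        return np.empty(0, dtype=int)
    kept = [valid[0]]
    ref = xy[valid[0]]
    for i in valid[1:]:
        if np.linalg.norm(xy[i] - ref) >= step:
            kept.append(i)
            ref = xy[i]
    return np.asarray(kept, dtype=int)


def daily_travel_distance(xy, step: float = 5.0) -> float:
    """Travel distance (m) summed over the 5 m-discretised track."""
    kept = discretize_track(xy, step)
    if kept.size < 2:
        return 0.0
    pts = np.asarray(xy, dtype=float)[kept]
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def daily_max_displacement(xy, sleep_site=None) -> float:
    """Straight-line distance from the sleeping site to the farthest fix.

    The sleeping site defaults to the first valid (morning) position.
    """
    xy = np.asarray(xy, dtype=float)
    valid = ~np.isnan(xy).any(axis=1)
    if not valid.any():
        raise ValueError("empty track")
    pts = xy[valid]
    site = pts[0] if sleep_site is None else np.asarray(sleep_site, float)
    return float(np.max(np.linalg.norm(pts - site, axis=1)))


def daily_summary(tracks: TrackSet, moving=None, step: float = 5.0) -> pd.DataFrame:
    """Per-individual daily travel distance, max displacement, minutes moving."""
    rows = []
    for i, ind_id in enumerate(tracks.ids):
        minutes = (float(np.nansum(moving[i])) / 60.0
                   if moving is not None else np.nan)
        rows.append({
            "individual_id": ind_id,
            "travel_distance_m": daily_travel_distance(tracks.xy[i], step),
            "max_displacement_m": daily_max_displacement(tracks.xy[i]),
            "minutes_moving": minutes,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gait reference and deviation

def characteristic_stride_frequency(stride_hz, states, focal: int) -> float:
    """Mean stride frequency of the focal while all group-mates are still.

    `stride_hz` is the focal's per-second stride-frequency series and
    `states` the (N, T) per-second moving states of the whole troop (the
    focal's own row included). Qualifying seconds are those where the focal
    is moving and every other tracked individual is stationary; NaN states
    (missing data) disqualify the second. Returns NaN when no second
    qualifies.
    """
    stride_hz = np.asarray(stride_hz, dtype=float)
    states = np.asarray(states, dtype=float)
    focal_moving = states[focal] == 1
    others = np.delete(states, focal, axis=0)
    if others.shape[0] == 0:
        quiet = np.ones_like(focal_moving, dtype=bool)
    else:
        quiet = np.all(others == 0, axis=0)
    qual = focal_moving & quiet & ~np.isnan(stride_hz)
    if not qual.any():
        return np.nan
    return float(np.mean(stride_hz[qual]))


def stride_deviation(stride_hz, f_char: float) -> np.ndarray:
    """Percent deviation from the characteristic stride frequency."""
    if not np.isfinite(f_char) or f_char <= 0:
        raise ValueError("characteristic stride frequency undefined")
    return 100.0 * (np.asarray(stride_hz, dtype=float) - f_char) / f_char


# ---------------------------------------------------------------------------
# intermittent locomotion

def move_pause_ratio(states) -> dict:
    """Move:pause statistics of one window of per-second states.

    Returns the raw ratio (inf when no pauses), the proportion of time
    moving, and the boundary-shrunk proportion ``(p (n - 1) + 0.5) / n``
    used by beta-family models.
    """
    s = np.asarray(states, dtype=float)
    s = s[~np.isnan(s)]
    n = len(s)
    if n == 0:
        return {"ratio": np.nan, "proportion": np.nan, "shrunk": np.nan, "n": 0}
    n_mov = float(np.sum(s == 1))
    n_stat = n - n_mov
    ratio = np.inf if n_stat == 0 else n_mov / n_stat
    prop = n_mov / n
    shrunk = (prop * (n - 1) + 0.5) / n
    return {"ratio": ratio, "proportion": prop, "shrunk": shrunk, "n": n}


def nearest_neighbour_size_diff(positions, leg_lengths, focal: int,
                                radius: float = 5.0) -> float:
    """Leg length of the nearest neighbour minus the focal's, within radius.

    NaN when the nearest neighbour is farther than `radius` metres or no
    neighbour has a fix.
    """
    pos = np.asarray(positions, dtype=float)
    leg = np.asarray(leg_lengths, dtype=float)
    dist = np.linalg.norm(pos - pos[focal], axis=1)
    dist[focal] = np.inf
    dist[np.isnan(dist)] = np.inf
    j = int(np.argmin(dist))
    if not np.isfinite(dist[j]) or dist[j] >= radius:
        return np.nan
    return float(leg[j] - leg[focal])


# ---------------------------------------------------------------------------
# separation / move:pause profile

def separation_series(frames: PositionFrames) -> np.ndarray:
    """Signed separation of each individual from the rest of the group.

    Separation is the focal front-back coordinate minus the front-back
    coordinate of the centroid of all other tracked individuals; positive
    means ahead. Shape (K, N).
    """
    d = frames.d
    with np.errstate(invalid="ignore"):
        total = np.nansum(d, axis=1, keepdims=True)
        m = np.sum(~np.isnan(d), axis=1, keepdims=True)
        rest = (total - np.nan_to_num(d)) / np.maximum(m - 1, 1)
    sep = d - rest
    sep[:, :][m[:, 0] < 2] = np.nan
    return sep


def separation_profile(separation, moving, bin_width: float = 5.0) -> pd.DataFrame:
    """Binned move:pause response to separation from the group.

    Pools (separation, moving) samples into `bin_width`-metre bins and
    reports per bin the sample count, the proportion of time moving and the
    implied move:pause ratio (shrunk at the boundaries).
    """
    sep = np.asarray(separation, dtype=float).ravel()
    mov = np.asarray(moving, dtype=float).ravel()
    ok = ~np.isnan(sep) & ~np.isnan(mov)
    sep, mov = sep[ok], mov[ok]
    if sep.size == 0:
        return pd.DataFrame(columns=["bin_center", "n", "prop_moving", "ratio"])
    lo = np.floor(sep.min() / bin_width) * bin_width
    hi = np.ceil(sep.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 1e-9, bin_width)
    idx = np.clip(np.digitize(sep, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        prop = float(mov[sel].mean())
        shrunk = (prop * (n - 1) + 0.5) / n
        rows.append({"bin_center": (edges[b] + edges[b + 1]) / 2, "n": n,
                     "prop_moving": prop, "ratio": shrunk / (1 - shrunk)})
    return pd.DataFrame(rows)


def _step_breakpoint(x, y, w):
    """Weighted least-squares single-step fit.

    Returns ``(break, sse_gain, step_height)`` where the height is the
    absolute difference between the two fitted levels.
    """
    order = np.argsort(x)
    x, y, w = x[order], y[order], w[order]
    if len(x) < 3:
        return np.nan, 0.0, 0.0
    mean_all = np.average(y, weights=w)
    sse_all = float(np.sum(w * (y - mean_all) ** 2))
    best_c, best_sse, best_h = np.nan, np.inf, 0.0
    for k in range(1, len(x)):
        wl, wr = w[:k], w[k:]
        ml = np.average(y[:k], weights=wl)
        mr = np.average(y[k:], weights=wr)
        sse = float(np.sum(wl * (y[:k] - ml) ** 2)
                    + np.sum(wr * (y[k:] - mr) ** 2))
        if sse < best_sse:
            best_sse = sse
            best_c = (x[k - 1] + x[k]) / 2
            best_h = abs(ml - mr)
    return best_c, sse_all - best_sse, best_h


def estimate_breakpoints(profile: pd.DataFrame, min_count: int = 20,
                         min_gain_fraction: float = 0.05,
                         min_step: float = 0.05) -> dict:
    """Separation breakpoints of the move:pause response, one per side.

    Fits a two-piece constant model to the binned proportion-moving curve
    separately ahead of (separation > 0) and behind (< 0) the group,
    weighting bins by their sample counts. A side returns NaN when too few
    bins are populated, the step explains almost none of the variance, or
    the fitted step is smaller than `min_step` in proportion units (the
    best split of a flat noisy curve always captures some variance, so the
    height criterion is what rejects flat profiles).
    """
    out = {"ahead": np.nan, "behind": np.nan}
    for side, mask in (("ahead", profile["bin_center"] > 0),
                       ("behind", profile["bin_center"] < 0)):
        sub = profile[mask & (profile["n"] >= min_count)]
        if len(sub) < 3:
            continue
        x = sub["bin_center"].to_numpy()
        y = sub["prop_moving"].to_numpy()
        w = sub["n"].to_numpy().astype(float)
        c, gain, height = _step_breakpoint(x, y, w)
        base = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
        if base > 0 and gain / base >= min_gain_fraction and height >= min_step:
            out[side] = float(c)
    return out


# ---------------------------------------------------------------------------
# 10 s window records

def window_records(frames_by_bout: dict, states, stride_hz, vedba,
                   f_char, leg_lengths, ids, window: int = 10,
                   nn_radius: float = 5.0) -> pd.DataFrame:
    """Aggregate per-individual metrics over 10 s windows of travel bouts.

    Parameters
    ----------
    frames_by_bout : mapping bout_id -> :class:`PositionFrames`
    states : (N, T) per-second moving states (1/0/NaN) on the day grid
    stride_hz : (N, T) per-second stride frequency (NaN where undefined)
    vedba : (N, T) per-second VeDBA
    f_char : (N,) characteristic stride frequencies
    leg_lengths : (N,) cm
    """
    states = np.asarray(states, dtype=float)
    stride_hz = np.asarray(stride_hz, dtype=float)
    vedba = np.asarray(vedba, dtype=float)
    leg = np.asarray(leg_lengths, dtype=float)
    rows = []
    for bout_id, frames in frames_by_bout.items():
        if len(frames.index) == 0:
            continue
        sep = separation_series(frames)
        pos_in_day = frames.index
        for w0 in range(0, len(pos_in_day) - window + 1, window):
            wsel = slice(w0, w0 + window)
            day_idx = pos_in_day[wsel]
            mid = w0 + window // 2
            for i, ind_id in enumerate(ids):
                st = states[i, day_idx]
                mp = move_pause_ratio(st)
                if mp["n"] == 0:
                    continue
                sh = stride_hz[i, day_idx]
                dev = (100.0 * (np.nanmean(sh) - f_char[i]) / f_char[i]
                       if np.isfinite(f_char[i]) and f_char[i] > 0
                       and np.isfinite(sh).any() else np.nan)
                pos_mid = np.stack([frames.d[mid], frames.lr[mid]], axis=1)
                rows.append({
                    "individual_id": ind_id,
                    "bout_id": bout_id,
                    "t0": float(frames.times[w0]),
                    "leg_length": leg[i],
                    "stride_dev_pct": dev,
                    "vedba": float(np.nanmean(vedba[i, day_idx])),
                    "p": float(np.nanmean(frames.p[wsel, i])),
                    "separation": float(np.nanmean(sep[wsel, i])),
                    "move_pause_ratio": mp["ratio"],
                    "prop_moving": mp["proportion"],
                    "prop_moving_shrunk": mp["shrunk"],
                    "nn_leg_diff": nearest_neighbour_size_diff(
                        pos_mid, leg, i, nn_radius),
                    "spread": float(np.nanmean(frames.spread[wsel])),
                    "group_speed": float(np.nanmean(frames.group_speed[wsel])),
                })
    return pd.DataFrame(rows)
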