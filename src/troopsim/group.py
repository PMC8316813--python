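"""Group-level state: centroid, travel-bout segmentation, spatial positions.

The group centroid is the unweighted mean of the available fixes each
second. Its displacement speed (over a 10 s window) drives a penalised
change-point segmentation (PELT, L2 mean-shift cost) that partitions the
day into stationary and non-stationary (travel) bouts. Within travel
bouts, individual positions are re-expressed in a frame aligned with the
centroid heading (rotation by the heading angle), giving signed front-back
coordinates, positional ranks (1 = backmost), rank-rescaled positions in
[-1, +1], and the group spread (front-back extent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TrackSet

MAD_TO_SD = 1.4826


@dataclass
class CentroidTrack:
    times: np.ndarray
    xy: np.ndarray               # (T, 2), NaN where coverage too low
    n_contributing: np.ndarray   # (T,)
    speed: np.ndarray            # (T,) m/s over the smoothing window
    heading: np.ndarray          # (T, 2) unit vectors, NaN when speed too low


def compute_centroid(tracks: TrackSet, coverage_threshold: int = 1,
                     speed_window: float = 10.0,
                     heading_min_speed: float = 0.1) -> CentroidTrack:
    """Per-second centroid with displacement speed and heading.

    Speed at time t is ``||c(t) - c(t - w)|| / w`` with w = `speed_window`;
    the heading is that displacement normalised, undefined below
    `heading_min_speed` (heading is noise-dominated when the group is
    quasi-stationary).
    """
    if tracks.n_individuals < 1:
        raise ValueError("need at least one track")
    with np.errstate(invalid="ignore"):
        xy = np.nanmean(tracks.xy, axis=0)
    n_contrib = np.sum(~np.isnan(tracks.xy[:, :, 0]), axis=0)
    xy[n_contrib < coverage_threshold] = np.nan

    w = int(round(speed_window))
    T = tracks.n_seconds
    speed = np.full(T, np.nan)
    heading = np.full((T, 2), np.nan)
    if T > w:
        disp = xy[w:] - xy[:-w]
        sp = np.linalg.norm(disp, axis=1) / w
        speed[w:] = sp
        with np.errstate(invalid="ignore"):
            ok = sp > heading_min_speed
        ok &= ~np.isnan(sp)
        heading[w:][ok] = disp[ok] / np.linalg.norm(disp[ok], axis=1,
                                                    keepdims=True)
    return CentroidTrack(tracks.times, xy, n_contrib, speed, heading)


# ---------------------------------------------------------------------------
# change-point segmentation (PELT, L2 cost on the mean)

def pelt_mean_shift(y, penalty: float | None = None,
                    min_size: int = 5) -> list:
    """Breakpoints of a piecewise-constant-mean signal by PELT.

    Minimises the penalised sum of within-segment squared deviations with
    an L2 cost; the default penalty is BIC-like, ``2 * sigma^2 * log(n)``
    with sigma estimated robustly from first differences. Returns sorted
    interior breakpoint indices (segment boundaries).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * min_size:
        return []
    if penalty is None:
        d = np.diff(y)
        sigma = MAD_TO_SD * np.median(np.abs(d - np.median(d))) / np.sqrt(2)
        sigma = max(sigma, 1e-9)
        penalty = 2.0 * sigma**2 * np.log(n)
    cum = np.concatenate([[0.0], np.cumsum(y)])
    cum2 = np.concatenate([[0.0], np.cumsum(y**2)])

    def cost(tau, t):
        length = t - tau
        s = cum[t] - cum[tau]
        return (cum2[t] - cum2[tau]) - s * s / length

    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    last = np.zeros(n + 1, dtype=int)
    cand = np.array([0], dtype=int)
    for t in range(min_size, n + 1):
        valid = cand[(t - cand) >= min_size]
        if valid.size == 0:
            valid = np.array([0])
        c = cost(valid, t)
        tot = F[valid] + c + penalty
        i = int(np.argmin(tot))
        F[t] = tot[i]
        last[t] = valid[i]
        keep = F[valid] + c <= F[t]
        cand = np.concatenate([valid[keep], cand[(t - cand) < min_size], [t]])
    # backtrack
    bps = []
    t = n
    while t > 0:
        tau = last[t]
        if tau > 0:
            bps.append(int(tau))
        t = tau
    return sorted(bps)


@dataclass
class GroupBout:
    start: int            # index into the centroid time grid (inclusive)
    end: int              # exclusive
    state: str            # "stationary" | "non-stationary"
    coverage: int         # typical number of individuals with data

    @property
    def duration(self) -> int:
        return self.end - self.start


def detect_bouts(centroid: CentroidTrack, penalty: float | None = None,
                 speed_threshold: float = 0.1, min_size: int = 30,
                 max_gap_fraction: float = 0.2) -> list:
    """Partition the day into stationary / non-stationary group bouts.

    Change points come from PELT on the centroid displacement speed (NaN
    gaps filled by nearest-neighbour interpolation, tolerated up to
    `max_gap_fraction`); segments are labelled stationary when their mean
    speed is below `speed_threshold` and adjacent same-label segments are
    merged, so the returned bouts partition the series.
    """
    y = np.asarray(centroid.speed, dtype=float)
    n = len(y)
    if n == 0:
        return []
    nan = np.isnan(y)
    if nan.all():
        return []
    if nan.mean() > max_gap_fraction:
        raise ValueError("too many gaps in the centroid speed series")
    if nan.any():
        idx = np.arange(n)
        y = np.interp(idx, idx[~nan], y[~nan])
    bps = pelt_mean_shift(y, penalty=penalty, min_size=min_size)
    edges = [0] + bps + [n]
    bouts = []
    for a, b in zip(edges[:-1], edges[1:]):
        state = ("stationary" if y[a:b].mean() < speed_threshold
                 else "non-stationary")
        cov = int(np.median(centroid.n_contributing[a:b]))
        if bouts and bouts[-1].state == state:
            prev = bouts[-1]
            cov = int(np.median(centroid.n_contributing[prev.start:b]))
            bouts[-1] = GroupBout(prev.start, b, state, cov)
        else:
            bouts.append(GroupBout(a, b, state, cov))
    return bouts


def filter_bouts(bouts, min_duration: int = 120, min_coverage: int = 16):
    """Travel bouts usable for positional analysis.

    Keeps non-stationary bouts lasting at least `min_duration` seconds with
    at least `min_coverage` tracked individuals; both bounds are closed
    (a bout of exactly 120 s with exactly 16 individuals is retained).
    """
    return [b for b in bouts
            if b.state == "non-stationary"
            and b.duration >= min_duration
            and b.coverage >= min_coverage]


# ---------------------------------------------------------------------------
# front-back geometry

@dataclass
class PositionFrames:
    """Per-second positional geometry within one travel bout.

    Arrays are (K, N) over the K seconds with a defined heading, except
    the per-frame summaries which are (K,). Ranks run 1..n_present with
    1 = backmost; ties in the front-back coordinate are broken by
    individual index. The rescaled position p maps the backmost individual
    to -1, the centre to 0 and the frontmost to +1.
    """

    times: np.ndarray
    index: np.ndarray            # (K,) indices into the day grid
    d: np.ndarray                # front-back coordinate, m
    lr: np.ndarray               # left-right coordinate, m
    rank: np.ndarray
    p: np.ndarray
    spread: np.ndarray           # front-back extent, m
    mean_dist: np.ndarray        # mean distance to centroid, m (secondary)
    group_speed: np.ndarray
    n_present: np.ndarray


def front_back_positions(tracks: TrackSet, centroid: CentroidTrack,
                         start: int, end: int) -> PositionFrames:
    """Rotate positions into the centroid-heading frame for one bout.

    Seconds whose heading is undefined (centroid speed below threshold or
    missing) are skipped.
    """
    sel = np.arange(start, end)
    ok = ~np.isnan(centroid.heading[sel, 0])
    sel = sel[ok]
    K, N = len(sel), tracks.n_individuals
    u = centroid.heading[sel]                       # (K, 2)
    perp = np.stack([-u[:, 1], u[:, 0]], axis=1)
    rel = tracks.xy[:, sel, :] - centroid.xy[sel]   # (N, K, 2)
    d = np.einsum("nkc,kc->kn", rel, u)
    lr = np.einsum("nkc,kc->kn", rel, perp)
    dist = np.linalg.norm(rel, axis=2).T            # (K, N)

    rank = np.full((K, N), np.nan)
    p = np.full((K, N), np.nan)
    n_present = np.zeros(K, dtype=int)
    ids_idx = np.arange(N)
    for k in range(K):
        present = ~np.isnan(d[k])
        m = int(present.sum())
        n_present[k] = m
        if m == 0:
            continue
        order = np.lexsort((ids_idx[present], d[k][present]))
        r = np.empty(m)
        r[order] = np.arange(1, m + 1)
        rank[k, present] = r
        p[k, present] = 0.0 if m == 1 else 2 * (r - 1) / (m - 1) - 1
    with np.errstate(all="ignore"):
        spread = np.nanmax(d, axis=1) - np.nanmin(d, axis=1)
        mean_dist = np.nanmean(dist, axis=1)
    return PositionFrames(centroid.times[sel], sel, d, lr, rank, p,
                          spread, mean_dist, centroid.speed[sel], n_present)


def group_spread(d_row) -> float:
    """Front-back extent of one frame (0 for a single individual)."""
    d = np.asarray(d_row, dtype=float)
    d = d[~np.isnan(d)]
    if d.size <= 1:
        return 0.0
    return float(d.max() - d.min())


def mean_rank_duration(frames: PositionFrames) -> float:
    """Mean time (s) an individual holds the same front-back rank."""
    durations = []
    K, N = frames.rank.shape
    if K == 0:
        return np.nan
    dt = np.median(np.diff(frames.times)) if K > 1 else 1.0
    for i in range(N):
        r = frames.rank[:, i]
        run = 0
        prev = np.nan
        for k in range(K):
            if np.isnan(r[k]):
                if run:
                    durations.append(run)
                run, prev = 0, np.nan
            elif r[k] == prev:
                run += 1
            else:
                if run:
                    durations.append(run)
                run, prev = 1, r[k]
        if run:
            durations.append(run)
    return float(np.mean(durations) * dt) if durations else np.nan
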