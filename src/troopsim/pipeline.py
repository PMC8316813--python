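"""End-to-end day pipeline: raw streams -> per-second metrics -> records.

Chains the analysis stages on one synthetic (or observed) day:
despiking -> stride frequency / VeDBA / activity classification per
individual -> group centroid, travel bouts and positional geometry ->
characteristic stride frequencies -> tidy 10 s window records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import accel as acc
from . import group as grp
from . import movement as mov
from .core import ACCEL_HZ, AccelSeries, TrackSet


def per_second_stride(heave, fs: float = ACCEL_HZ, window: float = 10.0) -> np.ndarray:
    """Per-second stride frequency, each second taking its window's estimate.

    Windows are non-overlapping (`hop = window`); every second inside a
    window inherits that window's stride estimate (NaN where undefined).
    """
    est = acc.estimate_stride_frequency(heave, fs=fs, window=window, hop=window)
    n_sec = int(np.ceil(len(heave) / fs))
    out = np.full(n_sec, np.nan)
    w = int(round(window))
    for t0, f in zip(est["t_start"].to_numpy(), est["stride_hz"].to_numpy()):
        a = int(round(t0))
        out[a:min(a + w, n_sec)] = f
    return out


@dataclass
class IndividualMetrics:
    """Per-second metrics for one individual."""

    vedba: np.ndarray            # (T,) per-second VeDBA
    stride_hz: np.ndarray        # (T,) windowed stride frequency
    moving: np.ndarray           # (T,) 1/0/NaN activity state
    features: pd.DataFrame       # per-second classification features


def process_individual(series: AccelSeries, classifier=None,
                       half_window: int = 24, n_mad: float = 3.0,
                       vedba_threshold: float = 0.7) -> IndividualMetrics:
    """Despike one accelerometry record and derive its per-second metrics."""
    clean = acc.despike(series, half_window, n_mad)
    features = acc.activity_features(clean)
    states = acc.classify_activity(features, model=classifier,
                                   vedba_threshold=vedba_threshold)
    stride = per_second_stride(clean.heave)
    return IndividualMetrics(
        vedba=features["vedba"].to_numpy(),
        stride_hz=stride,
        moving=states["moving"].to_numpy(),
        features=features,
    )


@dataclass
class DayResult:
    """Pipeline outputs for one day."""

    ids: list
    states: np.ndarray           # (N, T) 1/0/NaN
    stride_hz: np.ndarray        # (N, T)
    vedba: np.ndarray            # (N, T)
    f_char: np.ndarray           # (N,)
    centroid: object
    bouts: list
    travel_bouts: list
    frames_by_bout: dict = field(default_factory=dict)

    def window_records(self, leg_lengths, window: int = 10) -> pd.DataFrame:
        return mov.window_records(self.frames_by_bout, self.states,
                                  self.stride_hz, self.vedba, self.f_char,
                                  leg_lengths, self.ids, window=window)


def run_day(tracks: TrackSet, accel_by_id: dict, classifier=None,
            min_bout_duration: int = 120, min_coverage: int = 16,
            **individual_kwargs) -> DayResult:
    """Run the full pipeline on one day of GPS + accelerometry.

    `accel_by_id` maps individual id -> :class:`AccelSeries`, each covering
    the same seconds as `tracks`. Individuals missing from the mapping get
    NaN metrics.
    """
    n, T = tracks.n_individuals, tracks.n_seconds
    states = np.full((n, T), np.nan)
    stride = np.full((n, T), np.nan)
    vedba = np.full((n, T), np.nan)
    for i, ind_id in enumerate(tracks.ids):
        series = accel_by_id.get(ind_id)
        if series is None:
            continue
        m = process_individual(series, classifier=classifier,
                               **individual_kwargs)
        k = min(T, len(m.vedba))
        states[i, :k] = m.moving[:k]
        stride[i, :k] = m.stride_hz[:k]
        vedba[i, :k] = m.vedba[:k]

    f_char = np.array([
        mov.characteristic_stride_frequency(stride[i], states, i)
        for i in range(n)
    ])

    centroid = grp.compute_centroid(tracks)
    bouts = grp.detect_bouts(centroid)
    travel = grp.filter_bouts(bouts, min_duration=min_bout_duration,
                              min_coverage=min_coverage)
    frames = {f"bout{k:02d}": grp.front_back_positions(tracks, centroid,
                                                       b.start, b.end)
              for k, b in enumerate(travel)}
    return DayResult(list(tracks.ids), states, stride, vedba, f_char,
                     centroid, bouts, travel, frames)
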