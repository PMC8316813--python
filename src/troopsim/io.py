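"""Plain-text interchange: CSV for tracks/accelerometry/metrics, YAML configs."""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .core import AccelSeries, TrackSet


def tracks_to_frame(tracks: TrackSet) -> pd.DataFrame:
    """Long-format GPS table: individual_id, timestamp, x_m, y_m."""
    frames = []
    for i, ind_id in enumerate(tracks.ids):
        frames.append(pd.DataFrame({
            "individual_id": ind_id,
            "timestamp": tracks.times,
            "x_m": tracks.xy[i, :, 0],
            "y_m": tracks.xy[i, :, 1],
        }))
    return pd.concat(frames, ignore_index=True)


def write_tracks(tracks: TrackSet, path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks(path) -> TrackSet:
    df = pd.read_csv(path)
    ids = sorted(df["individual_id"].unique())
    times = np.sort(df["timestamp"].unique()).astype(float)
    t_index = {t: k for k, t in enumerate(times)}
    xy = np.full((len(ids), len(times), 2), np.nan)
    for i, ind_id in enumerate(ids):
        sub = df[df["individual_id"] == ind_id]
        idx = sub["timestamp"].map(t_index).to_numpy()
        xy[i, idx, 0] = sub["x_m"].to_numpy()
        xy[i, idx, 1] = sub["y_m"].to_numpy()
    return TrackSet(list(ids), times, xy)


def accel_to_frame(series: AccelSeries, individual_id: str) -> pd.DataFrame:
    return pd.DataFrame({
        "individual_id": individual_id,
        "timestamp": series.times,
        "ax": series.surge,
        "ay": series.sway,
        "az": series.heave,
    })


def write_accel(accel_by_id: dict, path) -> None:
    pd.concat([accel_to_frame(s, i) for i, s in accel_by_id.items()],
              ignore_index=True).to_csv(path, index=False)


def read_accel(path) -> dict:
    df = pd.read_csv(path)
    out = {}
    for ind_id, sub in df.groupby("individual_id"):
        sub = sub.sort_values("timestamp")
        out[ind_id] = AccelSeries(
            sub["timestamp"].to_numpy(float), sub["ax"].to_numpy(float),
            sub["ay"].to_numpy(float), sub["az"].to_numpy(float))
    return out


def write_config(obj, path) -> None:
    """Serialise a config dataclass (or dict) as YAML."""
    data = obj if isinstance(obj, dict) else asdict(obj)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
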