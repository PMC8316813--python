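#!/usr/bin/env python
"""Stage 4: window records, daily summaries, separation breakpoints.

Reads gps.csv, metrics.csv, labels.csv and bouts/ (stages 1-3); writes
windows.csv, daily_summary.csv and separation_profile.csv, and prints the
estimated pause breakpoints ahead of / behind the group.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import stage_args

from troopsim import cli
from troopsim import group as grp
from troopsim import io as tio
from troopsim import movement as mov


def main() -> int:
    args = stage_args(__doc__)
    out = args.results

    class _A:
        gps = out / "gps.csv"
        accel_metrics = out / "metrics.csv"
        bouts = out / "bouts"
        troop = out / "troop.csv"

    _A.out = out / "windows.csv"
    cli._cmd_metrics(_A)

    summary = pd.read_csv(out / "daily_summary.csv")
    print(f"daily travel distance: "
          f"{summary['travel_distance_m'].mean() / 1000:.2f} km (mean), "
          f"max displacement {summary['max_displacement_m'].mean() / 1000:.2f} km")

    # separation profile of the move:pause response, pooled over travel bouts
    tracks = tio.read_tracks(out / "gps.csv")
    metrics = pd.read_csv(out / "metrics.csv")
    states, _, _ = cli._metrics_matrices(metrics, tracks.ids, tracks.times)
    centroid = grp.compute_centroid(tracks)
    t0 = float(tracks.times[0])
    bouts = pd.read_csv(out / "bouts" / "bouts.csv")
    travel = grp.filter_bouts([
        grp.GroupBout(int(r.start - t0), int(r.end - t0), r.state,
                      int(r.coverage)) for r in bouts.itertuples()])
    seps, movings = [], []
    for b in travel:
        frames = grp.front_back_positions(tracks, centroid, b.start, b.end)
        if len(frames.index) == 0:
            continue
        seps.append(mov.separation_series(frames).ravel())
        movings.append(states[:, frames.index].T.ravel())
    profile = mov.separation_profile(np.concatenate(seps),
                                     np.concatenate(movings))
    profile.to_csv(out / "separation_profile.csv", index=False)
    bp = mov.estimate_breakpoints(profile)
    print(f"pause breakpoints: ahead {bp['ahead']} m, behind {bp['behind']} m")
    return 0


if __name__ == "__main__":
    sys.exit(main())
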