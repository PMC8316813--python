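#!/usr/bin/env python
"""Stage 1: generate the synthetic troop, one full day and accelerometry.

Writes gps.csv, accel.csv, labels.csv and troop.csv into the results
directory and prints the generator calibration (leg-length range, the
stride-frequency/leg-length correlation, travel-bout durations).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DAY_SECONDS, stage_args

from troopsim import io as tio
from troopsim import stats as st
from troopsim import synthetic as syn
from troopsim.core import rng_from_seed


def main() -> int:
    args = stage_args(__doc__)
    seeds = rng_from_seed(args.seed).integers(2**31, size=4)

    troop = syn.make_troop(syn.TroopConfig(seed=int(seeds[0])))
    legs = np.array([i.leg_length for i in troop])
    f = np.array([i.f_char_true for i in troop])
    r, p = st.pearson_corr(f, legs)
    print(f"troop: n={len(troop)}, legs {legs.min():.1f}-{legs.max():.1f} cm, "
          f"corr(f, leg) = {r:.3f} (p = {p:.2g})")

    schedule = syn.make_day_schedule(seed=int(seeds[1]),
                                     total_duration=DAY_SECONDS)
    travel_min = [s.duration / 60 for s in schedule.segments
                  if s.state == "travel"]
    print(f"schedule: {len(travel_min)} travel segments, "
          f"mean {np.mean(travel_min):.1f} min")

    tracks, labels = syn.simulate_day(troop, schedule, syn.MotionParams(),
                                      seed=int(seeds[2]))
    accel = syn.synth_troop_accel(tracks, labels, troop, syn.AccelParams(),
                                  seed=int(seeds[3]))

    out = args.results
    tio.write_tracks(tracks, out / "gps.csv")
    tio.write_accel(accel, out / "accel.csv")
    pd.DataFrame({
        "individual_id": np.repeat(tracks.ids, tracks.n_seconds),
        "timestamp": np.tile(tracks.times, tracks.n_individuals),
        "moving": labels.moving.astype(int).ravel(),
    }).to_csv(out / "labels.csv", index=False)
    pd.DataFrame({
        "individual_id": [i.id for i in troop],
        "leg_length_cm": legs, "f_char_hz": f,
        "v_char_ms": [i.v_char_true for i in troop],
    }).to_csv(out / "troop.csv", index=False)
    print(f"wrote day data to {out}/")
    return 0


if __name__ == "__main__":
    sys.exit(main())
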