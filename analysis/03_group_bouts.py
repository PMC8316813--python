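#!/usr/bin/env python
"""Stage 3: group centroid, change-point travel bouts, positional frames.

Reads gps.csv (stage 1); writes bouts.csv and frames.csv and prints the
bout summary (count, durations, coverage).
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


def main() -> int:
    args = stage_args(__doc__)
    out = args.results

    class _A:
        gps = out / "gps.csv"

    _A.out = out / "bouts"
    cli._cmd_group_bouts(_A)

    bouts = pd.read_csv(out / "bouts" / "bouts.csv")
    travel = bouts[bouts["state"] == "non-stationary"]
    durations = (travel["end"] - travel["start"]) / 60
    print(f"{len(travel)} travel bouts, durations "
          f"{durations.min():.1f}-{durations.max():.1f} min "
          f"(mean {durations.mean():.1f})")
    kept = grp.filter_bouts([
        grp.GroupBout(int(r.start), int(r.end), r.state, int(r.coverage))
        for r in bouts.itertuples()])
    print(f"{len(kept)} bouts pass the >=2 min / >=16 individuals filter")
    return 0


if __name__ == "__main__":
    sys.exit(main())
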