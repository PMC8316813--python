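#!/usr/bin/env python
"""Stage 2: per-second accelerometry metrics for every individual.

Reads accel.csv (stage 1); writes metrics.csv (individual_id, timestamp,
vedba, stride_hz, state) and prints classification accuracy against the
generator's ground-truth labels.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import stage_args

from troopsim import io as tio
from troopsim import pipeline as pl


def main() -> int:
    args = stage_args(__doc__)
    out = args.results
    accel = tio.read_accel(out / "accel.csv")
    rows = []
    for ind_id, series in accel.items():
        m = pl.process_individual(series)
        rows.append(pd.DataFrame({
            "individual_id": ind_id,
            "timestamp": float(series.times[0]) + np.arange(len(m.vedba)),
            "vedba": m.vedba, "stride_hz": m.stride_hz, "state": m.moving,
        }))
    metrics = pd.concat(rows, ignore_index=True)
    metrics.to_csv(out / "metrics.csv", index=False)

    labels = pd.read_csv(out / "labels.csv")
    joined = metrics.merge(labels, on=["individual_id", "timestamp"])
    ok = joined["state"].notna()
    accuracy = (joined.loc[ok, "state"] == joined.loc[ok, "moving"]).mean()
    print(f"classified {len(accel)} individuals; "
          f"activity accuracy vs truth: {accuracy:.3f}")
    print(f"median stride while moving: "
          f"{metrics.loc[metrics['state'] == 1, 'stride_hz'].median():.2f} Hz")
    return 0


if __name__ == "__main__":
    sys.exit(main())
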