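#!/usr/bin/env python
"""Stage 6: regression models on the 10 s window records.

Fits (i) stride deviation on leg length and front-back position with an
individual random intercept, and (ii) a beta regression of the shrunk
proportion of time moving on leg length with cluster-robust errors; writes
coefs_deviation.csv and coefs_moving.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import stage_args

from troopsim import stats as st


def main() -> int:
    args = stage_args(__doc__)
    out = args.results
    windows = pd.read_csv(out / "windows.csv")

    dev_spec = st.ModelSpec("stride_dev_pct", ["leg_length", "p"],
                            random=["individual_id"])
    res = st.fit_lmm(dev_spec, windows.dropna(subset=["stride_dev_pct", "p"]))
    table = res.coef_table()
    table.index.name = "term"
    table.to_csv(out / "coefs_deviation.csv")
    print(f"stride deviation model ({res.method}, converged={res.converged}):")
    print(table.to_string())

    beta_spec = st.ModelSpec("prop_moving_shrunk", ["leg_length"],
                             random=["individual_id"], family="beta")
    res_b = st.fit_beta_glmm(beta_spec, windows)
    table_b = res_b.coef_table()
    table_b.index.name = "term"
    table_b.to_csv(out / "coefs_moving.csv")
    print("proportion-moving beta model:")
    print(table_b.to_string())
    return 0


if __name__ == "__main__":
    sys.exit(main())
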