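"""Shared paths and parameters for the numbered analysis scripts.

Every script takes ``--seed`` (default 0) and ``--results`` (default
``results/`` next to this file); stage outputs are plain CSV/JSON so each
script can be re-run independently after its inputs exist.
"""

from __future__ import annotations

import argparse
from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"

# one full synthetic day at the calibrated troop size
DAY_SECONDS = 12 * 3600


def stage_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--results", type=Path, default=RESULTS)
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)
    return args
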