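"""Shared fixtures: a calibrated troop and one short synthetic day.

The day fixture is session-scoped; it is the most expensive object the
unit tests need and is deliberately short (2 h) to keep the suite fast.
"""

import numpy as np
import pytest

from troopsim import synthetic as syn


@pytest.fixture(scope="session")
def troop():
    return syn.make_troop(syn.TroopConfig(seed=0))


@pytest.fixture(scope="session")
def leg_lengths(troop):
    return np.array([ind.leg_length for ind in troop])


@pytest.fixture(scope="session")
def short_day(troop):
    """(tracks, labels, schedule) for a 2 h synthetic day."""
    schedule = syn.make_day_schedule(seed=1, total_duration=2 * 3600)
    tracks, labels = syn.simulate_day(troop, schedule, syn.MotionParams(),
                                      seed=2)
    return tracks, labels, schedule


@pytest.fixture(scope="session")
def short_day_accel(troop, short_day):
    tracks, labels, _ = short_day
    return syn.synth_troop_accel(tracks, labels, troop, syn.AccelParams(),
                                 seed=3)
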