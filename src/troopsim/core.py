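"""Shared in-memory containers for troop biologger data.

Coordinates are local planar metres (east = +x, north = +y); timestamps are
UTC epoch seconds. GPS tracks are on a common 1 Hz grid; accelerometry is on
a 12 Hz grid nested inside the GPS seconds. Missing data are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GPS_HZ = 1.0
ACCEL_HZ = 12.0
GRAVITY = 9.81


@dataclass
class TrackSet:
    """GPS tracks for a set of individuals on a common 1 Hz time grid.

    Attributes
    ----------
    ids : list of str
        Individual identifiers, one per row of ``xy``.
    times : ndarray, shape (T,)
        Epoch seconds, strictly increasing, 1 s apart.
    xy : ndarray, shape (N, T, 2)
        Planar positions in metres; NaN marks missing fixes.
    """

    ids: list
    times: np.ndarray
    xy: np.ndarray

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_seconds(self) -> int:
        return len(self.times)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (len(self.ids), len(self.times), 2):
            raise ValueError(
                f"xy shape {self.xy.shape} inconsistent with "
                f"{len(self.ids)} ids and {len(self.times)} times"
            )


@dataclass
class AccelSeries:
    """Tri-axial accelerometry for one individual at 12 Hz.

    Axes follow the collar convention: surge (anterior-posterior), sway
    (lateral), heave (dorsal-ventral, carrying gravity and footfalls).
    Missing samples are NaN in all three axes.
    """

    times: np.ndarray
    surge: np.ndarray
    sway: np.ndarray
    heave: np.ndarray

    def __post_init__(self):
        n = len(self.times)
        for name in ("surge", "sway", "heave"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"axis {name!r} length mismatch with times")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.heave)

    def copy(self) -> "AccelSeries":
        return AccelSeries(
            self.times.copy(), self.surge.copy(), self.sway.copy(), self.heave.copy()
        )


def rng_from_seed(seed) -> np.random.Generator:
    """Accept an int seed or a Generator and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
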