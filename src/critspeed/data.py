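"""Per-participant trial containers.

A :class:`TrialSet` holds one participant's exhaustive constant-speed
runs: the controlled speeds (m/s) and the measured times to exhaustion
(s).  Distance per trial is derived as speed * time.  The typical design
is four trials at 90, 100, 110 and 120 % of the peak speed of a maximal
incremental treadmill test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrialSet"]


@dataclass(frozen=True)
class TrialSet:
    """Observations for one participant.

    Parameters
    ----------
    participant_id : str
        Participant label.
    speeds : array-like of float
        Trial speeds, m/s; strictly positive and pairwise distinct.
    times : array-like of float
        Times to exhaustion, s; strictly positive, one per speed.
    peak_speed : float, optional
        Peak speed (PS) of the incremental test, m/s.
    """

    participant_id: str
    speeds: np.ndarray
    times: np.ndarray
    peak_speed: float | None = None

    def __post_init__(self) -> None:
        speeds = np.array(self.speeds, dtype=float)
        times = np.array(self.times, dtype=float)
        if speeds.ndim != 1 or times.ndim != 1 or speeds.size != times.size:
            raise ValueError("speeds and times must be 1-D arrays of equal length")
        if speeds.size == 0:
            raise ValueError("at least one observation is required")
        if np.any(speeds <= 0) or np.any(times <= 0):
            raise ValueError("speeds and times must be strictly positive")
        if np.unique(speeds).size != speeds.size:
            raise ValueError("trial speeds must be pairwise distinct")
        if self.peak_speed is not None and not self.peak_speed > 0:
            raise ValueError("peak_speed must be positive when given")
        speeds.setflags(write=False)
        times.setflags(write=False)
        object.__setattr__(self, "speeds", speeds)
        object.__setattr__(self, "times", times)

    @property
    def distances(self) -> np.ndarray:
        """Distance covered per trial, m (speed * time)."""
        return self.speeds * self.times

    @property
    def n_obs(self) -> int:
        return int(self.speeds.size)

    @property
    def min_speed(self) -> float:
        return float(self.speeds.min())

    @property
    def max_speed(self) -> float:
        return float(self.speeds.max())

    def sorted_by_speed(self) -> "TrialSet":
        order = np.argsort(self.speeds)
        return TrialSet(self.participant_id, self.speeds[order], self.times[order], self.peak_speed)
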