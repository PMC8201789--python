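"""Mapping between incremental-test physiology and critical speed.

The maximal incremental treadmill protocol ramps speed by a fixed
increment every stage (default 0.28 m/s every 2 min after a 2.78 m/s
warm-up), so attained speed is affine in time: s = 2.78 + 0.14 t with t
in minutes.  Inverting that line converts a critical-speed estimate to
the test time at which it was reached; inserting that time into the
participant's linear VO2-vs-time regression yields the oxygen uptake at
CS, expressible as a percent of VO2max.  Peak speed credits the
fraction of the uncompleted final stage: PS = s_VO2max + alpha * delta_s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "Protocol",
    "IncrementalProfile",
    "Vo2AtCs",
    "peak_speed",
    "incremental_time_at_speed",
    "vo2_at_cs",
    "relative_cs",
]


@dataclass(frozen=True)
class Protocol:
    """Incremental treadmill protocol geometry.

    The implied speed-time line is s = warmup_speed +
    (increment/step_duration) * t, with t in minutes.
    """

    warmup_speed: float = 2.78  # m/s
    increment: float = 0.28  # m/s per stage
    step_duration: float = 2.0  # min per stage

    def __post_init__(self) -> None:
        if min(self.warmup_speed, self.increment, self.step_duration) <= 0:
            raise ValueError("protocol fields must be positive")

    @property
    def slope(self) -> float:
        """m/s gained per minute."""
        return self.increment / self.step_duration

    def speed_at_time(self, minutes: float) -> float:
        return self.warmup_speed + self.slope * minutes


@dataclass(frozen=True)
class IncrementalProfile:
    """One participant's incremental-test summary.

    vo2_line is the (intercept, slope) of the linear VO2-vs-time
    regression over the test, in ml/min/kg and ml/min/kg per minute.
    """

    participant_id: str
    s_vo2max: float  # speed of last completed stage, m/s
    alpha: float  # fraction of the uncompleted final stage, [0, 1)
    vo2max: float  # ml/min/kg
    vt: float | None = None  # ventilatory threshold, ml/min/kg
    rcp: float | None = None  # respiratory compensation point, ml/min/kg
    vo2_intercept: float | None = None
    vo2_slope: float | None = None
    r_squared: float | None = None
    delta_s: float = 0.28

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must lie in [0, 1)")
        if self.vo2_slope is not None and self.vo2_slope < 0:
            raise ValueError("vo2 slope must be non-negative")

    @property
    def peak_speed(self) -> float:
        return peak_speed(self.s_vo2max, self.alpha, self.delta_s)


def peak_speed(s_vo2max: float, alpha: float, delta_s: float = 0.28) -> float:
    """PS = s_VO2max + alpha * delta_s (fractional final-stage credit)."""
    if not 0 <= alpha < 1:
        raise ValueError("alpha must lie in [0, 1)")
    return s_vo2max + alpha * delta_s


def incremental_time_at_speed(speed: float, protocol: Protocol = Protocol()) -> float:
    """Minutes into the incremental test at which ``speed`` is reached."""
    if speed < protocol.warmup_speed:
        raise ValueError(
            f"speed {speed} m/s below the warm-up speed {protocol.warmup_speed} m/s"
        )
    return (speed - protocol.warmup_speed) / protocol.slope


class Vo2AtCs(NamedTuple):
    vo2: float  # ml/min/kg
    percent_vo2max: float  # %
    extrapolated: bool  # CS above the peak speed actually attained


def vo2_at_cs(
    profile: IncrementalProfile, cs: float, protocol: Protocol = Protocol()
) -> Vo2AtCs:
    """Oxygen uptake at a CS estimate via the test's VO2-vs-time line.

    CS above the attained peak speed is extrapolation beyond the test
    end and is returned with ``extrapolated=True`` rather than raising.
    """
    if profile.vo2_intercept is None or profile.vo2_slope is None:
        raise ValueError("profile carries no VO2-vs-time regression")
    minutes = incremental_time_at_speed(cs, protocol)  # raises below warm-up speed
    vo2 = profile.vo2_intercept + profile.vo2_slope * minutes
    return Vo2AtCs(
        vo2=float(vo2),
        percent_vo2max=100.0 * float(vo2) / profile.vo2max,
        extrapolated=cs > profile.peak_speed,
    )


def relative_cs(cs: float, reference: float) -> float:
    """CS as a percent of a reference speed (e.g. s_VO2max)."""
    if not reference > 0:
        raise ValueError("reference speed must be positive")
    return 100.0 * cs / reference
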