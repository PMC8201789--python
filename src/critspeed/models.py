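"""Closed-form power-duration models for running.

The sustainable-duration curve t(s) relates a constant running speed s
(m/s) to the time t (s) it can be held before exhaustion.  Three model
families are implemented, each in two mathematically equivalent
formulations: time as a function of speed, and distance as a function of
speed, with d(s) = s * t(s).

====================  ==========================================  =============
family                t(s)                                        parameters
====================  ==========================================  =============
two-parameter         d' / (s - CS)                               CS, d'
three-parameter       d' (s_max - s) / [(s - CS)(s_max - CS)]     CS, d', s_max
three-parameter exp.  tau * ln[(s_max - CS) / (s - CS)]           CS, tau, s_max
====================  ==========================================  =============

CS is the critical speed (m/s), the asymptote of the speed-duration
relationship and the boundary between the heavy and severe exercise
intensity domains.  d' (m) is the finite distance that can be run above
CS.  s_max (m/s) is the maximal instantaneous running speed, at which
the predicted duration falls to zero.  tau (s) is the time constant of
the exponential family, whose logarithm is natural throughout.

The exponential family carries no native d' parameter: the distance
runnable above CS is transient, d'(t) = t (s_max - CS) e^(-t/tau),
which vanishes at t = 0 and is maximal at t = tau.  Its maximum,
d'_max = tau (s_max - CS) / e, serves as the d' estimate whenever the
exponential family is compared with the other two.

All functions are pure, operate in SI units (m/s, s, m), and accept
scalars or numpy arrays for the speed/time argument.  Speeds at or
below CS (infinite or undefined duration) and, for three-parameter
families, above s_max raise :class:`DomainError`; speed equal to s_max
returns exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

import numpy as np

__all__ = [
    "ModelFamily",
    "Formulation",
    "ModelSpec",
    "Params",
    "SpeedDomain",
    "DomainError",
    "BATTERY",
    "PARAM_NAMES",
    "speed_domain",
    "predict_time",
    "predict_distance",
    "predict",
    "speed_from_time_two_param",
    "dprime_transient_exp",
    "dprime_max_exp",
]


class DomainError(ValueError):
    """Evaluation requested outside a model's speed/time domain."""


class ModelFamily(str, Enum):
    """The three power-duration model families."""

    TWO_PARAM = "2p"
    THREE_PARAM = "3p"
    THREE_PARAM_EXP = "3pexp"


class Formulation(str, Enum):
    """Which dependent variable the model predicts (and WLS minimises).

    Speed is the controlled (independent) variable of an exhaustive
    constant-speed trial; time to exhaustion and distance (= speed x
    time) are the measured dependent variables.  The d(t)/t(d)
    variants are deliberately not implemented: there the errors of the
    two 'dependent' variables are perfectly correlated through the
    error-free speed (endogeneity), which no standard regression
    handles.
    """

    TIME_OF_SPEED = "ts"
    DISTANCE_OF_SPEED = "ds"


@dataclass(frozen=True)
class ModelSpec:
    """A (family, formulation) cell of the six-fit battery."""

    family: ModelFamily
    formulation: Formulation

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", ModelFamily(self.family))
        object.__setattr__(self, "formulation", Formulation(self.formulation))


#: Fixed battery order: families in increasing complexity, t(s) before d(s).
BATTERY: tuple[ModelSpec, ...] = tuple(
    ModelSpec(fam, form)
    for fam in (ModelFamily.TWO_PARAM, ModelFamily.THREE_PARAM, ModelFamily.THREE_PARAM_EXP)
    for form in (Formulation.TIME_OF_SPEED, Formulation.DISTANCE_OF_SPEED)
)

#: Free parameters per family, in fit order.
PARAM_NAMES: dict[ModelFamily, tuple[str, ...]] = {
    ModelFamily.TWO_PARAM: ("cs", "d_prime"),
    ModelFamily.THREE_PARAM: ("cs", "d_prime", "s_max"),
    ModelFamily.THREE_PARAM_EXP: ("cs", "tau", "s_max"),
}


@dataclass(frozen=True)
class Params:
    """Model parameters; only the fields a family uses need be set.

    Attributes
    ----------
    cs : float
        Critical speed, m/s.  Required, > 0.
    d_prime : float, optional
        Distance runnable above CS, m.  > 0 when present.
    s_max : float, optional
        Maximal instantaneous speed, m/s.  > cs when present.
    tau : float, optional
        Exponential time constant, s.  > 0 when present.
    """

    cs: float
    d_prime: float | None = None
    s_max: float | None = None
    tau: float | None = None

    def __post_init__(self) -> None:
        if not self.cs > 0:
            raise ValueError(f"cs must be > 0, got {self.cs}")
        if self.d_prime is not None and not self.d_prime > 0:
            raise ValueError(f"d_prime must be > 0, got {self.d_prime}")
        if self.s_max is not None and not self.s_max > self.cs:
            raise ValueError(f"s_max must exceed cs, got s_max={self.s_max}, cs={self.cs}")
        if self.tau is not None and not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")

    def require(self, family: ModelFamily) -> None:
        """Raise if any parameter the family needs is missing."""
        for name in PARAM_NAMES[ModelFamily(family)]:
            if getattr(self, name) is None:
                raise ValueError(f"{ModelFamily(family).name} requires parameter '{name}'")

    def as_array(self, family: ModelFamily) -> np.ndarray:
        self.require(family)
        return np.array([getattr(self, n) for n in PARAM_NAMES[ModelFamily(family)]], dtype=float)

    @classmethod
    def from_array(cls, family: ModelFamily, theta: np.ndarray) -> "Params":
        return cls(**dict(zip(PARAM_NAMES[ModelFamily(family)], map(float, theta))))


class SpeedDomain(NamedTuple):
    """Open-below interval of speeds with finite positive predicted time."""

    lower: float  # exclusive: CS
    upper: float  # inclusive: s_max, or +inf for the two-parameter family


def speed_domain(family: ModelFamily, params: Params) -> SpeedDomain:
    """Speeds where the family's t(s) is finite and non-negative."""
    family = ModelFamily(family)
    params.require(family)
    upper = math.inf if family is ModelFamily.TWO_PARAM else float(params.s_max)
    return SpeedDomain(float(params.cs), upper)


def _check_speed(family: ModelFamily, params: Params, s: np.ndarray) -> None:
    if np.any(s <= params.cs):
        raise DomainError(
            f"speed must exceed cs={params.cs} m/s (time to exhaustion undefined/infinite below CS)"
        )
    if family is not ModelFamily.TWO_PARAM and np.any(s > params.s_max):
        raise DomainError(f"speed must not exceed s_max={params.s_max} m/s")


def predict_time(family: ModelFamily, params: Params, speed) -> np.ndarray | float:
    """Time to exhaustion t(s) in seconds at constant speed(s) ``speed``.

    Strictly positive and strictly decreasing over the family's speed
    domain; exactly 0.0 at ``speed == s_max`` for three-parameter
    families.
    """
    family = ModelFamily(family)
    params.require(family)
    s = np.asarray(speed, dtype=float)
    scalar = s.ndim == 0
    s = np.atleast_1d(s)
    _check_speed(family, params, s)
    if family is ModelFamily.TWO_PARAM:
        t = params.d_prime / (s - params.cs)
    elif family is ModelFamily.THREE_PARAM:
        t = params.d_prime * (params.s_max - s) / ((s - params.cs) * (params.s_max - params.cs))
    else:
        t = params.tau * np.log((params.s_max - params.cs) / (s - params.cs))
    return float(t[0]) if scalar else t


def predict_distance(family: ModelFamily, params: Params, speed) -> np.ndarray | float:
    """Distance d(s) = s * t(s) in metres; same domain as `predict_time`."""
    s = np.asarray(speed, dtype=float)
    return s * predict_time(family, params, speed) if s.ndim else float(s) * predict_time(
        family, params, speed
    )


def predict(spec: ModelSpec, params: Params, speed) -> np.ndarray | float:
    """Evaluate the dependent variable named by the ModelSpec's formulation."""
    if spec.formulation is Formulation.TIME_OF_SPEED:
        return predict_time(spec.family, params, speed)
    return predict_distance(spec.family, params, speed)


def speed_from_time_two_param(params: Params, time) -> np.ndarray | float:
    """Two-parameter inverse s(t) = d'/t + CS; asymptotes to CS as t grows."""
    params.require(ModelFamily.TWO_PARAM)
    t = np.asarray(time, dtype=float)
    if np.any(t <= 0):
        raise DomainError("time must be strictly positive")
    out = params.d_prime / t + params.cs
    return float(out) if t.ndim == 0 else out


def dprime_transient_exp(params: Params, time) -> np.ndarray | float:
    """Transient distance above CS, d'(t) = t (s_max - CS) e^(-t/tau).

    Defined for the exponential family only; zero at t = 0 and maximal
    at t = tau.
    """
    params.require(ModelFamily.THREE_PARAM_EXP)
    t = np.asarray(time, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be non-negative")
    out = t * (params.s_max - params.cs) * np.exp(-t / params.tau)
    return float(out) if t.ndim == 0 else out


def dprime_max_exp(params: Params) -> float:
    """d'_max = tau (s_max - CS) / e, the exponential family's d' estimate."""
    params.require(ModelFamily.THREE_PARAM_EXP)
    return float(params.tau * (params.s_max - params.cs) / math.e)
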