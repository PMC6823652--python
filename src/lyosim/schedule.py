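"""Piecewise setpoint-and-ramp schedules for shelf temperature and chamber
pressure.

A schedule starts at an initial value and proceeds through ordered segments,
each ramping linearly to a target at a given rate (units per minute) and then
holding for a duration.  After the last segment the final value holds
indefinitely, so a schedule is defined for every t >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError


@dataclass(frozen=True)
class Segment:
    target: float  # setpoint in schedule units (degC or Torr)
    ramp_rate: float = 0.0  # units per minute; required > 0 if target changes
    hold: float = 0.0  # h


class Schedule:
    """Continuous piecewise-linear setpoint profile."""

    def __init__(self, initial: float, segments: tuple[Segment, ...] | list[Segment] = ()):
        self.initial = float(initial)
        self.segments = tuple(segments)
        # Precompute linear pieces as (t_start, t_end, v_start, v_end).
        pieces: list[tuple[float, float, float, float]] = []
        t = 0.0
        value = self.initial
        for seg in self.segments:
            if seg.hold < 0:
                raise InvalidInputError("hold duration must be nonnegative")
            if seg.target != value:
                if seg.ramp_rate <= 0:
                    raise InvalidInputError(
                        "ramp_rate must be positive when the target differs "
                        "from the previous setpoint"
                    )
                ramp_h = abs(seg.target - value) / (seg.ramp_rate * 60.0)
                pieces.append((t, t + ramp_h, value, seg.target))
                t += ramp_h
                value = seg.target
            if seg.hold > 0:
                pieces.append((t, t + seg.hold, value, value))
                t += seg.hold
        self._pieces = pieces
        self._duration = t
        self._final = value

    @classmethod
    def constant(cls, value: float) -> "Schedule":
        return cls(value)

    @property
    def duration(self) -> float:
        """Total scheduled time (h); the final value holds beyond it."""
        return self._duration

    @property
    def final_value(self) -> float:
        return self._final

    def value(self, t: float) -> float:
        """Setpoint at time ``t`` (h)."""
        if t < 0:
            raise InvalidInputError("schedule time must be nonnegative")
        for t0, t1, v0, v1 in self._pieces:
            if t <= t1:
                if t1 == t0:
                    return v1
                return v0 + (v1 - v0) * (t - t0) / (t1 - t0)
        return self._final

    __call__ = value

    def values(self, t) -> np.ndarray:
        return np.array([self.value(ti) for ti in np.atleast_1d(np.asarray(t, float))])
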