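"""Deterministic actuator schedules for the flush / clean / dry cycle.

Once an event is decided, the controller runs a fixed timed sequence:

* stool (or stool-and-urine): both flush valves and the water pump
  start immediately; the vacuum pump joins after 5 s; pump and valves
  stop at 10 s; the vacuum keeps pulling for 8 more s (off at 18 s);
* urine only: a 10 s delay first (time to detect a following stool),
  then the urine flush valve and pump for 5 s, then the vacuum alone
  for 10 s;
* cleaning: 15 s of the cleaning circuit(s), then drying — heater and
  fan on, the heater stops after 8 min and the fan 2 min later.

Alarms are threshold rules: the buzzer sounds when the patient's side
angle leaves ±30°, the clean-water level falls below its threshold, or
the dirt-tank level rises above its threshold.

Time is modeled as exact event timestamps in seconds; hardware clock
jitter is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from .evidence import EventLabel

__all__ = [
    "ACTUATORS",
    "Interval",
    "ActuatorSchedule",
    "AlarmInputs",
    "NoActionError",
    "run_flush",
    "run_clean_dry",
    "run_workflow",
    "check_alarms",
]

ACTUATORS = (
    "flush_valve_stool",
    "flush_valve_urine",
    "clean_valve_stool",
    "clean_valve_urine",
    "pump",
    "vacuum",
    "heater",
    "fan",
    "buzzer",
)

# Printed process timings, seconds.
FLUSH_PUMP_SOLO_S = 5.0       # pump alone before the vacuum joins (stool)
FLUSH_JOINT_S = 5.0           # pump + vacuum together (stool)
FLUSH_VACUUM_TAIL_S = 8.0     # vacuum alone after the pump stops (stool)
URINE_REDETECT_DELAY_S = 10.0
URINE_PUMP_S = 5.0
URINE_VACUUM_S = 10.0
CLEAN_S = 15.0
HEATER_S = 8 * 60.0
FAN_TAIL_S = 2 * 60.0


class NoActionError(ValueError):
    """Raised when a workflow is requested for a no-detection event."""


@dataclass(frozen=True)
class Interval:
    actuator: str
    on_s: float
    off_s: float

    def __post_init__(self) -> None:
        if self.actuator not in ACTUATORS:
            raise ValueError(f"unknown actuator {self.actuator!r}")
        if not self.off_s > self.on_s:
            raise ValueError(
                f"{self.actuator}: off time {self.off_s} not after on time {self.on_s}"
            )

    @property
    def duration(self) -> float:
        return self.off_s - self.on_s


@dataclass(frozen=True)
class ActuatorSchedule:
    """Timed on/off intervals; one actuator's intervals never overlap."""

    intervals: tuple[Interval, ...]

    def __post_init__(self) -> None:
        by_act: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            by_act.setdefault(iv.actuator, []).append(iv)
        for act, ivs in by_act.items():
            ivs = sorted(ivs, key=lambda iv: iv.on_s)
            for a, b in zip(ivs, ivs[1:]):
                if b.on_s < a.off_s:
                    raise ValueError(f"overlapping intervals for {act}")

    def on_time(self, actuator: str) -> float:
        """Total seconds the actuator is on."""
        return sum(iv.duration for iv in self.intervals if iv.actuator == actuator)

    def actuators(self) -> set[str]:
        return {iv.actuator for iv in self.intervals}

    @property
    def start(self) -> float:
        return min(iv.on_s for iv in self.intervals)

    @property
    def end(self) -> float:
        return max(iv.off_s for iv in self.intervals)

    def shifted(self, offset: float) -> "ActuatorSchedule":
        return ActuatorSchedule(tuple(
            Interval(iv.actuator, iv.on_s + offset, iv.off_s + offset)
            for iv in self.intervals
        ))

    def merged(self, other: "ActuatorSchedule") -> "ActuatorSchedule":
        return ActuatorSchedule(self.intervals + other.intervals)

    def timeline(self) -> str:
        lines = [
            f"{iv.on_s:8.1f}s - {iv.off_s:8.1f}s  {iv.actuator}"
            for iv in sorted(self.intervals, key=lambda iv: (iv.on_s, iv.actuator))
        ]
        return "\n".join(lines)


def _require_action(label: EventLabel) -> None:
    if label is EventLabel.NONE:
        raise NoActionError("no flushing/cleaning workflow for a no-detection event")


def run_flush(label: EventLabel) -> ActuatorSchedule:
    """Flushing schedule for a decided event, starting at t = 0."""
    _require_action(label)
    if label in (EventLabel.STOOL, EventLabel.BOTH):
        pump_off = FLUSH_PUMP_SOLO_S + FLUSH_JOINT_S
        return ActuatorSchedule((
            Interval("flush_valve_stool", 0.0, pump_off),
            Interval("flush_valve_urine", 0.0, pump_off),
            Interval("pump", 0.0, pump_off),
            Interval("vacuum", FLUSH_PUMP_SOLO_S,
                     pump_off + FLUSH_VACUUM_TAIL_S),
        ))
    # urine: wait for a possible follow-up stool, then a gentler flush
    t0 = URINE_REDETECT_DELAY_S
    return ActuatorSchedule((
        Interval("flush_valve_urine", t0, t0 + URINE_PUMP_S),
        Interval("pump", t0, t0 + URINE_PUMP_S),
        Interval("vacuum", t0 + URINE_PUMP_S,
                 t0 + URINE_PUMP_S + URINE_VACUUM_S),
    ))


def run_clean_dry(label: EventLabel) -> ActuatorSchedule:
    """Cleaning + drying schedule for a decided event, starting at t = 0."""
    _require_action(label)
    if label in (EventLabel.STOOL, EventLabel.BOTH):
        cleaning = [
            Interval("clean_valve_stool", 0.0, CLEAN_S),
            Interval("clean_valve_urine", 0.0, CLEAN_S),
            Interval("pump", 0.0, CLEAN_S),
            Interval("vacuum", 0.0, CLEAN_S),
        ]
    else:
        cleaning = [Interval("clean_valve_urine", 0.0, CLEAN_S)]
    drying = [
        Interval("heater", CLEAN_S, CLEAN_S + HEATER_S),
        Interval("fan", CLEAN_S, CLEAN_S + HEATER_S + FAN_TAIL_S),
    ]
    return ActuatorSchedule(tuple(cleaning + drying))


def run_workflow(label: EventLabel) -> ActuatorSchedule:
    """Full flush → clean → dry sequence for one decided event."""
    flush = run_flush(label)
    clean = run_clean_dry(label).shifted(flush.end)
    return flush.merged(clean)


@dataclass(frozen=True)
class AlarmInputs:
    """Side angle (degrees) and tank levels as fractions of threshold."""

    side_angle_deg: float
    clean_water_level: float = 1.0
    dirt_level: float = 0.0

    def __post_init__(self) -> None:
        if not -180.0 <= self.side_angle_deg <= 180.0:
            raise ValueError(f"side angle {self.side_angle_deg} outside sensor range")
        if not (math.isfinite(self.clean_water_level) and math.isfinite(self.dirt_level)):
            raise ValueError("tank levels must be finite")


def check_alarms(inputs: AlarmInputs) -> list[str]:
    """Threshold alarms; any alarm also activates the buzzer."""
    alarms: list[str] = []
    if not -30.0 <= inputs.side_angle_deg <= 30.0:
        alarms.append("side_angle")
    if inputs.clean_water_level < 1.0:
        alarms.append("clean_water_low")
    if inputs.dirt_level > 1.0:
        alarms.append("dirt_tank_high")
    if alarms:
        alarms.append("buzzer")
    return alarms
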