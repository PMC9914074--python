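"""Synthetic excretion events and the datasheet-faithful sensor model.

The generator stands in for bench data collection: each simulated
event draws one true excursion per channel from its class's interval
(uniformly), holds it constant across the session — the excretion
happened once; only sensor noise varies between the reads taken at
nearby moments — and pushes every read through an observation model
with Gaussian noise, datasheet range clipping and output quantization:

* humidity: measurable 0–99.9 %RH, 0.1 %RH steps;
* temperature: −40–80 °C, 0.1 °C steps;
* ammonia: detectable 1–300 ppm, readings below 1 ppm report 0.

Unbounded interval sides need sampling caps; the defaults cap urine at
x < 4 °C, y < 45 %RH, z < 10 ppm above baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .evidence import EventLabel
from .pipeline import ReadingSession
from .thresholds import CHANNELS

__all__ = [
    "SensorSpec",
    "SimConfig",
    "apply_sensor_model",
    "simulate_event",
    "simulate_dataset",
]

_CLASS_ORDER = (EventLabel.URINE, EventLabel.STOOL, EventLabel.BOTH, EventLabel.NONE)


@dataclass(frozen=True)
class SensorSpec:
    """Measurable range, detection floor and resolution of one channel."""

    lo: float
    hi: float
    resolution: float = 0.1
    detection_floor: float | None = None  # readings below it report 0

    def observe(self, value: float) -> float:
        if self.detection_floor is not None and value < self.detection_floor:
            return 0.0
        clipped = min(max(value, self.lo), self.hi)
        if self.resolution > 0:
            clipped = round(clipped / self.resolution) * self.resolution
        return float(min(max(clipped, self.lo), self.hi))


#: Datasheet specs: DHT22 temperature/humidity, GM-802B ammonia.
DEFAULT_SENSORS: Mapping[str, SensorSpec] = {
    "temperature": SensorSpec(lo=-40.0, hi=80.0),
    "humidity": SensorSpec(lo=0.0, hi=99.9),
    "ammonia": SensorSpec(lo=0.0, hi=300.0, detection_floor=1.0),
}


def _default_class_deltas() -> dict[EventLabel, dict[str, tuple[float, float]]]:
    return {
        EventLabel.STOOL: {
            "temperature": (0.5, 2.0), "humidity": (5.0, 12.0), "ammonia": (1.0, 2.0)
        },
        EventLabel.URINE: {
            "temperature": (1.8, 4.0), "humidity": (20.0, 45.0), "ammonia": (2.0, 10.0)
        },
        EventLabel.BOTH: {
            "temperature": (0.0, 1.0), "humidity": (12.0, 20.0), "ammonia": (1.0, 2.0)
        },
        EventLabel.NONE: {
            "temperature": (0.0, 0.0), "humidity": (0.0, 0.0), "ammonia": (0.0, 0.0)
        },
    }


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic benchmark.

    Class excursions are uniform within the detection-basis intervals
    (with caps on unbounded sides); per-read Gaussian noise SDs default
    to 0.4 °C / 4 %RH / 0.6 ppm — of the order of the sensor accuracies
    plus environmental fluctuation; three cycles of two reads each.
    """

    baseline_temperature: float = 22.0
    baseline_humidity: float = 40.0
    ambient_ammonia: float = 0.0
    class_deltas: Mapping[EventLabel, Mapping[str, tuple[float, float]]] = field(
        default_factory=_default_class_deltas
    )
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"temperature": 0.4, "humidity": 4.0, "ammonia": 0.6}
    )
    sensors: Mapping[str, SensorSpec] = field(
        default_factory=lambda: dict(DEFAULT_SENSORS)
    )
    cycles: int = 3
    reads_per_cycle: int = 2

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise SDs must be non-negative")
        for lab, chans in self.class_deltas.items():
            for ch, (lo, hi) in chans.items():
                if hi < lo:
                    raise ValueError(f"cap below lower bound: {lab}/{ch} ({lo}, {hi})")
        if self.cycles < 1 or self.reads_per_cycle < 1:
            raise ValueError("need at least one cycle and one read per cycle")

    def baselines(self) -> dict[str, float]:
        return {
            "temperature": self.baseline_temperature,
            "humidity": self.baseline_humidity,
            "ammonia": self.ambient_ammonia,
        }

    def with_noise(self, temperature: float, humidity: float, ammonia: float) -> "SimConfig":
        return replace(self, noise_sd={
            "temperature": temperature, "humidity": humidity, "ammonia": ammonia
        })


def apply_sensor_model(
    true_value: float,
    channel: str,
    spec: SensorSpec,
    rng: np.random.Generator,
    noise_sd: float = 0.0,
) -> float:
    """One noisy, clipped, quantized reading of a true physical value."""
    if not np.isfinite(true_value):
        raise ValueError(f"non-finite true value for {channel}: {true_value}")
    noisy = true_value + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
    return spec.observe(noisy)


def simulate_event(
    label: EventLabel,
    config: SimConfig,
    rng: np.random.Generator,
    session_id: str = "sim-0",
) -> ReadingSession:
    """Simulate one labeled excretion event as a full reading session."""
    bases = config.baselines()
    true_abs: dict[str, float] = {}
    for ch in CHANNELS:
        lo, hi = config.class_deltas[label][ch]
        delta = float(rng.uniform(lo, hi)) if hi > lo else lo
        true_abs[ch] = bases[ch] + delta
    reads = {
        cycle: {
            ch: [
                apply_sensor_model(
                    true_abs[ch], ch, config.sensors[ch], rng, config.noise_sd[ch]
                )
                for _ in range(config.reads_per_cycle)
            ]
            for ch in CHANNELS
        }
        for cycle in range(1, config.cycles + 1)
    }
    return ReadingSession(session_id=session_id, reads=reads, true_label=label)


def simulate_dataset(
    n_per_class: int,
    config: SimConfig | None = None,
    seed: int = 0,
) -> list[ReadingSession]:
    """A balanced, shuffled, seed-reproducible collection of sessions."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    labels = [lab for lab in _CLASS_ORDER for _ in range(n_per_class)]
    order = rng.permutation(len(labels))
    sessions = []
    for i, idx in enumerate(order):
        sessions.append(
            simulate_event(labels[idx], config, rng, session_id=f"sim-{i:05d}")
        )
    return sessions
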