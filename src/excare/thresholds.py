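"""Interval detection basis, per-sensor BPAs, and the direct classifier.

The device decides what happened from how far each channel —
temperature (x, °C), relative humidity (y, %RH) and ammonia
concentration (z, ppm) — rises above the indoor baseline. The detection
basis maps each channel × event to a numeric excursion interval
(defaults: stool x∈(0.5,2), y∈(5,12), z∈(1,2); urine x>1.8, y>20,
z>2; urine-and-stool x∈(0,1), y∈(12,20), z∈(1,2); no-detection ≈ 0 on
every channel).

Two readings of those intervals coexist:

* soft, for evidence fusion — trapezoidal membership with a per-channel
  linear ramp outside each finite edge, normalized into a per-sensor
  basic probability assignment (:func:`build_bpa`);
* crisp, for the traditional direct classifier — a delta either is or
  is not in the printed interval, and the three channels' verdict sets
  are merged by majority vote (:func:`direct_classify`).

Boundary convention for the crisp reading: printed inequalities are
strict, which leaves shared boundaries undefined; a boundary value is
assigned to the upper interval (e.g. an ammonia excursion of exactly
2 ppm counts as urine, not stool), i.e. bounded intervals behave as
[lo, hi) and unbounded ones as [lo, ∞).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .evidence import DECISION_TIE_ORDER, EventLabel, MassFunction

__all__ = [
    "CHANNELS",
    "ChannelDeltas",
    "DetectionBasis",
    "compute_deltas",
    "channel_membership",
    "build_bpa",
    "direct_classify",
]

#: Channel order everywhere: the paper's M1, M2, M3 sensors.
CHANNELS = ("temperature", "humidity", "ammonia")

_EVENT_KEYS = {
    "urine": EventLabel.URINE,
    "stool": EventLabel.STOOL,
    "both": EventLabel.BOTH,
    "none": EventLabel.NONE,
}

_DEFAULT_BASIS_PATH = Path(__file__).parent / "data" / "table1.yaml"


class ConfigurationError(ValueError):
    """Malformed or incomplete detection-basis configuration."""


@dataclass(frozen=True)
class ChannelDeltas:
    """Excursions above baseline: x °C, y %RH, z ppm (z floored at 0)."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"non-finite delta {(self.x, self.y, self.z)}")

    def by_channel(self) -> dict[str, float]:
        return {"temperature": self.x, "humidity": self.y, "ammonia": self.z}


@dataclass(frozen=True)
class DetectionBasis:
    """The interval table plus environment baselines and ramp widths.

    ``intervals[channel][event]`` is an ``(lo, hi)`` pair, ``hi`` may be
    ``inf``; the NONE event is the degenerate point interval (0, 0),
    softened to a triangular membership whose half-width is the
    smallest positive lower bound of the channel's other events.
    """

    intervals: Mapping[str, Mapping[EventLabel, tuple[float, float]]]
    baseline_temperature: float
    baseline_humidity: float
    ambient_ammonia: float
    softness: Mapping[str, float] = field(
        default_factory=lambda: {"temperature": 0.3, "humidity": 3.0, "ammonia": 0.5}
    )

    def __post_init__(self) -> None:
        for ch in CHANNELS:
            if ch not in self.intervals:
                raise ConfigurationError(f"missing channel {ch!r} in basis")
            for lab, (lo, hi) in self.intervals[ch].items():
                if lab is not EventLabel.NONE and not lo < hi:
                    raise ConfigurationError(
                        f"empty interval {ch}/{lab.value}: ({lo}, {hi})"
                    )
        for name, v in (
            ("baseline_temperature", self.baseline_temperature),
            ("baseline_humidity", self.baseline_humidity),
            ("ambient_ammonia", self.ambient_ammonia),
        ):
            if v is None or not math.isfinite(v):
                raise ConfigurationError(f"missing or non-finite {name}")

    def none_halfwidth(self, channel: str) -> float:
        """Half-width of the NONE triangle: smallest positive lower bound."""
        los = [lo for lab, (lo, hi) in self.intervals[channel].items()
               if lab is not EventLabel.NONE and lo > 0]
        return min(los)

    # -- serialization -------------------------------------------------

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "DetectionBasis":
        try:
            env = cfg["environment"]
            channels = cfg["channels"]
        except KeyError as e:  # pragma: no cover - defensive
            raise ConfigurationError(f"basis config missing section {e}") from None
        intervals: dict[str, dict[EventLabel, tuple[float, float]]] = {}
        for ch, events in channels.items():
            intervals[ch] = {}
            for key, (lo, hi) in events.items():
                intervals[ch][_EVENT_KEYS[key]] = (float(lo), float(hi))
        return cls(
            intervals=intervals,
            baseline_temperature=float(env["temperature_c"]),
            baseline_humidity=float(env["humidity_rh"]),
            ambient_ammonia=float(env["ammonia_ppm"]),
            softness={k: float(v) for k, v in cfg.get(
                "softness", {"temperature": 0.3, "humidity": 3.0, "ammonia": 0.5}
            ).items()},
        )

    def to_mapping(self) -> dict:
        return {
            "environment": {
                "temperature_c": self.baseline_temperature,
                "humidity_rh": self.baseline_humidity,
                "ammonia_ppm": self.ambient_ammonia,
            },
            "channels": {
                ch: {lab.value: [lo, hi] for lab, (lo, hi) in events.items()}
                for ch, events in self.intervals.items()
            },
            "softness": dict(self.softness),
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DetectionBasis":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=False)

    @classmethod
    def default(cls) -> "DetectionBasis":
        """The packaged default basis (the printed interval table)."""
        return cls.from_yaml(_DEFAULT_BASIS_PATH)


def compute_deltas(
    reading: tuple[float, float, float], basis: DetectionBasis
) -> ChannelDeltas:
    """Absolute (°C, %RH, ppm) reading → excursions above baseline.

    The ammonia delta is floored at 0: ambient ammonia is the zero of
    the z scale and readings cannot be negative in absolute terms.
    """
    t, h, a = reading
    return ChannelDeltas(
        x=t - basis.baseline_temperature,
        y=h - basis.baseline_humidity,
        z=max(0.0, a - basis.ambient_ammonia),
    )


def _trapezoid(delta: float, lo: float, hi: float, ramp: float) -> float:
    """Trapezoidal membership with an entry ramp inside the lower edge
    and an exit ramp outside the upper edge, each of width ``ramp``.

    Rising: 0 at ``lo``, 1 at ``lo + ramp`` (inside the interval).
    Falling: 1 up to ``hi``, 0 at ``hi + ramp`` (outside). Where two
    classes share an edge — the lower class's ``hi`` equals the upper
    class's ``lo`` — the two memberships crossfade and sum to 1 across
    the transition zone, so boundary evidence is split gradually
    instead of jumping to full support of both classes at once. A
    lower edge at 0 likewise gives a vanishing excursion zero
    membership rather than counting it as evidence of an event.
    """
    if ramp <= 0:
        return 1.0 if lo <= delta <= hi else 0.0
    if lo == 0.0:
        # the interval abuts the no-excursion point: ramp up inside so
        # a vanishing signal carries no membership
        if delta <= 0.0:
            return 0.0
        rising = min(1.0, delta / ramp)
        falling = 1.0 if delta <= hi else max(0.0, 1.0 - (delta - hi) / ramp)
        return min(rising, falling)
    if lo <= delta <= hi:
        return 1.0
    dist = lo - delta if delta < lo else delta - hi
    return max(0.0, 1.0 - dist / ramp)


def channel_membership(
    delta: float, channel: str, basis: DetectionBasis
) -> dict[EventLabel, float]:
    """Soft membership of one channel's excursion in each event's interval.

    Trapezoidal: 1 inside the interval, a linear ramp of the channel's
    softness width outside each finite edge, 0 beyond. NONE is a
    triangular peak at 0 whose half-width is the channel's smallest
    positive lower bound, so "no excursion" keeps non-zero support
    under sensor noise.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    ramp = basis.softness[channel]
    scores: dict[EventLabel, float] = {}
    for lab, (lo, hi) in basis.intervals[channel].items():
        if lab is EventLabel.NONE:
            hw = basis.none_halfwidth(channel)
            scores[lab] = max(0.0, 1.0 - abs(delta) / hw)
        else:
            scores[lab] = _trapezoid(delta, lo, hi, ramp)
    return scores


def build_bpa(
    delta: float, channel: str, basis: DetectionBasis, scheme: str = "union"
) -> MassFunction:
    """One sensor's basic probability assignment from its excursion.

    Applied to the temperature, humidity and ammonia channels this
    yields the three per-cycle assignments M1, M2, M3. If every
    membership is (numerically) zero the full mass goes to NONE.

    Two schemes turn memberships into masses:

    * ``"union"`` (default): support a singleton shares with the
      composite event C = {u, s} belongs to the union, i.e. to C
      itself; only the singleton's *excess* membership over C stays on
      it (``m_A ∝ max(0, μ_A − μ_C)``, likewise B; ``m_C ∝ μ_C``).
      This is the standard evidence-theory treatment of ambiguous
      evidence: a sensor band that cannot tell stool from
      stool-and-urine asserts the disjunction, not a 50/50 split.
      Without it the more specific singleton always out-accumulates C
      under Dempster's rule (B gains the B·C cross terms, C only C·C)
      and the combined event could never be decided.
    * ``"proportional"``: memberships normalized as they stand, each
      event treated as an unrelated hypothesis.
    """
    scores = channel_membership(delta, channel, basis)
    if scheme == "proportional":
        return MassFunction.from_scores(scores)
    if scheme != "union":
        raise ValueError(f"unknown BPA scheme {scheme!r}")
    mu_c = scores[EventLabel.BOTH]
    adjusted = {
        EventLabel.URINE: max(0.0, scores[EventLabel.URINE] - mu_c),
        EventLabel.STOOL: max(0.0, scores[EventLabel.STOOL] - mu_c),
        EventLabel.BOTH: mu_c,
        EventLabel.NONE: scores[EventLabel.NONE],
    }
    return MassFunction.from_scores(adjusted)


def _crisp_events(delta: float, channel: str, basis: DetectionBasis) -> set[EventLabel]:
    """Events whose printed interval contains the excursion, crisp reading."""
    out: set[EventLabel] = set()
    for lab, (lo, hi) in basis.intervals[channel].items():
        if lab is EventLabel.NONE:
            if delta == 0.0:
                out.add(lab)
        elif math.isinf(hi):
            if delta >= lo:
                out.add(lab)
        elif lo <= delta < hi:
            out.add(lab)
    return out


def direct_classify(deltas: ChannelDeltas, basis: DetectionBasis) -> EventLabel:
    """Traditional threshold detection without evidence fusion.

    Each channel votes for every event whose interval contains its
    excursion; the event appearing in the most channel verdict sets
    wins. Ties follow the decision tie order (BOTH > STOOL > URINE >
    NONE); if no interval matched on any channel, the verdict is NONE.
    """
    votes: dict[EventLabel, int] = {lab: 0 for lab in EventLabel}
    for ch, d in deltas.by_channel().items():
        for lab in _crisp_events(d, ch, basis):
            votes[lab] += 1
    if all(v == 0 for v in votes.values()):
        return EventLabel.NONE
    best = DECISION_TIE_ORDER[0]
    for lab in DECISION_TIE_ORDER[1:]:
        if votes[lab] > votes[best]:
            best = lab
    return best
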