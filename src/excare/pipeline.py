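"""The fusion detection pipeline and its comparison with direct detection.

One candidate event yields a :class:`ReadingSession`: three detection
cycles, each containing a couple of raw reads per channel taken at
nearby moments. The pipeline

1. screens out obviously unreasonable reads (a robust 3-MAD rule
   against the session median) and averages the survivors per cycle;
2. converts each cycle's mean reading into excursions above baseline
   and builds the three per-sensor BPAs M1 (temperature), M2
   (humidity), M3 (ammonia);
3. fuses M1 ⊕ M2 ⊕ M3 within each cycle, then fuses the per-cycle
   results across cycles;
4. decides by the maximum fused mass.

Masses are epsilon-floored before every combination so a stray
certain-but-conflicting pair of sensors degrades gracefully instead of
producing an undefined total-conflict fusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .evaluate import ComparisonReport, compare_predictions
from .evidence import (
    EPSILON_FLOOR,
    EventLabel,
    MassFunction,
    TotalConflictError,
    decide,
    fuse_many,
)
from .thresholds import (
    CHANNELS,
    ChannelDeltas,
    DetectionBasis,
    build_bpa,
    compute_deltas,
    direct_classify,
)

__all__ = [
    "ReadingSession",
    "MalformedSessionError",
    "Preprocessed",
    "DetectionResult",
    "preprocess",
    "detect_event",
    "session_mean_deltas",
    "compare_with_baseline",
]

MAD_SCALE = 1.4826  # makes the MAD a consistent SD estimate under normality
DEFAULT_MAD_THRESHOLD = 3.0


class MalformedSessionError(ValueError):
    """A session violating the cycle/read structure invariants."""


@dataclass(frozen=True)
class ReadingSession:
    """Raw multi-read, multi-cycle sensor data for one candidate event.

    ``reads[cycle][channel]`` is the list of raw absolute readings for
    that cycle; every cycle must carry at least one read on each of the
    three channels.
    """

    session_id: str
    reads: Mapping[int, Mapping[str, Sequence[float]]]
    true_label: EventLabel | None = None

    def __post_init__(self) -> None:
        if not self.reads:
            raise MalformedSessionError(f"session {self.session_id!r} has no cycles")
        for cycle, chans in self.reads.items():
            for ch in CHANNELS:
                if ch not in chans or len(chans[ch]) == 0:
                    raise MalformedSessionError(
                        f"session {self.session_id!r} cycle {cycle}: "
                        f"missing reads for channel {ch!r}"
                    )

    @property
    def cycles(self) -> list[int]:
        return sorted(self.reads)

    def channel_reads(self, channel: str) -> list[float]:
        """All reads of one channel pooled across cycles, cycle order."""
        return [v for cyc in self.cycles for v in self.reads[cyc][channel]]


@dataclass(frozen=True)
class Preprocessed:
    """Per-cycle mean deltas plus the audit of screened-out reads."""

    cycle_deltas: Mapping[int, ChannelDeltas]
    dropped: tuple[tuple[int, str, float], ...]  # (cycle, channel, value)


def _mad_keep_mask(
    values: np.ndarray, center: float, scaled_mad: float, threshold: float
) -> np.ndarray:
    return np.abs(values - center) <= threshold * scaled_mad


def preprocess(
    session: ReadingSession,
    basis: DetectionBasis,
    mad_threshold: float = DEFAULT_MAD_THRESHOLD,
) -> Preprocessed:
    """Screen unreasonable reads and average each cycle into deltas.

    Per channel, reads farther than ``mad_threshold`` scaled
    median-absolute-deviations from the *session* median are dropped;
    a cycle whose reads would all be dropped keeps them instead (the
    screen never silences a cycle). Survivors are averaged per cycle
    and turned into excursions above the basis baselines.
    """
    dropped: list[tuple[int, str, float]] = []
    cycle_means: dict[int, dict[str, float]] = {c: {} for c in session.cycles}
    for ch in CHANNELS:
        pooled = np.asarray(session.channel_reads(ch), dtype=float)
        center = float(np.median(pooled))
        scaled_mad = MAD_SCALE * float(np.median(np.abs(pooled - center)))
        for cycle in session.cycles:
            vals = np.asarray(session.reads[cycle][ch], dtype=float)
            keep = _mad_keep_mask(vals, center, scaled_mad, mad_threshold)
            if not keep.any():
                keep = np.ones_like(keep)
            else:
                dropped.extend(
                    (cycle, ch, float(v)) for v in vals[~keep]
                )
            cycle_means[cycle][ch] = float(vals[keep].mean())
    deltas = {
        cycle: compute_deltas(
            (means["temperature"], means["humidity"], means["ammonia"]), basis
        )
        for cycle, means in cycle_means.items()
    }
    return Preprocessed(cycle_deltas=deltas, dropped=tuple(dropped))


@dataclass(frozen=True)
class DetectionResult:
    """Everything the fusion run produced, decision plus audit trail."""

    session_id: str
    decided: EventLabel
    final_mass: MassFunction
    cycle_masses: Mapping[int, MassFunction]
    channel_bpas: Mapping[int, Mapping[str, MassFunction]]
    dropped_reads: tuple[tuple[int, str, float], ...] = ()
    true_label: EventLabel | None = None

    def __post_init__(self) -> None:
        if self.decided is not decide(self.final_mass):
            raise ValueError("decision inconsistent with final mass")

    def to_dict(self) -> dict:
        return {
            "session_id": self.session_id,
            "decided": self.decided.value,
            "true_label": self.true_label.value if self.true_label else None,
            "final_mass": self.final_mass.to_dict(),
            "cycle_masses": {c: m.to_dict() for c, m in self.cycle_masses.items()},
            "n_dropped_reads": len(self.dropped_reads),
        }


def detect_event(
    session: ReadingSession,
    basis: DetectionBasis,
    mad_threshold: float = DEFAULT_MAD_THRESHOLD,
    floor: float = EPSILON_FLOOR,
) -> DetectionResult:
    """Run the full per-cycle / cross-cycle fusion on one session."""
    prep = preprocess(session, basis, mad_threshold)
    channel_bpas: dict[int, dict[str, MassFunction]] = {}
    cycle_masses: dict[int, MassFunction] = {}
    try:
        for cycle, deltas in prep.cycle_deltas.items():
            bpas = {
                ch: build_bpa(d, ch, basis).floored(floor)
                for ch, d in deltas.by_channel().items()
            }
            channel_bpas[cycle] = bpas
            cycle_masses[cycle] = fuse_many(bpas[ch] for ch in CHANNELS)
        final = fuse_many(
            cycle_masses[c].floored(floor) for c in sorted(cycle_masses)
        )
    except TotalConflictError as e:
        raise TotalConflictError(
            f"session {session.session_id!r}: {e}"
        ) from e
    return DetectionResult(
        session_id=session.session_id,
        decided=decide(final),
        final_mass=final,
        cycle_masses=cycle_masses,
        channel_bpas=channel_bpas,
        dropped_reads=prep.dropped,
        true_label=session.true_label,
    )


def session_mean_deltas(session: ReadingSession, basis: DetectionBasis) -> ChannelDeltas:
    """Excursions from the plain mean of all raw reads — the single
    effective reading the traditional direct method consumes."""
    means = {
        ch: float(np.mean(session.channel_reads(ch))) for ch in CHANNELS
    }
    return compute_deltas(
        (means["temperature"], means["humidity"], means["ammonia"]), basis
    )


def compare_with_baseline(
    sessions: Sequence[ReadingSession],
    basis: DetectionBasis,
    mad_threshold: float = DEFAULT_MAD_THRESHOLD,
    corrected: bool = True,
) -> ComparisonReport:
    """Score fused vs direct detection on the same labeled sessions."""
    labeled = [s for s in sessions if s.true_label is not None]
    if not labeled:
        raise ValueError("compare_with_baseline needs at least one labeled session")
    truths = [s.true_label for s in labeled]
    fused = [detect_event(s, basis, mad_threshold).decided for s in labeled]
    direct = [direct_classify(session_mean_deltas(s, basis), basis) for s in labeled]
    return compare_predictions(fused, direct, truths, corrected=corrected)
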