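"""Mass-function algebra over the four-event excretion frame.

The detector distinguishes four outcomes of one candidate excretion
event: urine only (A), stool only (B), urine and stool together (C),
and nothing (D). The underlying frame of discernment has three atoms —
urine-present ``u``, stool-present ``s``, nothing ``n`` — and the four
events are the focal sets A = {u}, B = {s}, C = {u, s}, D = {n}.
Modelling C as the *union* of A and B (rather than a fourth atom) is
what makes A ∩ C = A and B ∩ C = B non-conflicting, which is exactly
how the normalization coefficient of Dempster's rule is expanded here.

Each sensor contributes a basic probability assignment (BPA, a mass
function) over these four events; Dempster's orthogonal sum ⊕ fuses
them by multiplying masses of intersecting focal sets and renormalizing
by the conflict coefficient K.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "EventLabel",
    "FOCAL_SETS",
    "MassFunction",
    "TotalConflictError",
    "conflict_coefficient",
    "combine",
    "fuse_many",
    "decide",
    "DECISION_TIE_ORDER",
]

_SUM_TOL = 1e-9
#: Mass floor applied before fusion in pipelines so that K never hits 0.
EPSILON_FLOOR = 1e-4


class EventLabel(str, enum.Enum):
    """The four mutually recognisable excretion events."""

    URINE = "urine"  # event A = {u}
    STOOL = "stool"  # event B = {s}
    BOTH = "both"    # event C = {u, s}
    NONE = "none"    # event D = {n}

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Focal set of each event over the atoms {u, s, n}.
FOCAL_SETS: Mapping[EventLabel, frozenset[str]] = {
    EventLabel.URINE: frozenset({"u"}),
    EventLabel.STOOL: frozenset({"s"}),
    EventLabel.BOTH: frozenset({"u", "s"}),
    EventLabel.NONE: frozenset({"n"}),
}

#: Tie-break order for decisions: prefer the label triggering the most
#: complete cleaning action, a fail-safe choice for a care device.
DECISION_TIE_ORDER = (
    EventLabel.BOTH,
    EventLabel.STOOL,
    EventLabel.URINE,
    EventLabel.NONE,
)


class TotalConflictError(ValueError):
    """Raised when two mass functions are totally conflicting (K = 0)."""


@dataclass(frozen=True)
class MassFunction:
    """Basic probability assignment over the four excretion events.

    Parameters
    ----------
    m_a, m_b, m_c, m_d:
        Masses on urine (A), stool (B), urine-and-stool (C) and
        no-detection (D). Non-negative and summing to 1 within 1e-9.
    """

    m_a: float
    m_b: float
    m_c: float
    m_d: float

    def __post_init__(self) -> None:
        masses = (self.m_a, self.m_b, self.m_c, self.m_d)
        if any(not math.isfinite(m) for m in masses):
            raise ValueError(f"non-finite mass in {masses}")
        if any(m < -_SUM_TOL for m in masses):
            raise ValueError(f"negative mass in {masses}")
        total = sum(masses)
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"masses sum to {total!r}, expected 1")

    def __getitem__(self, label: EventLabel) -> float:
        return {
            EventLabel.URINE: self.m_a,
            EventLabel.STOOL: self.m_b,
            EventLabel.BOTH: self.m_c,
            EventLabel.NONE: self.m_d,
        }[label]

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.m_a, self.m_b, self.m_c, self.m_d)

    def to_dict(self) -> dict[str, float]:
        return {"m_A": self.m_a, "m_B": self.m_b, "m_C": self.m_c, "m_D": self.m_d}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "MassFunction":
        return cls(d["m_A"], d["m_B"], d["m_C"], d["m_D"])

    @classmethod
    def from_scores(cls, scores: Mapping[EventLabel, float]) -> "MassFunction":
        """Normalize non-negative per-event scores into a mass function.

        All-zero scores collapse to full mass on NONE — no evidence of
        any excursion is evidence of nothing happening.
        """
        vals = [max(0.0, float(scores.get(lab, 0.0))) for lab in
                (EventLabel.URINE, EventLabel.STOOL, EventLabel.BOTH, EventLabel.NONE)]
        total = sum(vals)
        if total < 1e-9:
            return cls(0.0, 0.0, 0.0, 1.0)
        return cls(*(v / total for v in vals))

    def floored(self, eps: float = EPSILON_FLOOR) -> "MassFunction":
        """Return a copy with every mass floored at ``eps`` and renormalized.

        Pipelines fuse floored masses so a certain-but-conflicting pair
        (e.g. one sensor certain of urine, another certain of stool)
        degrades to near-certainty instead of an undefined K = 0 fusion.
        """
        vals = [max(m, eps) for m in self.as_tuple()]
        total = sum(vals)
        return MassFunction(*(v / total for v in vals))


def _pairwise_products(m1: MassFunction, m2: MassFunction):
    """Yield (intersection, product) over all focal-set pairs."""
    for lab1, set1 in FOCAL_SETS.items():
        for lab2, set2 in FOCAL_SETS.items():
            yield set1 & set2, m1[lab1] * m2[lab2]


def conflict_coefficient(m1: MassFunction, m2: MassFunction) -> float:
    """Normalization coefficient K of Dempster's rule for ``m1 ⊕ m2``.

    K is the total product mass landing on non-empty intersections,
    equivalently 1 minus the mass lost to empty intersections. On this
    frame it expands to the eight terms
    ``m1A·m2A + m1A·m2C + m1C·m2A + m1B·m2B + m1B·m2C + m1C·m2B +
    m1C·m2C + m1D·m2D``.

    Raises
    ------
    TotalConflictError
        If K = 0, i.e. the two assignments are irreconcilable.
    """
    k = sum(p for inter, p in _pairwise_products(m1, m2) if inter)
    if k <= 0.0:
        raise TotalConflictError(
            "total conflict between mass functions (K = 0); "
            "consider epsilon-floored masses"
        )
    return k


def combine(m1: MassFunction, m2: MassFunction) -> MassFunction:
    """Dempster's orthogonal sum ``m1 ⊕ m2``.

    Each fused event mass is the product mass of all focal-set pairs
    whose intersection equals that event's focal set, divided by K:

    * A: ``(m1A·m2A + m1A·m2C + m1C·m2A) / K``
    * B: ``(m1B·m2B + m1B·m2C + m1C·m2B) / K``
    * C: ``m1C·m2C / K``
    * D: ``m1D·m2D / K``
    """
    k = conflict_coefficient(m1, m2)
    acc: dict[frozenset[str], float] = {}
    for inter, p in _pairwise_products(m1, m2):
        if inter:
            acc[inter] = acc.get(inter, 0.0) + p
    fused = {lab: acc.get(fset, 0.0) / k for lab, fset in FOCAL_SETS.items()}
    return MassFunction(
        fused[EventLabel.URINE],
        fused[EventLabel.STOOL],
        fused[EventLabel.BOTH],
        fused[EventLabel.NONE],
    )


def fuse_many(masses: Iterable[MassFunction]) -> MassFunction:
    """Left-fold of :func:`combine` over an ordered collection.

    Dempster's rule is commutative and associative, so the association
    order does not matter (up to floating-point noise); a plain left
    fold is used. Raises ``ValueError`` on an empty collection and
    propagates :class:`TotalConflictError`.
    """
    it = iter(masses)
    try:
        result = next(it)
    except StopIteration:
        raise ValueError("fuse_many requires at least one mass function") from None
    for m in it:
        result = combine(result, m)
    return result


def decide(m: MassFunction) -> EventLabel:
    """Pick the event with the highest fused mass.

    Ties are broken by the fixed order BOTH > STOOL > URINE > NONE
    (:data:`DECISION_TIE_ORDER`).
    """
    best = DECISION_TIE_ORDER[0]
    for lab in DECISION_TIE_ORDER[1:]:
        if m[lab] > m[best]:
            best = lab
    return best
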