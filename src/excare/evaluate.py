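"""Scoring and the paired statistical comparison of two classifiers.

Fused and direct detection are run on the *same* trials, so their
accuracies are compared with McNemar's paired chi-square test on the
discordant pairs: b trials where fusion is wrong but direct is right,
c trials where fusion is right but direct is wrong. With continuity
correction,

    chi2 = (|b - c| - 1)^2 / (b + c),

significant at alpha = 0.05 when chi2 exceeds 3.841 (the 95th
percentile of chi-square with one degree of freedom). When b + c = 0
the test is undefined and reported as not applicable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .evidence import EventLabel

__all__ = [
    "LABEL_ORDER",
    "McNemarResult",
    "ComparisonReport",
    "accuracy",
    "paired_chi2",
    "confusion_matrix",
    "compare_predictions",
]

#: Row/column order of confusion matrices: A, B, C, D.
LABEL_ORDER = (EventLabel.URINE, EventLabel.STOOL, EventLabel.BOTH, EventLabel.NONE)

CHI2_CRITICAL_005 = 3.841


def accuracy(preds: Sequence[EventLabel], truths: Sequence[EventLabel]) -> float:
    """Percentage of predictions matching the truth (0–100)."""
    if len(preds) != len(truths):
        raise ValueError(f"length mismatch: {len(preds)} preds vs {len(truths)} truths")
    if not truths:
        raise ValueError("need at least one labeled trial")
    correct = sum(p == t for p, t in zip(preds, truths))
    return 100.0 * correct / len(truths)


@dataclass(frozen=True)
class McNemarResult:
    b: int
    c: int
    statistic: float | None
    p_value: float | None
    significant: bool | None  # None: not applicable (b + c = 0)
    corrected: bool = True

    def to_dict(self) -> dict:
        return {
            "b": self.b,
            "c": self.c,
            "chi2": self.statistic,
            "p_value": self.p_value,
            "significant_at_0.05": self.significant,
            "continuity_corrected": self.corrected,
        }


def paired_chi2(b: int, c: int, corrected: bool = True) -> McNemarResult:
    """McNemar's paired chi-square from the discordant-pair counts.

    ``corrected=False`` gives the uncorrected variant
    ``(b - c)^2 / (b + c)``.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n_disc = b + c
    if n_disc == 0:
        return McNemarResult(b, c, None, None, None, corrected)
    if corrected:
        stat = (abs(b - c) - 1) ** 2 / n_disc
    else:
        stat = (b - c) ** 2 / n_disc
    p = float(stats.chi2.sf(stat, df=1))
    return McNemarResult(b, c, float(stat), p, bool(stat > CHI2_CRITICAL_005), corrected)


def confusion_matrix(
    preds: Sequence[EventLabel], truths: Sequence[EventLabel]
) -> np.ndarray:
    """4x4 counts, rows = truth, columns = prediction, order A, B, C, D."""
    if len(preds) != len(truths):
        raise ValueError(f"length mismatch: {len(preds)} preds vs {len(truths)} truths")
    idx = {lab: i for i, lab in enumerate(LABEL_ORDER)}
    mat = np.zeros((4, 4), dtype=int)
    for p, t in zip(preds, truths):
        mat[idx[t], idx[p]] += 1
    return mat


@dataclass(frozen=True)
class ComparisonReport:
    """Side-by-side scoring of the fused and direct classifiers."""

    n: int
    accuracy_fused: float
    accuracy_direct: float
    mcnemar: McNemarResult
    confusion_fused: np.ndarray = field(repr=False)
    confusion_direct: np.ndarray = field(repr=False)

    @property
    def advantage(self) -> float:
        """Fused minus direct accuracy, percentage points."""
        return self.accuracy_fused - self.accuracy_direct

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy_fused_pct": self.accuracy_fused,
            "accuracy_direct_pct": self.accuracy_direct,
            "advantage_pct_points": self.advantage,
            "mcnemar": self.mcnemar.to_dict(),
            "labels": [lab.value for lab in LABEL_ORDER],
            "confusion_fused": self.confusion_fused.tolist(),
            "confusion_direct": self.confusion_direct.tolist(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def compare_predictions(
    fused: Sequence[EventLabel],
    direct: Sequence[EventLabel],
    truths: Sequence[EventLabel],
    corrected: bool = True,
) -> ComparisonReport:
    """Score two paired prediction sequences against the same truths."""
    if not (len(fused) == len(direct) == len(truths)):
        raise ValueError("fused, direct and truth sequences must align")
    b = sum(f != t and d == t for f, d, t in zip(fused, direct, truths))
    c = sum(f == t and d != t for f, d, t in zip(fused, direct, truths))
    report = ComparisonReport(
        n=len(truths),
        accuracy_fused=accuracy(fused, truths),
        accuracy_direct=accuracy(direct, truths),
        mcnemar=paired_chi2(b, c, corrected=corrected),
        confusion_fused=confusion_matrix(fused, truths),
        confusion_direct=confusion_matrix(direct, truths),
    )
    assert math.isclose(
        report.accuracy_fused,
        100.0 * np.trace(report.confusion_fused) / report.n,
    )
    return report
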