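"""Mass-function algebra: Dempster combination, conflict, decisions."""

import math

import pytest
from hypothesis import given, strategies as st

from excare.evidence import (
    FOCAL_SETS,
    EventLabel,
    MassFunction,
    TotalConflictError,
    combine,
    conflict_coefficient,
    decide,
    fuse_many,
)

# --- independent oracle: generic Dempster's rule on the subset lattice ---


def dempster_bruteforce(m1: MassFunction, m2: MassFunction) -> MassFunction:
    """Textbook orthogonal sum over subsets of the atom frame {u, s, n}."""
    acc: dict[frozenset, float] = {}
    conflict = 0.0
    for lab1, s1 in FOCAL_SETS.items():
        for lab2, s2 in FOCAL_SETS.items():
            p = m1[lab1] * m2[lab2]
            inter = s1 & s2
            if inter:
                acc[inter] = acc.get(inter, 0.0) + p
            else:
                conflict += p
    k = 1.0 - conflict
    if k <= 0:
        raise TotalConflictError("oracle: total conflict")
    get = lambda lab: acc.get(FOCAL_SETS[lab], 0.0) / k
    return MassFunction(
        get(EventLabel.URINE), get(EventLabel.STOOL),
        get(EventLabel.BOTH), get(EventLabel.NONE),
    )


def masses(min_mass=0.0):
    base = st.tuples(*[st.floats(min_mass, 1.0)] * 4).filter(
        lambda t: sum(t) > 1e-6
    )
    return base.map(lambda t: MassFunction(*(x / sum(t) for x in t)))


def approx_equal(m1: MassFunction, m2: MassFunction, tol=1e-9) -> bool:
    return all(abs(a - b) <= tol for a, b in zip(m1.as_tuple(), m2.as_tuple()))


# --- conflict coefficient -------------------------------------------------


@pytest.mark.parametrize(
    "m1, m2, expected",
    [
        ((0.25, 0.25, 0.25, 0.25), (0.25, 0.25, 0.25, 0.25), 0.5),
        ((0.2, 0.3, 0.4, 0.1), (0.0, 0.0, 1.0, 0.0), 0.9),
        ((1.0, 0.0, 0.0, 0.0), (0.5, 0.2, 0.2, 0.1), 0.7),
    ],
)
def test_conflict_coefficient_values(m1, m2, expected):
    k = conflict_coefficient(MassFunction(*m1), MassFunction(*m2))
    assert k == pytest.approx(expected, abs=1e-12)


def test_total_conflict_raises():
    certain_urine = MassFunction(1, 0, 0, 0)
    certain_stool = MassFunction(0, 1, 0, 0)
    with pytest.raises(TotalConflictError):
        conflict_coefficient(certain_urine, certain_stool)
    with pytest.raises(TotalConflictError):
        combine(certain_urine, certain_stool)
    # epsilon flooring is the documented escape hatch
    fused = combine(certain_urine.floored(), certain_stool.floored())
    assert math.isclose(sum(fused.as_tuple()), 1.0, abs_tol=1e-9)


# --- combination ----------------------------------------------------------


@pytest.mark.parametrize(
    "m1, m2, expected",
    [
        ((1, 0, 0, 0), (0.5, 0.2, 0.2, 0.1), (1, 0, 0, 0)),
        ((0.25, 0.25, 0.25, 0.25), (0.25, 0.25, 0.25, 0.25),
         (0.375, 0.375, 0.125, 0.125)),
        ((0.2, 0.3, 0.4, 0.1), (0, 0, 1, 0), (2 / 9, 3 / 9, 4 / 9, 0)),
    ],
)
def test_combine_worked_examples(m1, m2, expected):
    fused = combine(MassFunction(*m1), MassFunction(*m2))
    assert fused.as_tuple() == pytest.approx(expected, abs=1e-12)


@given(masses(0.01), masses(0.01))
def test_combine_valid_and_commutative(m1, m2):
    f12 = combine(m1, m2)
    f21 = combine(m2, m1)
    assert all(m >= 0 for m in f12.as_tuple())
    assert math.isclose(sum(f12.as_tuple()), 1.0, abs_tol=1e-9)
    assert approx_equal(f12, f21, tol=1e-12)


@given(masses(0.01), masses(0.01), masses(0.01))
def test_combine_associative(m1, m2, m3):
    left = combine(combine(m1, m2), m3)
    right = combine(m1, combine(m2, m3))
    assert approx_equal(left, right, tol=1e-9)


@given(masses(0.01), masses(0.01))
def test_combine_matches_bruteforce_oracle(m1, m2):
    assert approx_equal(combine(m1, m2), dempster_bruteforce(m1, m2), tol=1e-9)


@given(masses(0.01))
def test_certain_singleton_is_absorbing(m):
    certain = MassFunction(1, 0, 0, 0)
    fused = combine(certain, m)
    assert fused.m_a == pytest.approx(1.0, abs=1e-12)


# --- n-ary fusion ---------------------------------------------------------


def test_fuse_many_single_and_fold():
    m = MassFunction(0.25, 0.25, 0.25, 0.25)
    assert fuse_many([m]) is m
    assert approx_equal(fuse_many([m, m, m]), combine(combine(m, m), m))
    with pytest.raises(ValueError):
        fuse_many([])


@given(st.lists(masses(0.01), min_size=2, max_size=5), st.randoms(use_true_random=False))
def test_fuse_many_association_order_invariant(ms, rnd):
    shuffled = list(ms)
    rnd.shuffle(shuffled)
    assert approx_equal(fuse_many(ms), fuse_many(shuffled), tol=1e-9)


# --- decision -------------------------------------------------------------


@pytest.mark.parametrize(
    "m, expected",
    [
        ((0.1, 0.2, 0.6, 0.1), EventLabel.BOTH),
        ((0.4, 0.4, 0.1, 0.1), EventLabel.STOOL),  # tie broken C > B > A > D
        ((0.0, 0.0, 0.0, 1.0), EventLabel.NONE),
        ((0.25, 0.25, 0.25, 0.25), EventLabel.BOTH),
    ],
)
def test_decide(m, expected):
    assert decide(MassFunction(*m)) is expected


def test_repeated_fusion_can_flip_the_decision():
    """Self-combination polarizes toward singletons: a composite-heavy
    assignment loses its lead, so repeated fusion cycles are *not*
    decision-preserving in general."""
    m = MassFunction(0.3, 0.2, 0.4, 0.1)
    assert decide(m) is EventLabel.BOTH
    assert decide(combine(m, m)) is EventLabel.URINE


# --- validation / serialization ------------------------------------------


def test_mass_validation():
    with pytest.raises(ValueError):
        MassFunction(0.5, 0.5, 0.5, 0.5)
    with pytest.raises(ValueError):
        MassFunction(-0.1, 0.6, 0.3, 0.2)
    with pytest.raises(ValueError):
        MassFunction(float("nan"), 0, 0, 1)


def test_dict_roundtrip_and_floor():
    m = MassFunction(0.7, 0.2, 0.1, 0.0)
    assert MassFunction.from_dict(m.to_dict()) == m
    fl = m.floored(1e-4)
    assert min(fl.as_tuple()) > 0
    assert math.isclose(sum(fl.as_tuple()), 1.0, abs_tol=1e-9)


def test_event_label_roundtrip():
    for lab in EventLabel:
        assert EventLabel(lab.value) is lab
    assert len(EventLabel) == 4
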