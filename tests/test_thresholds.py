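"""Interval detection basis: deltas, memberships, BPAs, direct classifier."""

import numpy as np
import pytest

from excare.evidence import EventLabel
from excare.pipeline import detect_event
from excare.thresholds import (
    CHANNELS,
    ChannelDeltas,
    ConfigurationError,
    DetectionBasis,
    build_bpa,
    channel_membership,
    compute_deltas,
    direct_classify,
)

from conftest import make_session


# --- deltas ---------------------------------------------------------------


def test_compute_deltas_subtraction(basis):
    b = DetectionBasis(
        intervals=basis.intervals,
        baseline_temperature=15.1,
        baseline_humidity=22.9,
        ambient_ammonia=0.0,
        softness=basis.softness,
    )
    d = compute_deltas((16.1, 27.9, 1.0), b)
    assert (d.x, d.y, d.z) == pytest.approx((1.0, 5.0, 1.0))
    assert compute_deltas((15.1, 22.9, 0.0), b) == ChannelDeltas(0, 0, 0)


def test_ammonia_delta_floored_at_zero(basis):
    b = DetectionBasis(
        intervals=basis.intervals,
        baseline_temperature=22.0,
        baseline_humidity=40.0,
        ambient_ammonia=0.5,
        softness=basis.softness,
    )
    assert compute_deltas((22.0, 40.0, 0.2), b).z == 0.0


def test_missing_baseline_is_configuration_error(basis):
    with pytest.raises(ConfigurationError):
        DetectionBasis(
            intervals=basis.intervals,
            baseline_temperature=float("nan"),
            baseline_humidity=40.0,
            ambient_ammonia=0.0,
        )
    with pytest.raises(ConfigurationError):
        DetectionBasis.from_mapping({"channels": {}})


# --- membership -----------------------------------------------------------


def test_membership_temperature_example(basis):
    mu = channel_membership(1.2, "temperature", basis)
    assert mu[EventLabel.STOOL] == pytest.approx(1.0)
    assert mu[EventLabel.BOTH] == pytest.approx(1 - 0.2 / 0.3)
    assert mu[EventLabel.URINE] == 0.0
    assert mu[EventLabel.NONE] == 0.0


def test_membership_humidity_urine(basis):
    mu = channel_membership(25.0, "humidity", basis)
    assert mu[EventLabel.URINE] == pytest.approx(1.0)
    assert mu[EventLabel.STOOL] == mu[EventLabel.BOTH] == mu[EventLabel.NONE] == 0.0


@pytest.mark.parametrize("channel", CHANNELS)
def test_membership_zero_delta_is_pure_none(basis, channel):
    mu = channel_membership(0.0, channel, basis)
    assert mu[EventLabel.NONE] == pytest.approx(1.0)
    assert all(mu[lab] == 0.0 for lab in EventLabel if lab is not EventLabel.NONE)


@pytest.mark.parametrize("channel", CHANNELS)
def test_membership_is_continuous(basis, channel):
    """No jumps beyond the steepest ramp slope in a fine grid scan."""
    step = 0.005
    grid = np.arange(-2.0, 30.0, step)
    ramp = basis.softness[channel]
    steepest = max(1.0 / ramp, 1.0 / basis.none_halfwidth(channel))
    for lab in EventLabel:
        vals = np.array(
            [channel_membership(float(d), channel, basis)[lab] for d in grid]
        )
        assert np.max(np.abs(np.diff(vals))) <= steepest * step * 1.001


# --- BPA construction -----------------------------------------------------


def test_bpa_certain_urine_from_humidity(basis):
    assert build_bpa(25.0, "humidity", basis).as_tuple() == (1, 0, 0, 0)


def test_bpa_zero_delta_is_none(basis):
    assert build_bpa(0.0, "temperature", basis).as_tuple() == (0, 0, 0, 1)


def test_bpa_shared_ammonia_band(basis):
    """The 1-2 ppm band cannot tell stool from stool-and-urine: under the
    union scheme the shared support lands on the union focal set C, under
    the proportional scheme it splits evenly."""
    assert build_bpa(1.5, "ammonia", basis).as_tuple() == (0, 0, 1, 0)
    prop = build_bpa(1.5, "ammonia", basis, scheme="proportional")
    assert prop.as_tuple() == pytest.approx((0, 0.5, 0.5, 0))


def test_bpa_unknown_scheme(basis):
    with pytest.raises(ValueError):
        build_bpa(1.0, "ammonia", basis, scheme="bogus")
    with pytest.raises(ValueError):
        channel_membership(1.0, "pressure", basis)


# --- direct classifier ----------------------------------------------------


@pytest.mark.parametrize(
    "deltas, expected",
    [
        ((1.0, 8.0, 1.5), EventLabel.STOOL),
        ((2.5, 25.0, 3.0), EventLabel.URINE),
        ((0.0, 0.0, 0.0), EventLabel.NONE),
        # shared boundaries belong to the upper class: exactly 2 ppm is urine
        ((2.0, 25.0, 2.0), EventLabel.URINE),
        ((1.0, 8.0, 1.99), EventLabel.STOOL),
    ],
)
def test_direct_classify(basis, deltas, expected):
    assert direct_classify(ChannelDeltas(*deltas), basis) is expected


# --- interior recovery (both soft and crisp paths) ------------------------

INTERIOR = {
    EventLabel.URINE: (2.5, 26.0, 4.0),
    EventLabel.STOOL: (1.5, 8.5, 1.5),
    EventLabel.BOTH: (0.4, 16.0, 1.5),
    EventLabel.NONE: (0.0, 0.0, 0.0),
}


@pytest.mark.parametrize("label", list(INTERIOR))
def test_interior_deltas_recovered_by_both_classifiers(basis, label):
    deltas = INTERIOR[label]
    assert direct_classify(ChannelDeltas(*deltas), basis) is label
    session = make_session(basis, [deltas] * 3, session_id=f"interior-{label.value}")
    assert detect_event(session, basis).decided is label


# --- serialization --------------------------------------------------------


def test_basis_yaml_roundtrip(basis, tmp_path):
    path = tmp_path / "basis.yaml"
    basis.to_yaml(path)
    loaded = DetectionBasis.from_yaml(path)
    assert loaded.intervals == basis.intervals
    assert loaded.baseline_temperature == basis.baseline_temperature
    assert loaded.softness == basis.softness


def test_default_basis_matches_printed_table(basis):
    assert basis.intervals["temperature"][EventLabel.STOOL] == (0.5, 2.0)
    assert basis.intervals["temperature"][EventLabel.URINE] == (1.8, float("inf"))
    assert basis.intervals["temperature"][EventLabel.BOTH] == (0.0, 1.0)
    assert basis.intervals["humidity"][EventLabel.STOOL] == (5.0, 12.0)
    assert basis.intervals["humidity"][EventLabel.URINE] == (20.0, float("inf"))
    assert basis.intervals["humidity"][EventLabel.BOTH] == (12.0, 20.0)
    assert basis.intervals["ammonia"][EventLabel.STOOL] == (1.0, 2.0)
    assert basis.intervals["ammonia"][EventLabel.URINE] == (2.0, float("inf"))
    assert basis.intervals["ammonia"][EventLabel.BOTH] == (1.0, 2.0)
    # NONE triangles: half-width is the smallest positive lower bound
    assert basis.none_halfwidth("temperature") == 0.5
    assert basis.none_halfwidth("humidity") == 5.0
    assert basis.none_halfwidth("ammonia") == 1.0


def test_empty_interval_rejected(basis):
    bad = {ch: dict(ev) for ch, ev in basis.intervals.items()}
    bad["humidity"][EventLabel.STOOL] = (12.0, 5.0)
    with pytest.raises(ConfigurationError):
        DetectionBasis(
            intervals=bad,
            baseline_temperature=22.0,
            baseline_humidity=40.0,
            ambient_ammonia=0.0,
        )
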