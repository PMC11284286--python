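"""Plan geometry: frozen reference values, jaw rule properties, error injection."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from bpfqa import (
    BPFConfig,
    ErrorSpec,
    MachineModel,
    PlanGeometryError,
    Segment,
    build_bpf_plan,
    build_static_jaw_plan,
    expected_positions,
    inject_errors,
    jaw_positions,
    picket_centers,
)

# Frozen reference values of the standard 8-segment jaw-tracking pattern
# (2-mm aperture, 20-mm slit steps from +/-70 mm, 5-mm retraction).
PLANNED_X1 = [-74.0, -54.0, -34.0, -14.0, -16.0, -36.0, -56.0, -76.0]
PLANNED_X2 = [76.0, 56.0, 36.0, 16.0, 14.0, 34.0, 54.0, 74.0]

# A published validation pattern: per-segment (dx1, dx2) offsets of
# +/-0.5 / +/-1.0 mm and the jaw positions they must produce.
VALIDATION_OFFSETS = {
    1: (1.0, -1.0),
    2: (0.5, 0.5),
    3: (-0.5, 1.0),
    4: (-1.0, -0.5),
    5: (1.0, 1.0),
    6: (0.5, -0.5),
    7: (-1.0, -1.0),
    8: (-0.5, 0.5),
}
VALIDATION_X1 = [-73.0, -53.5, -34.5, -15.0, -15.0, -35.5, -57.0, -76.5]
VALIDATION_X2 = [75.0, 56.5, 37.0, 15.5, 15.0, 33.5, 53.0, 74.5]


def test_default_plan_jaw_positions(plan):
    table = expected_positions(plan)
    assert list(table["segment"]) == list(range(1, 9))
    np.testing.assert_allclose(table["x1"], PLANNED_X1, atol=1e-12)
    np.testing.assert_allclose(table["x2"], PLANNED_X2, atol=1e-12)


def test_default_plan_slit_centers(plan):
    table = expected_positions(plan)
    np.testing.assert_allclose(
        table["upper_center"], [70, 50, 30, 10, -10, -30, -50, -70], atol=1e-12
    )
    np.testing.assert_allclose(
        table["lower_center"], [-70, -50, -30, -10, 10, 30, 50, 70], atol=1e-12
    )


def test_picket_centers(plan):
    np.testing.assert_allclose(
        picket_centers(plan), [-70, -50, -30, -10, 10, 30, 50, 70], atol=1e-12
    )


def test_jaw_rule_matches_plan(config):
    for c_up, c_low, x1, x2 in zip(
        config.upper_centers, config.lower_centers, PLANNED_X1, PLANNED_X2
    ):
        got = jaw_positions(c_up, c_low, config.aperture_width, config.retraction)
        assert got == (x1, x2)


def test_validation_offsets_reproduce_reference(plan):
    err = inject_errors(plan, ErrorSpec(jaw_offsets=VALIDATION_OFFSETS))
    assert err.plan_kind == "error_added"
    table = expected_positions(err)
    np.testing.assert_allclose(table["x1"], VALIDATION_X1, atol=1e-12)
    np.testing.assert_allclose(table["x2"], VALIDATION_X2, atol=1e-12)


def test_jaw_retraction_gap(plan, config):
    """Each jaw clears every open leaf tip by at least retraction - width."""
    min_gap = config.retraction - config.aperture_width
    for seg in plan.segments:
        assert float(seg.bank_a.min()) - seg.x1 >= min_gap - 1e-12
        assert seg.x2 - float(seg.bank_b.max()) >= min_gap - 1e-12


def test_segment_mu_fractions(plan, config):
    fractions = [seg.mu_fraction for seg in plan.segments]
    assert all(f == pytest.approx(1.0 / 8.0) for f in fractions)
    assert sum(fractions) == pytest.approx(1.0)
    assert config.total_mu == 120.0 and config.dose_rate == 600.0


@given(
    c_up=st.floats(-80, 80),
    c_low=st.floats(-80, 80),
    w=st.floats(0.5, 10),
    r=st.floats(0, 10),
)
def test_jaw_rule_antisymmetry(c_up, c_low, w, r):
    """Mirroring both slit centers swaps and negates the jaw positions:
    x1(-c_up, -c_low) == -x2(c_up, c_low) (and symmetrically for x2)."""
    try:
        x1, x2 = jaw_positions(c_up, c_low, w, r)
        x1m, x2m = jaw_positions(-c_up, -c_low, w, r)
    except PlanGeometryError:
        assume(False)
    assert x1m == pytest.approx(-x2, abs=1e-9)
    assert x2m == pytest.approx(-x1, abs=1e-9)


@given(
    c_up=st.floats(-80, 80),
    c_low=st.floats(-80, 80),
    w=st.floats(0.5, 10),
    r=st.floats(0, 10),
)
def test_jaw_rule_covers_both_slits(c_up, c_low, w, r):
    """With retraction >= aperture width (as in the standard pattern),
    neither jaw ever shadows either slit."""
    assume(r >= w)
    try:
        x1, x2 = jaw_positions(c_up, c_low, w, r)
    except PlanGeometryError:
        assume(False)
    for c in (c_up, c_low):
        assert x1 <= c - w / 2 + 1e-9
        assert x2 >= c + w / 2 - 1e-9


def test_inject_and_negate_round_trip(plan):
    spec = ErrorSpec(jaw_offsets={2: (0.7, -0.3)}, leaf_offsets={45: 1.0, 12: -0.5})
    restored = inject_errors(inject_errors(plan, spec), spec.negated())
    for seg, orig in zip(restored.segments, plan.segments):
        assert seg.x1 == pytest.approx(orig.x1, abs=1e-9)
        assert seg.x2 == pytest.approx(orig.x2, abs=1e-9)
        np.testing.assert_allclose(seg.bank_a, orig.bank_a, atol=1e-9)
        np.testing.assert_allclose(seg.bank_b, orig.bank_b, atol=1e-9)


def test_inject_errors_does_not_mutate_input(plan):
    before = plan.segments[0].bank_a.copy()
    inject_errors(plan, ErrorSpec(leaf_offsets={40: 2.0}))
    np.testing.assert_array_equal(plan.segments[0].bank_a, before)


def test_inject_errors_rejects_unknown_leaf(plan):
    with pytest.raises(ValueError, match="leaf id"):
        inject_errors(plan, ErrorSpec(leaf_offsets={61: 1.0}))


def test_inject_errors_rejects_crossing_jaws(plan):
    with pytest.raises(PlanGeometryError):
        inject_errors(plan, ErrorSpec(jaw_offsets={4: (20.0, -20.0)}))


def test_static_jaw_plan(machine, config):
    plan = build_static_jaw_plan(machine, config, -90.0, 90.0)
    assert plan.plan_kind == "static_jaw"
    assert all(seg.x1 == -90.0 and seg.x2 == 90.0 for seg in plan.segments)


def test_static_jaw_plan_rejects_blocking_jaws(machine, config):
    # slits reach +/-71 mm, so jaws at +/-60 would shadow them
    with pytest.raises(PlanGeometryError, match="block"):
        build_static_jaw_plan(machine, config, -60.0, 60.0)


def test_segment_rejects_crossed_leaves():
    with pytest.raises(PlanGeometryError, match="cross"):
        Segment(
            index=1,
            upper_center=0.0,
            lower_center=0.0,
            x1=-10.0,
            x2=10.0,
            bank_a=np.array([1.0, -1.0]),
            bank_b=np.array([-1.0, 1.0]),
            mu_fraction=0.5,
        )


def test_segment_rejects_crossed_jaws():
    with pytest.raises(PlanGeometryError, match="jaws cross"):
        Segment(
            index=1,
            upper_center=0.0,
            lower_center=0.0,
            x1=10.0,
            x2=-10.0,
            bank_a=np.array([-1.0]),
            bank_b=np.array([1.0]),
            mu_fraction=0.5,
        )


def test_rotation_mode_gantry_angles(machine):
    cfg = BPFConfig(gantry_mode="rotation")
    plan = build_bpf_plan(machine, cfg)
    np.testing.assert_allclose(
        [seg.gantry_deg for seg in plan.segments], np.arange(8) * 45.0
    )


def test_config_rejects_mismatched_center_lists():
    with pytest.raises(ValueError):
        BPFConfig(upper_centers=(10.0, -10.0), lower_centers=(0.0,))


def test_leaf_error_shifts_expected_center(plan, machine):
    err = inject_errors(plan, ErrorSpec(leaf_offsets={45: 3.0}))
    n_upper = sum(
        machine.is_upper_leaf(i + 1) for i in range(machine.n_leaf_pairs)
    )
    base = expected_positions(plan)["upper_center"]
    shifted = expected_positions(err)["upper_center"]
    np.testing.assert_allclose(shifted - base, 3.0 / n_upper, atol=1e-12)
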