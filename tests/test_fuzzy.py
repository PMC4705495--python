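"""Membership functions, T-norm, and the six-rule obstruction inference."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from airwaydx.fuzzy import (
    MembershipVector,
    PATTERN_LABELS,
    SEVERITY_ORDER,
    evaluate_rules,
    export_membership_grid,
    fuzzify,
    mu_high_reactance,
    mu_high_resistance,
    mu_min_delta_r,
    mu_none_delta_r,
    mu_normal_reactance,
    mu_normal_resistance,
    mu_sig_delta_r,
    rule_activations,
    tnorm,
)
from conftest import make_ios

APPROX = pytest.approx


@pytest.mark.parametrize(
    "fn,x,expected",
    [
        # resistance (% predicted): shoulder pair over [150, 155]
        (mu_normal_resistance, 100.0, 1.0),
        (mu_normal_resistance, 160.0, 0.0),
        (mu_normal_resistance, 152.5, 0.5),
        (mu_high_resistance, 150.0, 0.0),
        (mu_high_resistance, 155.0, 1.0),
        (mu_high_resistance, 152.5, 0.5),
        # reactance deficit: shoulder pair over [0.15, 0.155]
        (mu_normal_reactance, 0.10, 1.0),
        (mu_normal_reactance, 0.20, 0.0),
        (mu_normal_reactance, 0.1525, 0.5),
        (mu_high_reactance, 0.10, 0.0),
        (mu_high_reactance, 0.16, 1.0),
        (mu_high_reactance, 0.1525, 0.5),
        # R5-R20 difference: none / minimum (triangle) / significant
        (mu_none_delta_r, -0.01, 1.0),
        (mu_none_delta_r, 0.1, 0.0),
        (mu_none_delta_r, 0.025, 0.5),
        (mu_min_delta_r, 0.04, 0.0),
        (mu_min_delta_r, 0.125, 1.0),
        (mu_min_delta_r, 0.0875, 0.5),
        (mu_min_delta_r, 0.25, 0.0),
        (mu_sig_delta_r, 0.2, 0.0),
        (mu_sig_delta_r, 0.4, 1.0),
        (mu_sig_delta_r, 0.275, 0.5),
    ],
)
def test_membership_values_at_breakpoints(fn, x, expected):
    assert fn(x) == APPROX(expected, abs=1e-12)


@pytest.mark.parametrize("fn", [mu_normal_resistance, mu_high_resistance])
def test_resistance_membership_rejects_bad_input(fn):
    with pytest.raises(ValueError):
        fn(-5.0)
    with pytest.raises(ValueError):
        fn(float("nan"))


def test_delta_r_membership_rejects_non_finite():
    with pytest.raises(ValueError):
        mu_min_delta_r(float("inf"))


@given(st.floats(min_value=1.0, max_value=400.0))
@settings(derandomize=True)
def test_resistance_pair_complementary(r):
    assert mu_normal_resistance(r) + mu_high_resistance(r) == APPROX(1.0)


@given(st.floats(min_value=-0.5, max_value=0.8))
@settings(derandomize=True)
def test_reactance_pair_complementary(d):
    assert mu_normal_reactance(d) + mu_high_reactance(d) == APPROX(1.0)


def test_memberships_bounded_and_monotone_on_grid():
    rs = np.linspace(1, 400, 2001)
    drs = np.linspace(-0.3, 0.8, 2001)
    hi_r = [mu_high_resistance(r) for r in rs]
    lo_r = [mu_normal_resistance(r) for r in rs]
    sig = [mu_sig_delta_r(d) for d in drs]
    none = [mu_none_delta_r(d) for d in drs]
    for seq in (hi_r, lo_r, sig, none, [mu_min_delta_r(d) for d in drs]):
        assert min(seq) >= 0.0 and max(seq) <= 1.0
    assert np.all(np.diff(hi_r) >= 0) and np.all(np.diff(sig) >= 0)
    assert np.all(np.diff(lo_r) <= 0) and np.all(np.diff(none) <= 0)


def test_memberships_piecewise_linear_continuous():
    # no jump exceeding the local slope times the grid step
    for fn, lo, hi, max_slope in [
        (mu_normal_resistance, 100, 200, 1 / 5),
        (mu_min_delta_r, -0.1, 0.4, 1 / 0.075),
        (mu_sig_delta_r, -0.1, 0.6, 1 / 0.15),
        (mu_normal_reactance, 0.0, 0.3, 1 / 0.005),
    ]:
        xs = np.linspace(lo, hi, 20001)
        ys = np.array([fn(x) for x in xs])
        step = xs[1] - xs[0]
        assert np.max(np.abs(np.diff(ys))) <= max_slope * step * 1.001


def test_tnorm_properties():
    assert tnorm(1.0, 0.37) == 0.37
    assert tnorm(0.3, 0.7) == 0.3
    assert tnorm(0.0, 1.0) == 0.0
    assert tnorm(0.4, 0.6) == tnorm(0.6, 0.4)
    with pytest.raises(ValueError):
        tnorm(1.2, 0.5)


def test_fuzzify_crisp_normal_and_abnormal():
    normal = fuzzify(make_ios(r5_pct=100, r20_pct=100, r5=0.35, r20=0.35, x5=-0.10, x5_pred=0.0))
    assert normal.r5_normal == normal.r20_normal == normal.x5_normal == normal.dr_none == 1.0
    assert normal.r5_high == normal.r20_high == normal.x5_high == normal.dr_min == normal.dr_sig == 0.0
    abn = fuzzify(make_ios(r5_pct=160, r20_pct=160, r5=0.8, r20=0.4, x5=-0.25, x5_pred=-0.05))
    assert abn.r5_high == abn.r20_high == abn.x5_high == abn.dr_sig == 1.0
    assert abn.r5_normal == abn.dr_none == abn.dr_min == 0.0


def test_fuzzify_mid_breakpoint():
    mv = fuzzify(make_ios(r5_pct=152.5, r20_pct=100, r5=0.35, r20=0.35, x5=-0.10, x5_pred=0.0))
    assert mv.r5_normal == APPROX(0.5) and mv.r5_high == APPROX(0.5)


def _crisp_vector(r5_high, r20_high, x5_high, dr_state):
    return MembershipVector(
        r5_normal=1.0 - r5_high, r5_high=float(r5_high),
        r20_normal=1.0 - r20_high, r20_high=float(r20_high),
        x5_normal=1.0 - x5_high, x5_high=float(x5_high),
        dr_none=float(dr_state == "none"),
        dr_min=float(dr_state == "min"),
        dr_sig=float(dr_state == "sig"),
    )


def _crisp_rule_oracle(r5_high, r20_high, x5_high, dr_state):
    """Boolean-logic transcription of the six rules, independent of the engine."""
    matches = []
    if not r5_high and not r20_high and not x5_high:
        if dr_state == "none":
            matches.append("NSCO-SV")
        elif dr_state == "min":
            matches.append("NSCO-DV")
        else:
            matches.append("NSPO")
    if r5_high and r20_high:
        if dr_state == "none" and not x5_high:
            matches.append("CO-SV")
        matches.append("CO-DV")  # the X5 alternatives make the OR group true crisply
        if dr_state == "sig" and x5_high:
            matches.append("PO")
    return matches


def test_rule_engine_matches_crisp_boolean_oracle():
    """Brute-force enumeration of all crisp membership combinations."""
    for r5h, r20h, x5h in itertools.product([False, True], repeat=3):
        for dr in ("none", "min", "sig"):
            mv = _crisp_vector(r5h, r20h, x5h, dr)
            acts = rule_activations(mv)
            expected = _crisp_rule_oracle(r5h, r20h, x5h, dr)
            for lab in PATTERN_LABELS:
                assert acts[lab] == (1.0 if lab in expected else 0.0), (r5h, r20h, x5h, dr, lab)
            out = evaluate_rules(mv)
            if len(expected) == 1:
                assert out.label == expected[0] and out.activations[out.label] == 1.0
            elif expected:
                # severity-order tie-break among the matched rules
                assert out.label == min(expected, key=SEVERITY_ORDER.index)


def test_rule_engine_crisp_examples():
    assert evaluate_rules(_crisp_vector(False, False, False, "none")).label == "NSCO-SV"
    assert evaluate_rules(_crisp_vector(False, False, False, "min")).label == "NSCO-DV"
    assert evaluate_rules(_crisp_vector(True, True, True, "sig")).label == "PO"


def test_rule_engine_argmax_scale_invariant():
    rng = np.random.default_rng(5)
    for _ in range(50):
        vals = rng.uniform(0, 1, 3)
        mv = MembershipVector(
            r5_normal=1 - vals[0], r5_high=vals[0],
            r20_normal=1 - vals[1], r20_high=vals[1],
            x5_normal=1 - vals[2], x5_high=vals[2],
            dr_none=rng.uniform(0, 1), dr_min=rng.uniform(0, 1), dr_sig=rng.uniform(0, 1),
        )
        base = evaluate_rules(mv)
        for c in (0.5, 0.1):
            scaled = MembershipVector(
                **{k: getattr(mv, k) * c for k in (
                    "r5_normal", "r5_high", "r20_normal", "r20_high",
                    "x5_normal", "x5_high", "dr_none", "dr_min", "dr_sig")}
            )
            assert evaluate_rules(scaled).label == base.label


def test_membership_vector_rejects_out_of_range():
    with pytest.raises(ValueError):
        _crisp_vector(2.0, False, False, "none")


def test_membership_grid_export(tmp_path):
    out = tmp_path / "grid.csv"
    export_membership_grid(out, n=11)
    lines = out.read_text().strip().splitlines()
    assert len(lines) == 12 and lines[0].startswith("r_pct,")
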