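"""Fuzzy interpretation of impulse-oscillometry measurements.

Three measurements drive the rule base: R5 and R20 as percent of
predicted, the reactance deficit X5pred - X5 in kPa/(L/s), and the
resistance difference dR = R5 - R20 in kPa/(L/s).  Each is mapped by
piecewise-linear membership functions to linguistic degrees (normal /
upper-limit-of-normal for resistances and reactance; none / minimum /
significant for dR), and six Mamdani-style rules classify the
obstruction pattern:

====== ================================================
label  meaning
====== ================================================
NSCO-SV negative sub-central obstruction, same values
NSCO-DV negative sub-central obstruction, different values
NSPO    negative sub-peripheral obstruction
CO-SV   central obstruction, same values
CO-DV   central obstruction, different values
PO      peripheral obstruction
====== ================================================

AND is the minimum T-norm, OR the maximum; the output label is the
argmax of rule activations with ties broken toward the clinically more
severe pattern.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, fields

import numpy as np

from .reports import IOSResult

PATTERN_LABELS = ("NSCO-SV", "NSCO-DV", "NSPO", "CO-SV", "CO-DV", "PO")

#: tie-break priority, most severe first
SEVERITY_ORDER = ("PO", "CO-DV", "CO-SV", "NSPO", "NSCO-DV", "NSCO-SV")


@dataclass(frozen=True)
class FuzzyBreakpoints:
    """Breakpoints of the membership functions (defaults per GINA/GOLD-derived
    IOS interpretation: resistances in %predicted, reactance deficit and dR
    in kPa/(L/s))."""

    r_normal_hi: float = 150.0
    r_high_lo: float = 150.0
    r_high_hi: float = 155.0
    x_normal_hi: float = 0.15
    x_high_hi: float = 0.155
    dr_none_hi: float = 0.05
    dr_min_peak: float = 0.125
    dr_min_hi: float = 0.2
    dr_sig_hi: float = 0.35

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyBreakpoints":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown fuzzy breakpoint(s): {sorted(unknown)}")
        return cls(**d)


DEFAULT_BREAKPOINTS = FuzzyBreakpoints()


def _check_degree_input(x: float, name: str, positive: bool = False) -> None:
    if not math.isfinite(x):
        raise ValueError(f"{name} must be finite, got {x!r}")
    if positive and x <= 0:
        raise ValueError(f"{name} must be positive, got {x!r}")


def _falling(x: float, lo: float, hi: float) -> float:
    """Descending shoulder: 1 below lo, 0 above hi, linear between."""
    if x <= lo:
        return 1.0
    if x >= hi:
        return 0.0
    return (hi - x) / (hi - lo)


def mu_normal_resistance(r_pct: float, bp: FuzzyBreakpoints = DEFAULT_BREAKPOINTS) -> float:
    """Degree to which a resistance (%predicted) is within reference range."""
    _check_degree_input(r_pct, "r_pct", positive=True)
    return _falling(r_pct, bp.r_high_lo, bp.r_high_hi)


def mu_high_resistance(r_pct: float, bp: FuzzyBreakpoints = DEFAULT_BREAKPOINTS) -> float:
    """Degree to which a resistance (%predicted) is above the upper limit of normal."""
    _check_degree_input(r_pct, "r_pct", positive=True)
    return 1.0 - _falling(r_pct, bp.r_high_lo, bp.r_high_hi)


def mu_normal_reactance(d: float, bp: FuzzyBreakpoints = DEFAULT_BREAKPOINTS) -> float:
    """Degree to which the reactance deficit X5pred - X5 is within reference range."""
    _check_degree_input(d, "reactance deficit")
    return _falling(d, bp.x_normal_hi, bp.x_high_hi)


def mu_high_reactance(d: float, bp: FuzzyBreakpoints = DEFAULT_BREAKPOINTS) -> float:
    """Degree to which the reactance deficit is above the upper limit of normal."""
    _check_degree_input(d, "reactance deficit")
    return 1.0 - _falling(d, bp.x_normal_hi, bp.x_high_hi)


def mu_none_delta_r(dr: float, bp: FuzzyBreakpoints = DEFAULT_BREAKPOINTS) -> float:
    """Degree of *no* difference between R5 and R20."""
    _check_degree_input(dr, "delta_r")
    return _falling(dr, 0.0, bp.dr_none_hi)


def mu_min_delta_r(dr: float, bp: FuzzyBreakpoints = DEFAULT_BREAKPOINTS) -> float:
    """Degree of a *minimum* R5-R20 difference: triangle on
    (dr_none_hi, dr_min_peak, dr_min_hi)."""
    _check_degree_input(dr, "delta_r")
    if dr <= bp.dr_none_hi or dr >= bp.dr_min_hi:
        return 0.0
    if dr <= bp.dr_min_peak:
        return (dr - bp.dr_none_hi) / (bp.dr_min_peak - bp.dr_none_hi)
    return (bp.dr_min_hi - dr) / (bp.dr_min_hi - bp.dr_min_peak)


def mu_sig_delta_r(dr: float, bp: FuzzyBreakpoints = DEFAULT_BREAKPOINTS) -> float:
    """Degree of a *significant* R5-R20 difference."""
    _check_degree_input(dr, "delta_r")
    return 1.0 - _falling(dr, bp.dr_min_hi, bp.dr_sig_hi)


@dataclass(frozen=True)
class MembershipVector:
    """Fuzzy degrees of all linguistic terms for one IOS measurement set.

    The normal/high pairs are complementary (sum to 1) by construction.
    """

    r5_normal: float
    r5_high: float
    r20_normal: float
    r20_high: float
    x5_normal: float
    x5_high: float
    dr_none: float
    dr_min: float
    dr_sig: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{f.name} must lie in [0, 1], got {v!r}")


@dataclass(frozen=True)
class ObstructionPattern:
    """Rule-base output: winning pattern label plus all six rule activations."""

    label: str
    activations: dict

    def __post_init__(self) -> None:
        if self.label not in PATTERN_LABELS:
            raise ValueError(f"unknown pattern label {self.label!r}")


def fuzzify(ios: IOSResult, bp: FuzzyBreakpoints = DEFAULT_BREAKPOINTS) -> MembershipVector:
    """Map one IOS measurement set to its membership degrees."""
    d = ios.reactance_deficit
    dr = ios.delta_r
    return MembershipVector(
        r5_normal=mu_normal_resistance(ios.r5_pct_pred, bp),
        r5_high=mu_high_resistance(ios.r5_pct_pred, bp),
        r20_normal=mu_normal_resistance(ios.r20_pct_pred, bp),
        r20_high=mu_high_resistance(ios.r20_pct_pred, bp),
        x5_normal=mu_normal_reactance(d, bp),
        x5_high=mu_high_reactance(d, bp),
        dr_none=mu_none_delta_r(dr, bp),
        dr_min=mu_min_delta_r(dr, bp),
        dr_sig=mu_sig_delta_r(dr, bp),
    )


def tnorm(a: float, b: float) -> float:
    """Minimum T-norm (fuzzy AND)."""
    for name, v in (("a", a), ("b", b)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
    return min(a, b)


def _and(*degrees: float) -> float:
    out = 1.0
    for d in degrees:
        out = tnorm(out, d)
    return out


def rule_activations(mv: MembershipVector) -> dict:
    """Activation of each of the six rules for one membership vector.

    Rule 5 (CO-DV) ANDs the central-resistance terms with an OR group over
    (dR minimum, X5 normal, X5 high); the X5 alternatives make the group
    saturate for crisp inputs, so crisply the rule reads "central
    obstruction with a minimal-or-any dR/X5 combination".
    """
    return {
        "NSCO-SV": _and(mv.r5_normal, mv.r20_normal, mv.dr_none, mv.x5_normal),
        "NSCO-DV": _and(mv.r5_normal, mv.r20_normal, mv.dr_min, mv.x5_normal),
        "NSPO": _and(mv.r5_normal, mv.r20_normal, mv.dr_sig, mv.x5_normal),
        "CO-SV": _and(mv.r5_high, mv.r20_high, mv.dr_none, mv.x5_normal),
        "CO-DV": _and(mv.r5_high, mv.r20_high, max(mv.dr_min, mv.x5_normal, mv.x5_high)),
        "PO": _and(mv.r5_high, mv.r20_high, mv.dr_sig, mv.x5_high),
    }


def evaluate_rules(mv: MembershipVector) -> ObstructionPattern:
    """Run the six-rule base; argmax label with severity-order tie-break."""
    acts = rule_activations(mv)
    best = max(SEVERITY_ORDER, key=lambda lab: (acts[lab], -SEVERITY_ORDER.index(lab)))
    return ObstructionPattern(label=best, activations=acts)


def export_membership_grid(path, bp: FuzzyBreakpoints = DEFAULT_BREAKPOINTS, n: int = 501) -> None:
    """Write a CSV grid of all membership curves, for plotting."""
    r = np.linspace(50.0, 250.0, n)
    x = np.linspace(0.0, 0.3, n)
    dr = np.linspace(-0.1, 0.5, n)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["r_pct", "mu_normal_r", "mu_high_r",
             "deficit", "mu_normal_x5", "mu_high_x5",
             "delta_r", "mu_none_dr", "mu_min_dr", "mu_sig_dr"]
        )
        for i in range(n):
            w.writerow(
                [r[i], mu_normal_resistance(r[i], bp), mu_high_resistance(r[i], bp),
                 x[i], mu_normal_reactance(x[i], bp), mu_high_reactance(x[i], bp),
                 dr[i], mu_none_delta_r(dr[i], bp), mu_min_delta_r(dr[i], bp),
                 mu_sig_delta_r(dr[i], bp)]
            )
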