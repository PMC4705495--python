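"""Crisp GINA/GOLD diagnostic criteria and challenge-test positivity rules.

Static criteria combine symptom gates with IOS and spirometry thresholds
(all comparisons strict).  The bronchodilatation test (BDT, salbutamol
400 ug) is positive when R5 falls by more than 25%, |X5| falls by more
than 20%, and FEV1 improves by more than 12% of baseline *and* more than
200 mL.  The bronchoprovocation test (BPT, serial methacholine doses) is
positive at the first dose producing a 20% or greater FEV1 fall.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

from .reports import ChallengeSeries, PatientReport


class CriteriaEvaluationError(ValueError):
    """A measurement required by a criterion is missing or unusable."""


@dataclass(frozen=True)
class CriteriaThresholds:
    r5_pct_min: float = 150.0          # % predicted
    r20_pct_min: float = 150.0         # % predicted
    x5_deficit_min: float = 0.15       # kPa/(L/s)
    asthma_ratio_max: float = 0.8      # FEV1/FVC
    copd_ratio_max: float = 0.7        # FEV1/FVC
    copd_age_min: float = 40.0         # years
    bdt_r5_drop_min: float = 0.25      # fraction of baseline
    bdt_x5_drop_min: float = 0.20      # fraction of baseline |X5|
    bdt_fev1_change_min_frac: float = 0.12
    bdt_fev1_change_min_ml: float = 200.0
    bpt_fev1_fall_min: float = 0.20    # fraction of baseline

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be strictly positive")
        for name in ("asthma_ratio_max", "copd_ratio_max"):
            if getattr(self, name) >= 1:
                raise ValueError(f"{name} must be < 1")

    @classmethod
    def from_dict(cls, d: dict) -> "CriteriaThresholds":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown criteria threshold(s): {sorted(unknown)}")
        return cls(**d)


DEFAULT_THRESHOLDS = CriteriaThresholds()


@dataclass(frozen=True)
class ReversibilityResult:
    """Relative changes after bronchodilator, with the positivity verdict.

    Changes are signed fractions of baseline (negative = decrease);
    ``x5_abs_rel_change`` is the relative change of |X5|.
    """

    r5_rel_change: float
    x5_abs_rel_change: float
    fev1_rel_change: float
    fev1_abs_change_ml: float
    positive: bool


def asthma_static(report: PatientReport, th: CriteriaThresholds = DEFAULT_THRESHOLDS) -> bool:
    """Asthma by symptoms + baseline IOS/spirometry alone.

    Requires asthma-pattern symptoms, R5 and R20 above the upper limit of
    normal, an abnormal reactance deficit, and an obstructive ratio < 0.8.
    """
    ios, sp = report.ios, report.spirometry
    return (
        report.symptoms.asthma_symptoms
        and ios.r5_pct_pred > th.r5_pct_min
        and ios.r20_pct_pred > th.r20_pct_min
        and ios.reactance_deficit > th.x5_deficit_min
        and sp.ratio < th.asthma_ratio_max
    )


def copd_static(report: PatientReport, th: CriteriaThresholds = DEFAULT_THRESHOLDS) -> bool:
    """COPD by history + baseline IOS/spirometry alone.

    Requires COPD symptoms with an exposure history at age above 40,
    R5 above the upper limit of normal, an abnormal reactance deficit,
    and a fixed-obstruction ratio < 0.7.
    """
    ios, sp, sy = report.ios, report.spirometry, report.symptoms
    return (
        sy.copd_symptoms
        and sy.exposure_history
        and sy.age_years > th.copd_age_min
        and ios.r5_pct_pred > th.r5_pct_min
        and ios.reactance_deficit > th.x5_deficit_min
        and sp.ratio < th.copd_ratio_max
    )


def bdt_assess(series: ChallengeSeries, th: CriteriaThresholds = DEFAULT_THRESHOLDS) -> ReversibilityResult:
    """Evaluate bronchodilator reversibility from the single post-BDT step."""
    if series.kind != "BDT":
        raise CriteriaEvaluationError(f"expected a BDT series, got kind={series.kind!r}")
    if len(series.post_steps) != 1:
        raise CriteriaEvaluationError("BDT series must have exactly one post step")
    pre_ios, pre_sp = series.pre_ios, series.pre_spirometry
    post = series.post_steps[0]
    if pre_ios.r5_kpa <= 0 or pre_sp.fev1_l <= 0:
        raise CriteriaEvaluationError("baseline R5 and FEV1 must be positive")
    if pre_ios.x5_kpa == 0:
        raise CriteriaEvaluationError("baseline X5 must be nonzero to assess its relative change")
    r5_rel = (post.ios.r5_kpa - pre_ios.r5_kpa) / pre_ios.r5_kpa
    x5_rel = (abs(post.ios.x5_kpa) - abs(pre_ios.x5_kpa)) / abs(pre_ios.x5_kpa)
    fev1_rel = (post.spirometry.fev1_l - pre_sp.fev1_l) / pre_sp.fev1_l
    fev1_ml = (post.spirometry.fev1_l - pre_sp.fev1_l) * 1000.0
    positive = (
        -r5_rel > th.bdt_r5_drop_min
        and -x5_rel > th.bdt_x5_drop_min
        and fev1_rel > th.bdt_fev1_change_min_frac
        and fev1_ml > th.bdt_fev1_change_min_ml
    )
    return ReversibilityResult(
        r5_rel_change=r5_rel,
        x5_abs_rel_change=x5_rel,
        fev1_rel_change=fev1_rel,
        fev1_abs_change_ml=fev1_ml,
        positive=positive,
    )


def bpt_assess(series: ChallengeSeries, th: CriteriaThresholds = DEFAULT_THRESHOLDS) -> tuple[bool, Optional[str]]:
    """Evaluate methacholine provocation: (positive, first triggering dose label).

    Positive at the first dose whose FEV1 is at or below (1 - 20%) of
    baseline; doses after the trigger are ignored.
    """
    if series.kind != "BPT":
        raise CriteriaEvaluationError(f"expected a BPT series, got kind={series.kind!r}")
    if not series.post_steps:
        raise CriteriaEvaluationError("BPT series has no post steps")
    baseline = series.pre_spirometry.fev1_l
    if baseline <= 0:
        raise CriteriaEvaluationError("baseline FEV1 must be positive")
    cutoff = (1.0 - th.bpt_fev1_fall_min) * baseline
    for step in series.post_steps:
        if step.spirometry.fev1_l <= cutoff:
            return True, step.dose_label
    return False, None
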