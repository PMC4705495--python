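"""Stepwise asthma/COPD/healthy classification workflow.

The pipeline mirrors clinical practice: a *static* assessment from
symptoms plus baseline spirometry and IOS; when the static picture is
nonspecific, a bronchodilatation test (BDT); and when BDT does not
settle the diagnosis, a methacholine bronchoprovocation test (BPT).
Each diagnosis carries the step at which it was reached and a full
decision trace.  The rule pathway is authoritative; when a trained
network is supplied its scores are recorded alongside the diagnosis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .criteria import (
    CriteriaThresholds,
    DEFAULT_THRESHOLDS,
    asthma_static,
    bdt_assess,
    bpt_assess,
    copd_static,
)
from .fuzzy import DEFAULT_BREAKPOINTS, FuzzyBreakpoints, ObstructionPattern, evaluate_rules, fuzzify
from .network import NeuralNet, encode_features, forward
from .reports import PatientReport

STEPS = ("STATIC", "POST_BDT", "POST_BPT")

#: fuzzy patterns compatible with normal lung function at the static step
_NORMAL_PATTERNS = ("NSCO-SV", "NSCO-DV")


class NeedsChallengeError(RuntimeError):
    """A nonspecific report lacks the challenge series required to proceed."""

    def __init__(self, patient_id: str, missing: str):
        self.patient_id = patient_id
        self.missing = missing
        super().__init__(
            f"patient {patient_id!r}: nonspecific findings; {missing} required to classify"
        )


class CohortClassificationError(RuntimeError):
    """One or more patients in a cohort could not be classified."""

    def __init__(self, errors: dict):
        self.errors = errors
        msgs = "; ".join(f"{pid}: {msg}" for pid, msg in errors.items())
        super().__init__(f"{len(errors)} patient(s) failed classification: {msgs}")


@dataclass
class Diagnosis:
    label: str
    step: str
    pattern: ObstructionPattern
    ann_scores: Optional[np.ndarray] = None
    trace: list = field(default_factory=list)


def classify_patient(
    report: PatientReport,
    model: Optional[NeuralNet] = None,
    th: CriteriaThresholds = DEFAULT_THRESHOLDS,
    bp: FuzzyBreakpoints = DEFAULT_BREAKPOINTS,
) -> Diagnosis:
    """Classify one patient through the static -> BDT -> BPT cascade.

    Static step: COPD criteria are checked before asthma (the stricter
    FEV1/FVC threshold belongs to COPD); a patient with a sub-central
    fuzzy pattern, non-obstructive ratio and no positive symptom set is
    healthy.  Otherwise the report is nonspecific and the challenge
    cascade decides: a positive BDT with asthma symptoms means asthma, a
    negative BDT with the full COPD gate means COPD, and the BPT verdict
    settles the remainder (positive -> asthma, negative -> healthy).

    Raises :class:`NeedsChallengeError` when the required challenge
    series is absent.
    """
    sy, sp = report.symptoms, report.spirometry
    mv = fuzzify(report.ios, bp)
    pattern = evaluate_rules(mv)
    scores = None
    if model is not None:
        scores = forward(model, encode_features(report, pattern))
    trace: list = [("STATIC", "pattern", f"fuzzy obstruction pattern {pattern.label}")]

    def done(label, step, reason):
        trace.append((step, label, reason))
        return Diagnosis(label=label, step=step, pattern=pattern, ann_scores=scores, trace=trace)

    # --- step 1: static assessment
    if copd_static(report, th):
        return done("copd", "STATIC", "COPD history with R5, reactance deficit and ratio beyond thresholds")
    if asthma_static(report, th):
        return done("asthma", "STATIC", "asthma symptoms with R5, R20, reactance deficit and ratio beyond thresholds")
    asthma_set = sy.asthma_symptoms
    copd_set = sy.copd_symptoms and sy.exposure_history
    if pattern.label in _NORMAL_PATTERNS and sp.ratio >= th.asthma_ratio_max and not asthma_set and not copd_set:
        return done("healthy", "STATIC", "all measurements within normal limits and no symptom set positive")
    trace.append(("STATIC", "nonspecific", "static criteria inconclusive; challenge testing required"))

    # --- step 2: bronchodilatation test
    if report.bdt is None:
        raise NeedsChallengeError(report.patient_id, "BDT")
    rev = bdt_assess(report.bdt, th)
    if rev.positive and sy.asthma_symptoms:
        return done(
            "asthma", "POST_BDT",
            f"reversible obstruction (R5 {rev.r5_rel_change:+.0%}, FEV1 {rev.fev1_rel_change:+.0%}) with asthma symptoms",
        )
    if (
        not rev.positive
        and sy.copd_symptoms
        and sy.exposure_history
        and sy.age_years > th.copd_age_min
        and sp.ratio < th.copd_ratio_max
    ):
        return done("copd", "POST_BDT", "non-reversible obstruction with COPD history, age and fixed ratio")
    trace.append(("POST_BDT", "nonspecific", "bronchodilator response inconclusive; provocation required"))

    # --- step 3: bronchoprovocation test
    if report.bpt is None:
        raise NeedsChallengeError(report.patient_id, "BPT")
    positive, dose = bpt_assess(report.bpt, th)
    if positive:
        return done("asthma", "POST_BPT", f"bronchial hyperreactivity at methacholine dose {dose}")
    return done("healthy", "POST_BPT", "no bronchial hyperreactivity across methacholine doses")


def classify_cohort(
    reports: Sequence[PatientReport],
    model: Optional[NeuralNet] = None,
    th: CriteriaThresholds = DEFAULT_THRESHOLDS,
    bp: FuzzyBreakpoints = DEFAULT_BREAKPOINTS,
) -> list[Diagnosis]:
    """Element-wise :func:`classify_patient`, order preserved.

    Per-patient failures are aggregated into one
    :class:`CohortClassificationError` naming every affected patient.
    """
    diagnoses: list[Diagnosis] = []
    errors: dict = {}
    for r in reports:
        try:
            diagnoses.append(classify_patient(r, model, th, bp))
        except (NeedsChallengeError, ValueError) as exc:
            errors[r.patient_id] = str(exc)
    if errors:
        raise CohortClassificationError(errors)
    return diagnoses


def summarize_steps(diagnoses: Sequence[Diagnosis]) -> dict:
    """Per-(step, label) counts — the stepwise hits breakdown of a run."""
    counts = Counter((d.step, d.label) for d in diagnoses)
    return {f"{step}:{label}": n for (step, label), n in sorted(counts.items())}
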