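"""Seeded synthetic patient-report generator.

Emulates the content of Master Screen IOS-style pulmonary-function
reports for three phenotypes (healthy, asthma, COPD).  Measurements are
drawn from class-conditional truncated normals whose supports are chosen
so that, at ``noise_scale`` 0, every report is classified back to its
true label by the rule workflow: *specific* diseased cases meet the
static criteria with margin, while a configurable *nonspecific* fraction
is drawn near-threshold (failing the static criteria) and carries a BDT
series — and, for the BDT-non-responding asthma subset, a methacholine
BPT series — constructed to yield the correct challenge outcome.

Age distributions default to the cohort profile of the validation study
(asthma 19.85 +/- 8.185, COPD 52.25 +/- 7.636, healthy 30.03 +/- 11.833
years), truncated symmetrically about the mean so the mean is preserved;
the COPD lower bound of 41 additionally guarantees the age-above-40
criterion.  ``noise_scale`` applies multiplicative Gaussian noise to all
stored measurements after construction; label recovery is only
guaranteed at 0.

Draw order per report is fixed (age, smoking, allergies, nonspecific
flag, BPT-bound flag, the ten baseline measurements, then challenge
draws) so adding parameters never silently reorders existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.stats import truncnorm

from .reports import (
    ChallengeSeries,
    ChallengeStep,
    IOSResult,
    LABELS,
    PatientReport,
    SpirometryResult,
    SymptomProfile,
)

#: standard serially-increasing methacholine doses (mg/mL)
BPT_DOSES = ("0.0625", "0.25", "1", "4", "16")


@dataclass(frozen=True)
class Dist:
    """Truncated normal N(mean, sd) restricted to [lo, hi]."""

    mean: float
    sd: float
    lo: float
    hi: float

    def draw(self, rng: np.random.Generator) -> float:
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return float(truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, random_state=rng))


# measurement names in draw order
_MEAS = ("r5_pct", "r20_pct", "r5_kpa", "delta_r", "x5_pred", "deficit", "ratio", "fvc", "fev1_pct", "fres")


def _profile(**kw) -> dict:
    assert set(kw) == set(_MEAS)
    return kw


_DEFAULT_PROFILES = {
    # normal lung function: everything well inside reference limits
    "healthy": _profile(
        r5_pct=Dist(95, 15, 60, 130), r20_pct=Dist(92, 12, 60, 130),
        r5_kpa=Dist(0.30, 0.05, 0.18, 0.45), delta_r=Dist(0.01, 0.012, -0.02, 0.04),
        x5_pred=Dist(-0.10, 0.02, -0.16, -0.05), deficit=Dist(0.04, 0.03, -0.04, 0.12),
        ratio=Dist(0.85, 0.025, 0.805, 0.95), fvc=Dist(4.2, 0.6, 2.8, 5.8),
        fev1_pct=Dist(97, 8, 80, 120), fres=Dist(10, 2, 6, 16),
    ),
    # asthma meeting all four static criteria with margin
    "asthma": _profile(
        r5_pct=Dist(180, 15, 157, 230), r20_pct=Dist(170, 10, 157, 200),
        r5_kpa=Dist(0.55, 0.08, 0.42, 0.80), delta_r=Dist(0.10, 0.04, 0.01, 0.19),
        x5_pred=Dist(-0.12, 0.02, -0.18, -0.06), deficit=Dist(0.30, 0.07, 0.16, 0.55),
        ratio=Dist(0.72, 0.03, 0.63, 0.795), fvc=Dist(3.8, 0.5, 2.8, 5.0),
        fev1_pct=Dist(68, 10, 45, 85), fres=Dist(20, 4, 12, 30),
    ),
    # near-threshold asthma: resistances below the 150 %pred gate, small
    # reactance deficit — needs a challenge test to classify
    "asthma_nonspecific": _profile(
        r5_pct=Dist(135, 8, 112, 149), r20_pct=Dist(128, 8, 105, 148),
        r5_kpa=Dist(0.42, 0.05, 0.32, 0.55), delta_r=Dist(0.03, 0.01, 0.005, 0.045),
        x5_pred=Dist(-0.11, 0.02, -0.16, -0.06), deficit=Dist(0.08, 0.03, 0.0, 0.14),
        ratio=Dist(0.76, 0.015, 0.72, 0.795), fvc=Dist(3.8, 0.5, 2.8, 5.0),
        fev1_pct=Dist(78, 6, 65, 92), fres=Dist(14, 3, 8, 22),
    ),
    # COPD: peripheral obstruction, fixed low ratio
    "copd": _profile(
        r5_pct=Dist(190, 18, 157, 250), r20_pct=Dist(165, 6, 156, 185),
        r5_kpa=Dist(0.75, 0.10, 0.58, 1.0), delta_r=Dist(0.43, 0.04, 0.36, 0.52),
        x5_pred=Dist(-0.13, 0.02, -0.19, -0.07), deficit=Dist(0.40, 0.08, 0.20, 0.65),
        ratio=Dist(0.58, 0.05, 0.42, 0.68), fvc=Dist(3.4, 0.5, 2.4, 4.6),
        fev1_pct=Dist(48, 10, 28, 68), fres=Dist(28, 5, 18, 40),
    ),
    # near-threshold COPD: R5 and deficit below the static gates, but the
    # fixed ratio and history persist — resolved by a negative BDT
    "copd_nonspecific": _profile(
        r5_pct=Dist(138, 7, 118, 149), r20_pct=Dist(125, 8, 100, 148),
        r5_kpa=Dist(0.45, 0.05, 0.35, 0.60), delta_r=Dist(0.10, 0.03, 0.03, 0.17),
        x5_pred=Dist(-0.11, 0.02, -0.16, -0.06), deficit=Dist(0.08, 0.03, 0.0, 0.14),
        ratio=Dist(0.64, 0.02, 0.58, 0.69), fvc=Dist(3.4, 0.5, 2.4, 4.6),
        fev1_pct=Dist(60, 8, 45, 75), fres=Dist(22, 4, 14, 32),
    ),
}

# bronchodilator response magnitudes (fractions of baseline)
_DEFAULT_BDT = {
    "responder": {
        "r5_drop": Dist(0.35, 0.04, 0.28, 0.45),
        "x5_drop": Dist(0.30, 0.04, 0.23, 0.42),
        "fev1_gain": Dist(0.18, 0.03, 0.13, 0.28),
    },
    "nonresponder": {
        "r5_drop": Dist(0.05, 0.03, -0.03, 0.12),
        "x5_drop": Dist(0.05, 0.03, -0.05, 0.12),
        "fev1_gain": Dist(0.03, 0.02, -0.02, 0.07),
    },
}

# ages truncated symmetrically about the mean (mean-preserving); COPD lower
# bound 41 guarantees the age-above-40 history criterion
_DEFAULT_AGE = {
    "asthma": Dist(19.85, 8.185, 5.0, 34.7),
    "copd": Dist(52.25, 7.636, 41.0, 63.5),
    "healthy": Dist(30.03, 11.833, 5.0, 55.06),
}


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the synthetic cohort generator.

    Defaults reproduce the validation-study structure: class counts
    170/248/37, nonspecific fractions 21/170 (asthma) and 36/248 (COPD)
    with 4/21 of nonspecific asthma resolved only at BPT, and the
    study's per-class smoking/allergy prevalences.
    """

    n_asthma: int = 170
    n_copd: int = 248
    n_healthy: int = 37
    noise_scale: float = 0.0
    seed: int = 0
    nonspecific_fraction: dict = field(
        default_factory=lambda: {"asthma": 21 / 170, "copd": 36 / 248, "healthy": 0.0}
    )
    bpt_fraction_asthma: float = 4 / 21
    profiles: dict = field(default_factory=lambda: dict(_DEFAULT_PROFILES))
    bdt_response: dict = field(default_factory=lambda: dict(_DEFAULT_BDT))
    age: dict = field(default_factory=lambda: dict(_DEFAULT_AGE))
    smoking_p: dict = field(
        default_factory=lambda: {"asthma": 0.341, "copd": 0.714, "healthy": 0.595}
    )
    allergies_p: dict = field(
        default_factory=lambda: {"asthma": 0.418, "copd": 0.314, "healthy": 0.351}
    )

    def validate(self) -> None:
        for name in ("n_asthma", "n_copd", "n_healthy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        for d in (self.nonspecific_fraction, self.smoking_p, self.allergies_p):
            for k, v in d.items():
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"probability {k}={v} outside [0, 1]")
        if not (0.0 <= self.bpt_fraction_asthma <= 1.0):
            raise ValueError("bpt_fraction_asthma outside [0, 1]")


def _spiro(fev1: float, fvc: float, fev1_pct: float) -> SpirometryResult:
    return SpirometryResult(fev1_l=fev1, fvc_l=fvc, fev1_pct_pred=fev1_pct)


def _ios(m: dict) -> IOSResult:
    return IOSResult(
        r5_kpa=m["r5_kpa"],
        r20_kpa=m["r5_kpa"] - m["delta_r"],
        x5_kpa=m["x5_pred"] - m["deficit"],
        x5_pred_kpa=m["x5_pred"],
        r5_pct_pred=m["r5_pct"],
        r20_pct_pred=m["r20_pct"],
        fres_hz=m["fres"],
    )


def _bdt_series(m: dict, response: dict, rng: np.random.Generator) -> ChallengeSeries:
    r5_drop = response["r5_drop"].draw(rng)
    x5_drop = response["x5_drop"].draw(rng)
    fev1_gain = response["fev1_gain"].draw(rng)
    post = dict(m)
    post["r5_kpa"] = m["r5_kpa"] * (1 - r5_drop)
    post["delta_r"] = m["delta_r"] * (1 - r5_drop)
    post["r5_pct"] = m["r5_pct"] * (1 - r5_drop)
    post["r20_pct"] = m["r20_pct"] * (1 - r5_drop)
    # reactance moves toward predicted: |X5| shrinks by x5_drop
    x5 = m["x5_pred"] - m["deficit"]
    post_x5 = x5 * (1 - x5_drop)
    post["deficit"] = m["x5_pred"] - post_x5
    fev1 = m["ratio"] * m["fvc"]
    post_fev1 = fev1 * (1 + fev1_gain)
    post_fvc = m["fvc"] * (1 + fev1_gain / 2)
    return ChallengeSeries(
        kind="BDT",
        agent="salbutamol_400ug",
        pre_spirometry=_spiro(fev1, m["fvc"], m["fev1_pct"]),
        pre_ios=_ios(m),
        post_steps=[
            ChallengeStep(
                dose_label="post",
                spirometry=_spiro(post_fev1, post_fvc, m["fev1_pct"] * (1 + fev1_gain)),
                ios=_ios(post),
            )
        ],
    )


def _bpt_series(m: dict, rng: np.random.Generator) -> ChallengeSeries:
    """Serial methacholine doses ending at the first >= 20% FEV1 fall."""
    trigger = int(rng.integers(1, len(BPT_DOSES)))
    fev1 = m["ratio"] * m["fvc"]
    steps = []
    for i in range(trigger + 1):
        if i < trigger:
            frac = Dist(0.93 - 0.02 * i, 0.015, 0.85, 0.99).draw(rng)
        else:
            frac = Dist(0.74, 0.02, 0.68, 0.79).draw(rng)
        step_m = dict(m)
        step_m["r5_kpa"] = m["r5_kpa"] * (1 + 0.06 * (i + 1))
        step_m["deficit"] = m["deficit"] + 0.01 * (i + 1)
        steps.append(
            ChallengeStep(
                dose_label=BPT_DOSES[i],
                spirometry=_spiro(fev1 * frac, m["fvc"], m["fev1_pct"] * frac),
                ios=_ios(step_m),
            )
        )
    return ChallengeSeries(
        kind="BPT",
        agent="methacholine",
        pre_spirometry=_spiro(fev1, m["fvc"], m["fev1_pct"]),
        pre_ios=_ios(m),
        post_steps=steps,
    )


def _noisy_spiro(s: SpirometryResult, scale: float, rng: np.random.Generator) -> SpirometryResult:
    fev1 = max(s.fev1_l * (1 + scale * rng.standard_normal()), 0.2)
    fvc = max(s.fvc_l * (1 + scale * rng.standard_normal()), fev1 / 1.2)
    pct = max(s.fev1_pct_pred * (1 + scale * rng.standard_normal()), 5.0)
    return SpirometryResult(fev1_l=fev1, fvc_l=fvc, fev1_pct_pred=pct)


def _noisy_ios(i: IOSResult, scale: float, rng: np.random.Generator) -> IOSResult:
    def pos(v):
        return max(v * (1 + scale * rng.standard_normal()), 0.01)

    return IOSResult(
        r5_kpa=pos(i.r5_kpa),
        r20_kpa=pos(i.r20_kpa),
        x5_kpa=i.x5_kpa * (1 + scale * rng.standard_normal()),
        x5_pred_kpa=i.x5_pred_kpa * (1 + scale * rng.standard_normal()),
        r5_pct_pred=pos(i.r5_pct_pred),
        r20_pct_pred=pos(i.r20_pct_pred),
        fres_hz=pos(i.fres_hz) if i.fres_hz is not None else None,
    )


def _apply_noise(report: PatientReport, scale: float, rng: np.random.Generator) -> PatientReport:
    if scale == 0:
        return report

    def perturb_series(s: Optional[ChallengeSeries]) -> Optional[ChallengeSeries]:
        if s is None:
            return None
        return replace(
            s,
            pre_spirometry=_noisy_spiro(s.pre_spirometry, scale, rng),
            pre_ios=_noisy_ios(s.pre_ios, scale, rng),
            post_steps=[
                ChallengeStep(
                    dose_label=st.dose_label,
                    spirometry=_noisy_spiro(st.spirometry, scale, rng),
                    ios=_noisy_ios(st.ios, scale, rng),
                )
                for st in s.post_steps
            ],
        )

    return replace(
        report,
        spirometry=_noisy_spiro(report.spirometry, scale, rng),
        ios=_noisy_ios(report.ios, scale, rng),
        bdt=perturb_series(report.bdt),
        bpt=perturb_series(report.bpt),
    )


def sample_report(
    true_label: str,
    params: GeneratorParams,
    rng: np.random.Generator,
    patient_id: str = "PT0000",
) -> PatientReport:
    """Draw one phenotype-consistent report from the class-conditional model."""
    if true_label not in LABELS:
        raise ValueError(f"unknown label {true_label!r}")
    params.validate()
    age = int(round(params.age[true_label].draw(rng)))
    smoking = bool(rng.random() < params.smoking_p[true_label])
    allergies = bool(rng.random() < params.allergies_p[true_label])
    nonspecific = bool(rng.random() < params.nonspecific_fraction[true_label])
    bpt_bound = bool(rng.random() < params.bpt_fraction_asthma) and true_label == "asthma" and nonspecific

    profile_key = true_label + ("_nonspecific" if nonspecific and true_label != "healthy" else "")
    prof = params.profiles[profile_key]
    m = {name: prof[name].draw(rng) for name in _MEAS}

    if true_label == "asthma":
        symptoms = SymptomProfile(True, False, smoking, allergies, smoking, age)
    elif true_label == "copd":
        symptoms = SymptomProfile(False, True, True, allergies, smoking, age)
    else:
        symptoms = SymptomProfile(False, False, smoking, allergies, smoking, age)

    bdt = bpt = None
    if nonspecific and true_label != "healthy":
        if true_label == "asthma" and not bpt_bound:
            bdt = _bdt_series(m, params.bdt_response["responder"], rng)
        else:
            bdt = _bdt_series(m, params.bdt_response["nonresponder"], rng)
        if bpt_bound:
            bpt = _bpt_series(m, rng)

    fev1 = m["ratio"] * m["fvc"]
    report = PatientReport(
        patient_id=patient_id,
        symptoms=symptoms,
        spirometry=_spiro(fev1, m["fvc"], m["fev1_pct"]),
        ios=_ios(m),
        bdt=bdt,
        bpt=bpt,
        true_label=true_label,
    )
    return _apply_noise(report, params.noise_scale, rng)


def generate_cohort(params: GeneratorParams) -> list[PatientReport]:
    """Generate the full cohort: exact per-class counts, shuffled, seeded."""
    params.validate()
    total = params.n_asthma + params.n_copd + params.n_healthy
    if total == 0:
        raise ValueError("all class counts are zero; nothing to generate")
    rng = np.random.default_rng(params.seed)
    reports: list[PatientReport] = []
    for label, count in (("asthma", params.n_asthma), ("copd", params.n_copd), ("healthy", params.n_healthy)):
        for _ in range(count):
            reports.append(sample_report(label, params, rng))
    order = rng.permutation(total)
    shuffled = [reports[i] for i in order]
    width = max(4, len(str(total)))
    for i, r in enumerate(shuffled):
        shuffled[i] = replace(r, patient_id=f"PT{i + 1:0{width}d}")
    return shuffled
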