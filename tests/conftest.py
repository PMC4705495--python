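import numpy as np
import pytest

from airwaydx.reports import (
    ChallengeSeries,
    ChallengeStep,
    IOSResult,
    PatientReport,
    SpirometryResult,
    SymptomProfile,
)


def make_spiro(fev1=2.8, fvc=3.2, pct=95.0, ratio=None):
    return SpirometryResult(fev1_l=fev1, fvc_l=fvc, fev1_pct_pred=pct, ratio=ratio)


def make_ios(r5=0.35, r20=0.33, x5=-0.12, x5_pred=-0.10, r5_pct=100.0, r20_pct=100.0, fres=12.0):
    return IOSResult(
        r5_kpa=r5, r20_kpa=r20, x5_kpa=x5, x5_pred_kpa=x5_pred,
        r5_pct_pred=r5_pct, r20_pct_pred=r20_pct, fres_hz=fres,
    )


def make_symptoms(asthma=False, copd=False, exposure=False, allergies=False, smoking=False, age=30):
    return SymptomProfile(
        asthma_symptoms=asthma, copd_symptoms=copd, exposure_history=exposure,
        allergies=allergies, smoking=smoking, age_years=age,
    )


def make_report(patient_id="P1", symptoms=None, spirometry=None, ios=None,
                bdt=None, bpt=None, true_label=None):
    return PatientReport(
        patient_id=patient_id,
        symptoms=symptoms or make_symptoms(),
        spirometry=spirometry or make_spiro(),
        ios=ios or make_ios(),
        bdt=bdt,
        bpt=bpt,
        true_label=true_label,
    )


def make_bdt(pre_spiro, pre_ios, post_spiro, post_ios):
    return ChallengeSeries(
        kind="BDT", agent="salbutamol_400ug",
        pre_spirometry=pre_spiro, pre_ios=pre_ios,
        post_steps=[ChallengeStep(dose_label="post", spirometry=post_spiro, ios=post_ios)],
    )


def make_bpt(pre_spiro, pre_ios, fev1_values, doses=None):
    doses = doses or [str(2 ** i) for i in range(len(fev1_values))]
    steps = [
        ChallengeStep(
            dose_label=d,
            spirometry=make_spiro(fev1=f, fvc=pre_spiro.fvc_l, pct=pre_spiro.fev1_pct_pred),
            ios=pre_ios,
        )
        for d, f in zip(doses, fev1_values)
    ]
    return ChallengeSeries(
        kind="BPT", agent="methacholine",
        pre_spirometry=pre_spiro, pre_ios=pre_ios, post_steps=steps,
    )


@pytest.fixture
def table4_confusion():
    """The published 455-patient validation confusion counts."""
    from airwaydx.metrics import Confusion3

    return Confusion3(counts=np.array([[169, 0, 1], [1, 246, 1], [0, 0, 37]]))
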