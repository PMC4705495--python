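"""Patient-report domain types and cohort file I/O.

A :class:`PatientReport` bundles one patient's symptom/history flags with
baseline spirometry and impulse-oscillometry (IOS) measurements, plus
optional bronchodilatation (BDT) and bronchoprovocation (BPT) challenge
series.  Cohorts are stored as flat CSV (baseline + single post-BDT step)
or JSON (full nesting, including multi-dose BPT series).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

LABELS = ("asthma", "copd", "healthy")

#: tolerance for the FEV1/FVC ratio consistency invariant
RATIO_TOL = 1e-6


class CohortSchemaError(ValueError):
    """A mandatory column/field is missing from a cohort file."""


class CohortParseError(ValueError):
    """A value could not be parsed as the required type."""


class CohortValidationError(ValueError):
    """A record violates a report invariant (e.g. duplicate patient_id)."""


def _finite(x: float) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x)


@dataclass
class SpirometryResult:
    """Forced-expiration test result.

    ``ratio`` (FEV1/FVC) is computed from the volumes when not supplied.
    """

    fev1_l: float
    fvc_l: float
    fev1_pct_pred: float
    ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ratio is None:
            if self.fvc_l <= 0:
                raise CohortValidationError("fvc_l must be positive to derive ratio")
            self.ratio = self.fev1_l / self.fvc_l


@dataclass
class IOSResult:
    """Impulse-oscillometry measurement set.

    Resistances in kPa/(L/s); reactance X5 is stored as measured (typically
    negative).  The rule inputs are derived:  ``delta_r`` = R5 - R20
    (peripheral-obstruction index) and ``reactance_deficit`` =
    X5pred - X5 (positive when reactance is more negative than predicted).
    """

    r5_kpa: float
    r20_kpa: float
    x5_kpa: float
    x5_pred_kpa: float
    r5_pct_pred: float
    r20_pct_pred: float
    fres_hz: Optional[float] = None

    @property
    def delta_r(self) -> float:
        return self.r5_kpa - self.r20_kpa

    @property
    def reactance_deficit(self) -> float:
        return self.x5_pred_kpa - self.x5_kpa


@dataclass
class SymptomProfile:
    asthma_symptoms: bool
    copd_symptoms: bool
    exposure_history: bool
    allergies: bool
    smoking: bool
    age_years: int


@dataclass
class ChallengeStep:
    dose_label: str
    spirometry: SpirometryResult
    ios: IOSResult


@dataclass
class ChallengeSeries:
    """Pre/post measurement series for a BDT or BPT challenge.

    BDT (salbutamol 400 ug) carries exactly one post step; BPT
    (methacholine) carries one step per administered dose, in strictly
    increasing dose order.
    """

    kind: str  # "BDT" | "BPT"
    agent: str  # "salbutamol_400ug" | "methacholine"
    pre_spirometry: SpirometryResult
    pre_ios: IOSResult
    post_steps: list[ChallengeStep] = field(default_factory=list)


@dataclass
class PatientReport:
    patient_id: str
    symptoms: SymptomProfile
    spirometry: SpirometryResult
    ios: IOSResult
    bdt: Optional[ChallengeSeries] = None
    bpt: Optional[ChallengeSeries] = None
    true_label: Optional[str] = None


# ---------------------------------------------------------------------------
# validation

def _check_spiro(s: SpirometryResult, prefix: str, issues: list[str]) -> None:
    for name in ("fev1_l", "fvc_l", "fev1_pct_pred", "ratio"):
        v = getattr(s, name)
        if v is None or not _finite(v) or v <= 0:
            issues.append(f"{prefix}{name}: must be a finite positive number (got {v!r})")
            return
    if s.ratio > 1.2:
        issues.append(f"{prefix}ratio: FEV1/FVC must lie in (0, 1.2] (got {s.ratio:g})")
    if abs(s.ratio - s.fev1_l / s.fvc_l) > RATIO_TOL:
        issues.append(
            f"{prefix}ratio: inconsistent with fev1_l/fvc_l "
            f"({s.ratio:g} vs {s.fev1_l / s.fvc_l:g})"
        )


def _check_ios(i: IOSResult, prefix: str, issues: list[str]) -> None:
    for name in ("r5_kpa", "r20_kpa", "r5_pct_pred", "r20_pct_pred"):
        v = getattr(i, name)
        if not _finite(v) or v <= 0:
            issues.append(f"{prefix}{name}: must be a finite positive number (got {v!r})")
    for name in ("x5_kpa", "x5_pred_kpa"):
        if not _finite(getattr(i, name)):
            issues.append(f"{prefix}{name}: must be finite")
    if i.fres_hz is not None and (not _finite(i.fres_hz) or i.fres_hz <= 0):
        issues.append(f"{prefix}fres_hz: must be finite positive when present")


def validate_report(report: PatientReport) -> list[str]:
    """Return a list of invariant violations; empty iff the report is valid."""
    issues: list[str] = []
    if not report.patient_id:
        issues.append("patient_id: must be non-empty")
    sp = report.symptoms
    for name in ("asthma_symptoms", "copd_symptoms", "exposure_history", "allergies", "smoking"):
        if not isinstance(getattr(sp, name), bool):
            issues.append(f"symptoms.{name}: must be an explicit boolean")
    if not isinstance(sp.age_years, int) or sp.age_years < 0:
        issues.append(f"symptoms.age_years: must be a non-negative integer (got {sp.age_years!r})")
    _check_spiro(report.spirometry, "spirometry.", issues)
    _check_ios(report.ios, "ios.", issues)
    if report.true_label is not None and report.true_label not in LABELS:
        issues.append(f"true_label: must be one of {LABELS} (got {report.true_label!r})")
    if report.bpt is not None and report.bdt is None:
        issues.append("bpt: present without bdt (challenge tests are ordered BDT before BPT)")
    for series, name in ((report.bdt, "bdt"), (report.bpt, "bpt")):
        if series is None:
            continue
        expected_kind = name.upper()
        if series.kind != expected_kind:
            issues.append(f"{name}.kind: expected {expected_kind} (got {series.kind!r})")
        if not series.post_steps:
            issues.append(f"{name}.post_steps: at least one post step required")
        if name == "bdt" and len(series.post_steps) != 1:
            issues.append(f"bdt.post_steps: BDT has exactly one post step (got {len(series.post_steps)})")
        _check_spiro(series.pre_spirometry, f"{name}.pre.", issues)
        _check_ios(series.pre_ios, f"{name}.pre.", issues)
        for k, step in enumerate(series.post_steps):
            _check_spiro(step.spirometry, f"{name}.post[{k}].", issues)
            _check_ios(step.ios, f"{name}.post[{k}].", issues)
        if name == "bpt" and len(series.post_steps) >= 2:
            try:
                doses = [float(s.dose_label) for s in series.post_steps]
            except ValueError:
                doses = None
            if doses is not None and any(b <= a for a, b in zip(doses, doses[1:])):
                issues.append("bpt.post_steps: dose labels must be strictly increasing")
    return issues


# ---------------------------------------------------------------------------
# CSV layout

_SPIRO_COLS = ("fev1_l", "fvc_l", "fev1_pct_pred", "ratio")
_IOS_COLS = ("r5_kpa", "r20_kpa", "r5_pct_pred", "r20_pct_pred", "x5_kpa", "x5_pred_kpa", "fres_hz")
_BOOL_COLS = ("asthma_symptoms", "copd_symptoms", "exposure_history", "allergies", "smoking")

#: mandatory CSV columns (fres_hz, ratio and true_label may be empty but the
#: columns must exist; bdt_* columns are optional as a block)
CSV_COLUMNS = (
    ("patient_id", "age_years")
    + _BOOL_COLS
    + _SPIRO_COLS
    + _IOS_COLS
    + tuple("bdt_" + c for c in _SPIRO_COLS + _IOS_COLS)
    + ("true_label",)
)

_OPTIONAL_VALUE_COLS = {"ratio", "fres_hz", "true_label", "bdt_ratio", "bdt_fres_hz"}


def _spiro_to_row(s: SpirometryResult, prefix: str = "") -> dict:
    return {prefix + c: getattr(s, c) for c in _SPIRO_COLS}


def _ios_to_row(i: IOSResult, prefix: str = "") -> dict:
    return {prefix + c: getattr(i, c) for c in _IOS_COLS}


def _spiro_from_row(row: dict, prefix: str = "") -> SpirometryResult:
    vals = {c: row.get(prefix + c) for c in _SPIRO_COLS}
    return SpirometryResult(**vals)


def _ios_from_row(row: dict, prefix: str = "") -> IOSResult:
    vals = {c: row.get(prefix + c) for c in _IOS_COLS}
    return IOSResult(**vals)


def _report_to_flat(r: PatientReport) -> dict:
    row: dict = {"patient_id": r.patient_id, "age_years": r.symptoms.age_years}
    for c in _BOOL_COLS:
        row[c] = getattr(r.symptoms, c)
    row.update(_spiro_to_row(r.spirometry))
    row.update(_ios_to_row(r.ios))
    if r.bdt is not None:
        step = r.bdt.post_steps[0]
        row.update(_spiro_to_row(step.spirometry, "bdt_"))
        row.update(_ios_to_row(step.ios, "bdt_"))
    else:
        for c in _SPIRO_COLS + _IOS_COLS:
            row["bdt_" + c] = None
    row["true_label"] = r.true_label
    return row


# ---------------------------------------------------------------------------
# JSON layout

def _spiro_to_json(s: SpirometryResult) -> dict:
    return {c: getattr(s, c) for c in _SPIRO_COLS}


def _ios_to_json(i: IOSResult) -> dict:
    return {c: getattr(i, c) for c in _IOS_COLS}


def _series_to_json(s: ChallengeSeries) -> dict:
    return {
        "kind": s.kind,
        "agent": s.agent,
        "pre": {"spirometry": _spiro_to_json(s.pre_spirometry), "ios": _ios_to_json(s.pre_ios)},
        "post_steps": [
            {
                "dose_label": st.dose_label,
                "spirometry": _spiro_to_json(st.spirometry),
                "ios": _ios_to_json(st.ios),
            }
            for st in s.post_steps
        ],
    }


def _series_from_json(d: dict) -> ChallengeSeries:
    return ChallengeSeries(
        kind=d["kind"],
        agent=d["agent"],
        pre_spirometry=SpirometryResult(**d["pre"]["spirometry"]),
        pre_ios=IOSResult(**d["pre"]["ios"]),
        post_steps=[
            ChallengeStep(
                dose_label=st["dose_label"],
                spirometry=SpirometryResult(**st["spirometry"]),
                ios=IOSResult(**st["ios"]),
            )
            for st in d["post_steps"]
        ],
    )


def _report_to_json(r: PatientReport) -> dict:
    d = {
        "patient_id": r.patient_id,
        "symptoms": {c: getattr(r.symptoms, c) for c in _BOOL_COLS + ("age_years",)},
        "spirometry": _spiro_to_json(r.spirometry),
        "ios": _ios_to_json(r.ios),
        "true_label": r.true_label,
    }
    if r.bdt is not None:
        d["bdt"] = _series_to_json(r.bdt)
    if r.bpt is not None:
        d["bpt"] = _series_to_json(r.bpt)
    return d


def _report_from_json(d: dict) -> PatientReport:
    return PatientReport(
        patient_id=d["patient_id"],
        symptoms=SymptomProfile(**d["symptoms"]),
        spirometry=SpirometryResult(**d["spirometry"]),
        ios=IOSResult(**d["ios"]),
        bdt=_series_from_json(d["bdt"]) if "bdt" in d and d["bdt"] is not None else None,
        bpt=_series_from_json(d["bpt"]) if "bpt" in d and d["bpt"] is not None else None,
        true_label=d.get("true_label"),
    )


# ---------------------------------------------------------------------------
# public I/O

def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise ValueError(f"format must be 'csv' or 'json', got {fmt!r}")
        return fmt
    return "json" if path.suffix.lower() == ".json" else "csv"


def read_cohort(path, format: Optional[str] = None) -> list[PatientReport]:
    """Read a cohort file (CSV or JSON) into validated reports, row order kept."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        reports = [_report_from_json(d) for d in payload]
    else:
        reports = _read_csv(path)
    seen: set[str] = set()
    for i, r in enumerate(reports):
        if r.patient_id in seen:
            raise CohortValidationError(f"duplicate patient_id {r.patient_id!r}")
        seen.add(r.patient_id)
        issues = validate_report(r)
        if issues:
            raise CohortValidationError(
                f"record {i} ({r.patient_id!r}): " + "; ".join(issues)
            )
    return reports


def _read_csv(path: Path) -> list[PatientReport]:
    # parse numbers ourselves with Python float() so values written as
    # repr round-trip bit-exactly (pandas' fast parser is not exact)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    reports = []
    for idx, raw in df.iterrows():
        row: dict = {}
        for c in CSV_COLUMNS:
            v = raw[c]
            if pd.isna(v):
                row[c] = None
                continue
            if c in ("patient_id", "true_label"):
                row[c] = str(v)
            elif c in _BOOL_COLS:
                row[c] = _parse_bool(v, c, idx)
            elif c == "age_years":
                row[c] = _parse_int(v, c, idx)
            else:
                row[c] = _parse_float(v, c, idx)
        has_bdt = row.get("bdt_fev1_l") is not None
        symptoms = SymptomProfile(
            **{c: row[c] for c in _BOOL_COLS}, age_years=row["age_years"]
        )
        bdt = None
        if has_bdt:
            bdt = ChallengeSeries(
                kind="BDT",
                agent="salbutamol_400ug",
                pre_spirometry=_spiro_from_row(row),
                pre_ios=_ios_from_row(row),
                post_steps=[
                    ChallengeStep(
                        dose_label="post",
                        spirometry=_spiro_from_row(row, "bdt_"),
                        ios=_ios_from_row(row, "bdt_"),
                    )
                ],
            )
        reports.append(
            PatientReport(
                patient_id=row["patient_id"],
                symptoms=symptoms,
                spirometry=_spiro_from_row(row),
                ios=_ios_from_row(row),
                bdt=bdt,
                true_label=row["true_label"],
            )
        )
    return reports


def _parse_bool(v, col, idx):
    if isinstance(v, (bool,)):
        return v
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise CohortParseError(f"row {idx}: column {col!r}: cannot parse boolean from {v!r}")


def _parse_int(v, col, idx):
    try:
        f = float(v)
        if f != int(f):
            raise ValueError
        return int(f)
    except (TypeError, ValueError):
        raise CohortParseError(f"row {idx}: column {col!r}: cannot parse integer from {v!r}") from None


def _parse_float(v, col, idx):
    try:
        return float(v)
    except (TypeError, ValueError):
        raise CohortParseError(f"row {idx}: column {col!r}: cannot parse number from {v!r}") from None


def write_cohort(reports: Iterable[PatientReport], path, format: Optional[str] = None) -> None:
    """Write a non-empty cohort to CSV or JSON.

    CSV is flat (baseline + the single post-BDT step); cohorts containing
    BPT series require JSON.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("cannot write an empty cohort")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump([_report_to_json(r) for r in reports], fh, indent=1)
        return
    if any(r.bpt is not None for r in reports):
        raise ValueError("cohort contains BPT series; the flat CSV layout cannot hold them — write JSON instead")
    # keep cells as Python objects and render floats with repr so every
    # value round-trips bit-exactly through the text format
    df = pd.DataFrame([_report_to_flat(r) for r in reports], columns=list(CSV_COLUMNS), dtype=object)
    df = df.map(lambda v: repr(v) if isinstance(v, float) else v)
    df.to_csv(path, index=False)
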