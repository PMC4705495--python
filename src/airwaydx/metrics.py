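"""Confusion matrices and diagnostic performance metrics.

The three-class confusion matrix (asthma, COPD, healthy) collapses to a
binary diseased-vs-healthy matrix in which any diseased prediction for a
diseased patient counts as test-positive (including cross-confusions
between the two diseases).  Two sensitivities are distinguished: ``tpr``
(diseased detected as diseased) and ``disease_sensitivity``
(diseased assigned their *correct* disease label).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

LABELS = ("asthma", "copd", "healthy")
_DISEASED = ("asthma", "copd")


@dataclass(frozen=True)
class Confusion3:
    """3x3 counts indexed (true class, predicted class) over (asthma, copd, healthy)."""

    counts: np.ndarray
    labels: tuple = LABELS

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3) or np.any(c < 0):
            raise ValueError("counts must be a non-negative 3x3 matrix")

    @property
    def total(self) -> int:
        return int(np.sum(self.counts))


@dataclass(frozen=True)
class Confusion2:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Diagnostic metrics as full-precision percentages.

    Fields with a zero denominator are ``None`` (undefined) rather than
    raising.  Use :func:`round2` / :meth:`rounded` for the conventional
    half-up two-decimal presentation.
    """

    accuracy: Optional[float]
    tpr: Optional[float]
    tnr: Optional[float]
    fpr: Optional[float]
    fnr: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    fdr: Optional[float]
    fomr: Optional[float]
    prevalence: Optional[float]
    per_class_accuracy: dict
    disease_sensitivity: Optional[float]

    def rounded(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "per_class_accuracy":
                out[f.name] = {k: round2(x) for k, x in v.items()}
            else:
                out[f.name] = round2(v)
        return out


def round2(x: Optional[float]) -> Optional[float]:
    """Half-up rounding to 2 decimals (the convention of printed clinical tables)."""
    if x is None:
        return None
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def confusion_3class(truth: Sequence[str], pred: Sequence[str]) -> Confusion3:
    """Exact tally of (true, predicted) label pairs."""
    if len(truth) != len(pred):
        raise ValueError(f"length mismatch: {len(truth)} truth vs {len(pred)} predictions")
    for name, seq in (("truth", truth), ("pred", pred)):
        bad = set(seq) - set(LABELS)
        if bad:
            raise ValueError(f"unknown label(s) in {name}: {sorted(bad)}")
    if len(truth) == 0:
        return Confusion3(counts=np.zeros((3, 3), dtype=int))
    c = _sk_confusion(list(truth), list(pred), labels=list(LABELS))
    return Confusion3(counts=c)


def collapse_binary(c3: Confusion3) -> Confusion2:
    """Diseased-vs-healthy collapse; disease cross-confusions stay test-positive."""
    c = np.asarray(c3.counts)
    idx = {lab: i for i, lab in enumerate(c3.labels)}
    d = [idx[lab] for lab in _DISEASED]
    h = idx["healthy"]
    tp = int(c[np.ix_(d, d)].sum())
    fn = int(c[d, h].sum())
    fp = int(c[h, d].sum())
    tn = int(c[h, h])
    return Confusion2(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio_pct(num: float, den: float) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(c3: Confusion3) -> MetricSet:
    """Binary metrics on the diseased-vs-healthy collapse, plus per-class
    accuracies from the 3x3 diagonal."""
    b = collapse_binary(c3)
    n = b.total
    per_class = {}
    c = np.asarray(c3.counts, dtype=float)
    for i, lab in enumerate(c3.labels):
        per_class[lab] = _ratio_pct(c[i, i], c[i].sum())
    diseased_correct = sum(
        c[i, i] for i, lab in enumerate(c3.labels) if lab in _DISEASED
    )
    diseased_total = sum(
        c[i].sum() for i, lab in enumerate(c3.labels) if lab in _DISEASED
    )
    return MetricSet(
        accuracy=_ratio_pct(b.tp + b.tn, n),
        tpr=_ratio_pct(b.tp, b.tp + b.fn),
        tnr=_ratio_pct(b.tn, b.tn + b.fp),
        fpr=_ratio_pct(b.fp, b.tn + b.fp),
        fnr=_ratio_pct(b.fn, b.tp + b.fn),
        ppv=_ratio_pct(b.tp, b.tp + b.fp),
        npv=_ratio_pct(b.tn, b.tn + b.fn),
        fdr=_ratio_pct(b.fp, b.tp + b.fp),
        fomr=_ratio_pct(b.fn, b.tn + b.fn),
        prevalence=_ratio_pct(b.tp + b.fn, n),
        per_class_accuracy=per_class,
        disease_sensitivity=_ratio_pct(diseased_correct, diseased_total),
    )


def format_report(c3: Confusion3) -> str:
    """Human-readable 3-class table plus the binary confusion layout."""
    m = compute_metrics(c3).rounded()
    b = collapse_binary(c3)
    c = np.asarray(c3.counts)

    def pct(v):
        return "undefined" if v is None else f"{v:.2f}%"

    lines = [f"Total population: {c3.total}", "",
             f"{'':>10} {'asthma':>8} {'copd':>8} {'healthy':>8} {'accuracy':>10}"]
    for i, lab in enumerate(c3.labels):
        lines.append(
            f"{lab:>10} {c[i, 0]:>8d} {c[i, 1]:>8d} {c[i, 2]:>8d} "
            f"{pct(m['per_class_accuracy'][lab]):>10}"
        )
    lines += [
        "",
        f"Binary (diseased vs healthy): tp={b.tp} fp={b.fp} fn={b.fn} tn={b.tn}",
        f"  accuracy {pct(m['accuracy'])}  prevalence {pct(m['prevalence'])}",
        f"  tpr {pct(m['tpr'])}  fnr {pct(m['fnr'])}  tnr {pct(m['tnr'])}  fpr {pct(m['fpr'])}",
        f"  ppv {pct(m['ppv'])}  fdr {pct(m['fdr'])}  npv {pct(m['npv'])}  fomr {pct(m['fomr'])}",
        f"  disease sensitivity (correct disease label) {pct(m['disease_sensitivity'])}",
    ]
    return "\n".join(lines)
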