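"""One-hidden-layer feed-forward classifier trained with Levenberg-Marquardt.

The network maps a 15-dimensional feature vector (fuzzy rule activations
plus scaled IOS/spirometry measurements and symptom flags) through a
tansig (hyperbolic tangent) hidden layer to three linear outputs, fitted
against one-hot class targets by sum-of-squared-error.  Training is
damped Gauss-Newton: solve (J'J + lambda*I) delta = -J'e on the full
Jacobian, accept only steps that reduce the SSE, and adapt the damping
multiplicatively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .fuzzy import (
    DEFAULT_BREAKPOINTS,
    FuzzyBreakpoints,
    PATTERN_LABELS,
    ObstructionPattern,
    evaluate_rules,
    fuzzify,
)
from .reports import PatientReport

CLASS_ORDER = ("asthma", "copd", "healthy")

FEATURE_NAMES = tuple(
    [f"activation_{lab}" for lab in PATTERN_LABELS]
    + [
        "r5_pct_pred_scaled",
        "r20_pct_pred_scaled",
        "reactance_deficit",
        "delta_r",
        "fev1_pct_pred_scaled",
        "fev1_fvc_ratio",
        "asthma_symptoms",
        "copd_history",
        "age_over_40",
    ]
)


def encode_features(report: PatientReport, pattern: ObstructionPattern) -> np.ndarray:
    """Deterministic fixed-order feature vector for one report.

    Percent-of-predicted values are divided by 100 so all features share a
    roughly unit scale; ``copd_history`` is the conjunction of COPD
    symptoms and exposure history.
    """
    ios, sp, sy = report.ios, report.spirometry, report.symptoms
    x = np.array(
        [pattern.activations[lab] for lab in PATTERN_LABELS]
        + [
            ios.r5_pct_pred / 100.0,
            ios.r20_pct_pred / 100.0,
            ios.reactance_deficit,
            ios.delta_r,
            sp.fev1_pct_pred / 100.0,
            sp.ratio,
            float(sy.asthma_symptoms),
            float(sy.copd_symptoms and sy.exposure_history),
            float(sy.age_years > 40),
        ],
        dtype=float,
    )
    if not np.all(np.isfinite(x)):
        raise ValueError("feature vector contains non-finite values")
    return x


def tansig(x):
    """Hyperbolic-tangent activation (MATLAB's ``tansig``)."""
    return np.tanh(x)


@dataclass
class NeuralNet:
    hidden_weights: np.ndarray   # (hidden_size, n_features)
    hidden_biases: np.ndarray    # (hidden_size,)
    output_weights: np.ndarray   # (3, hidden_size)
    output_biases: np.ndarray    # (3,)
    hidden_size: int
    class_order: tuple = CLASS_ORDER
    feature_names: tuple = FEATURE_NAMES

    def __post_init__(self) -> None:
        h, k = self.hidden_size, len(self.class_order)
        if self.hidden_weights.shape[0] != h or self.hidden_biases.shape != (h,):
            raise ValueError("hidden layer shapes inconsistent with hidden_size")
        if self.output_weights.shape != (k, h) or self.output_biases.shape != (k,):
            raise ValueError("output layer shapes inconsistent")
        for a in (self.hidden_weights, self.hidden_biases, self.output_weights, self.output_biases):
            if not np.all(np.isfinite(a)):
                raise ValueError("weights must be finite")

    def save(self, path) -> None:
        payload = {
            "hidden_size": self.hidden_size,
            "class_order": list(self.class_order),
            "feature_names": list(self.feature_names),
            "hidden_weights": self.hidden_weights.tolist(),
            "hidden_biases": self.hidden_biases.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_biases": self.output_biases.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "NeuralNet":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            hidden_weights=np.asarray(d["hidden_weights"], dtype=float),
            hidden_biases=np.asarray(d["hidden_biases"], dtype=float),
            output_weights=np.asarray(d["output_weights"], dtype=float),
            output_biases=np.asarray(d["output_biases"], dtype=float),
            hidden_size=int(d["hidden_size"]),
            class_order=tuple(d["class_order"]),
            feature_names=tuple(d["feature_names"]),
        )


@dataclass
class TrainingRecord:
    sse_per_iteration: list = field(default_factory=list)
    damping_per_iteration: list = field(default_factory=list)
    n_estimation: int = 0
    n_validation: int = 0
    seed: int = 0
    stop_reason: str = ""


@dataclass(frozen=True)
class LMConfig:
    """Levenberg-Marquardt controls: initial damping, x10 increase on a
    rejected step, /10 decrease on acceptance, hard damping cap, and the
    three stopping tolerances."""

    damping_init: float = 1e-3
    damping_up: float = 10.0
    damping_down: float = 10.0
    damping_cap: float = 1e10
    max_iter: int = 200
    grad_tol: float = 1e-8
    sse_tol: float = 1e-12


def forward(net: NeuralNet, x: np.ndarray) -> np.ndarray:
    """Linear readout of the tansig hidden layer; accepts a vector or a
    (n, n_features) matrix."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != net.hidden_weights.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match network input size "
            f"{net.hidden_weights.shape[1]}"
        )
    a = tansig(X @ net.hidden_weights.T + net.hidden_biases)
    y = a @ net.output_weights.T + net.output_biases
    return y[0] if single else y


def predict_class(net: NeuralNet, x: np.ndarray) -> str:
    """Argmax label; ties break toward the earliest class in class_order."""
    y = forward(net, x)
    return net.class_order[int(np.argmax(y))]


def split_estimation_validation(
    labels: Sequence[str], fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified index split of round(n*fraction) records to estimation.

    Per-class estimation counts are allocated by largest remainder so the
    overall estimation size equals round(n*fraction) exactly while staying
    proportional within classes.  Returns (estimation_idx, validation_idx);
    disjoint, exhaustive, and reproducible for a given seed.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty data")
    classes = sorted(set(labels.tolist()))
    sizes = {c: int(np.sum(labels == c)) for c in classes}
    for c, n_c in sizes.items():
        if n_c < 2:
            raise ValueError(f"class {c!r} has fewer than 2 members; cannot stratify")
    total_est = int(np.floor(labels.size * fraction + 0.5))
    total_est = min(max(total_est, len(classes)), labels.size - len(classes))
    quota = {c: sizes[c] * fraction for c in classes}
    alloc = {c: min(max(int(np.floor(quota[c])), 1), sizes[c] - 1) for c in classes}
    # hand out the remaining slots by largest fractional remainder
    by_remainder = sorted(classes, key=lambda c: (-(quota[c] - np.floor(quota[c])), c))
    i = 0
    while sum(alloc.values()) < total_est:
        c = by_remainder[i % len(classes)]
        if alloc[c] < sizes[c] - 1:
            alloc[c] += 1
        i += 1
    rng = np.random.default_rng(seed)
    est, val = [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        perm = rng.permutation(idx)
        est.append(perm[: alloc[c]])
        val.append(perm[alloc[c]:])
    return np.sort(np.concatenate(est)), np.sort(np.concatenate(val))


def one_hot(labels: Sequence[str], class_order: tuple = CLASS_ORDER) -> np.ndarray:
    T = np.zeros((len(labels), len(class_order)))
    pos = {c: i for i, c in enumerate(class_order)}
    for i, lab in enumerate(labels):
        T[i, pos[lab]] = 1.0
    return T


# ---------------------------------------------------------------------------
# Levenberg-Marquardt core (generic residual minimizer)

def levenberg_marquardt(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    jacobian_fn: Callable[[np.ndarray], np.ndarray],
    theta0: np.ndarray,
    config: LMConfig = LMConfig(),
) -> tuple[np.ndarray, TrainingRecord]:
    """Minimize ||r(theta)||^2 by damped Gauss-Newton.

    Accepted steps never increase the SSE; the damping grows by
    ``damping_up`` on each rejected step until the cap, which ends the run.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    lam = config.damping_init
    r = residual_fn(theta)
    sse = float(r @ r)
    rec = TrainingRecord(sse_per_iteration=[sse], damping_per_iteration=[lam])
    for _ in range(config.max_iter):
        if sse < config.sse_tol:
            rec.stop_reason = "sse_tol"
            break
        J = jacobian_fn(theta)
        g = J.T @ r
        if np.max(np.abs(g)) < config.grad_tol:
            rec.stop_reason = "grad_tol"
            break
        JtJ = J.T @ J
        eye = np.eye(theta.size)
        accepted = False
        while lam <= config.damping_cap:
            try:
                delta = np.linalg.solve(JtJ + lam * eye, -g)
            except np.linalg.LinAlgError:
                lam *= config.damping_up
                continue
            trial = theta + delta
            r_trial = residual_fn(trial)
            sse_trial = float(r_trial @ r_trial)
            if np.isfinite(sse_trial) and sse_trial <= sse:
                theta, r, sse = trial, r_trial, sse_trial
                lam = max(lam / config.damping_down, 1e-15)
                accepted = True
                break
            lam *= config.damping_up
        if not accepted:
            rec.stop_reason = "damping_cap"
            break
        rec.sse_per_iteration.append(sse)
        rec.damping_per_iteration.append(lam)
    else:
        rec.stop_reason = "max_iter"
    return theta, rec


# ---------------------------------------------------------------------------
# network-specific wrapper

def _pack(W1, b1, W2, b2):
    return np.concatenate([W1.ravel(), b1, W2.ravel(), b2])


def _unpack(theta, h, n_in, k):
    i = 0
    W1 = theta[i:i + h * n_in].reshape(h, n_in); i += h * n_in
    b1 = theta[i:i + h]; i += h
    W2 = theta[i:i + k * h].reshape(k, h); i += k * h
    b2 = theta[i:i + k]
    return W1, b1, W2, b2


def _net_jacobian(theta, X, h, k):
    """Analytic Jacobian of the residuals (y - t) w.r.t. all parameters.

    Residual index runs over (sample, output); columns follow the pack
    order W1, b1, W2, b2.
    """
    n, n_in = X.shape
    W1, b1, W2, b2 = _unpack(theta, h, n_in, k)
    A = np.tanh(X @ W1.T + b1)          # (n, h)
    D = 1.0 - A * A                     # tanh' at the hidden pre-activation
    WD = np.einsum("kj,nj->nkj", W2, D)             # (n, k, h)
    J_W1 = np.einsum("nkj,ni->nkji", WD, X).reshape(n * k, h * n_in)
    J_b1 = WD.reshape(n * k, h)
    J_W2 = np.einsum("kl,nj->nklj", np.eye(k), A).reshape(n * k, k * h)
    J_b2 = np.tile(np.eye(k), (n, 1))
    return np.hstack([J_W1, J_b1, J_W2, J_b2])


def train_lm(
    X: np.ndarray,
    labels: Sequence[str],
    hidden_size: int = 10,
    seed: int = 0,
    config: LMConfig = LMConfig(),
    class_order: tuple = CLASS_ORDER,
    feature_names: Optional[tuple] = None,
) -> tuple[NeuralNet, TrainingRecord]:
    """Fit the network to one-hot targets by Levenberg-Marquardt.

    Weights are initialized uniformly in [-0.5, 0.5] from a generator
    seeded with ``seed``; two runs with identical inputs and seed produce
    identical weight trajectories.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty (n, n_features) matrix")
    unknown = set(labels) - set(class_order)
    if unknown:
        raise ValueError(f"unknown label(s): {sorted(unknown)}")
    T = one_hot(list(labels), class_order)
    n, n_in = X.shape
    k = len(class_order)
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(-0.5, 0.5, size=hidden_size * n_in + hidden_size + k * hidden_size + k)

    def residual_fn(theta):
        W1, b1, W2, b2 = _unpack(theta, hidden_size, n_in, k)
        Y = np.tanh(X @ W1.T + b1) @ W2.T + b2
        return (Y - T).ravel()

    def jacobian_fn(theta):
        return _net_jacobian(theta, X, hidden_size, k)

    theta, rec = levenberg_marquardt(residual_fn, jacobian_fn, theta0, config)
    rec.seed = seed
    rec.n_estimation = n
    W1, b1, W2, b2 = _unpack(theta, hidden_size, n_in, k)
    if feature_names is not None:
        names = tuple(feature_names)
    elif n_in == len(FEATURE_NAMES):
        names = FEATURE_NAMES
    else:
        names = tuple(f"f{i}" for i in range(n_in))
    net = NeuralNet(
        hidden_weights=W1.copy(),
        hidden_biases=b1.copy(),
        output_weights=W2.copy(),
        output_biases=b2.copy(),
        hidden_size=hidden_size,
        class_order=class_order,
        feature_names=names,
    )
    return net, rec


def featurize_cohort(
    reports: Sequence[PatientReport], bp: FuzzyBreakpoints = DEFAULT_BREAKPOINTS
) -> tuple[np.ndarray, list]:
    """Feature matrix and true-label list for a labelled cohort."""
    X = np.empty((len(reports), len(FEATURE_NAMES)))
    labels = []
    for i, r in enumerate(reports):
        if r.true_label is None:
            raise ValueError(f"report {r.patient_id!r} has no true_label; cannot train on it")
        pattern = evaluate_rules(fuzzify(r.ios, bp))
        X[i] = encode_features(r, pattern)
        labels.append(r.true_label)
    return X, labels


def accuracy(net: NeuralNet, X: np.ndarray, labels: Sequence[str]) -> float:
    """Fraction of records whose argmax output matches the label."""
    Y = forward(net, np.asarray(X, dtype=float))
    pred = np.argmax(Y, axis=1)
    pos = {c: i for i, c in enumerate(net.class_order)}
    truth = np.array([pos[l] for l in labels])
    return float(np.mean(pred == truth))
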