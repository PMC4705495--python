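"""Feed-forward net, feature encoding, and the Levenberg-Marquardt trainer."""

import numpy as np
import pytest

from airwaydx.cohort import GeneratorParams, generate_cohort
from airwaydx.fuzzy import evaluate_rules, fuzzify
from airwaydx.network import (
    CLASS_ORDER,
    FEATURE_NAMES,
    LMConfig,
    NeuralNet,
    accuracy,
    encode_features,
    featurize_cohort,
    forward,
    levenberg_marquardt,
    one_hot,
    predict_class,
    split_estimation_validation,
    tansig,
    train_lm,
)
from conftest import make_ios, make_report, make_spiro

APPROX = pytest.approx


def test_tansig_is_tanh():
    xs = np.linspace(-5, 5, 21)
    assert np.allclose(tansig(xs), np.tanh(xs))
    assert tansig(0.0) == 0.0
    assert np.allclose(tansig(-xs), -tansig(xs))
    assert tansig(20.0) == APPROX(1.0, abs=1e-12)


def test_encode_features_deterministic_and_ordered():
    r = make_report(spirometry=make_spiro(fev1=2.0, fvc=4.0), ios=make_ios(r20=0.35))
    pattern = evaluate_rules(fuzzify(r.ios))
    x1 = encode_features(r, pattern)
    x2 = encode_features(r, pattern)
    assert np.array_equal(x1, x2)
    assert len(x1) == len(FEATURE_NAMES) == 15
    assert x1[FEATURE_NAMES.index("fev1_fvc_ratio")] == 0.5
    # crisp-normal report: first pattern activation (NSCO-SV) is 1
    assert x1[0] == 1.0


def _zero_net(n_in=2, hidden=1):
    return NeuralNet(
        hidden_weights=np.zeros((hidden, n_in)),
        hidden_biases=np.zeros(hidden),
        output_weights=np.zeros((3, hidden)),
        output_biases=np.zeros(3),
        hidden_size=hidden,
    )


def test_forward_zero_net_and_bias_passthrough():
    net = _zero_net()
    assert np.array_equal(forward(net, np.zeros(2)), np.zeros(3))
    net.output_biases = np.array([1.0, 2.0, 3.0])
    for x in (np.zeros(2), np.array([5.0, -7.0])):
        assert np.array_equal(forward(net, x), [1.0, 2.0, 3.0])


def test_forward_hand_sized_net():
    # 2 inputs, 1 hidden unit, unit weights: at x=(0,0) tanh(0)=0 so outputs = biases
    net = NeuralNet(
        hidden_weights=np.ones((1, 2)),
        hidden_biases=np.zeros(1),
        output_weights=np.ones((3, 1)),
        output_biases=np.array([0.1, 0.2, 0.3]),
        hidden_size=1,
    )
    assert np.allclose(forward(net, np.zeros(2)), [0.1, 0.2, 0.3])
    # at x=(1,1): tanh(2) through unit output weights plus bias
    assert np.allclose(forward(net, np.ones(2)), np.tanh(2.0) + np.array([0.1, 0.2, 0.3]))


def test_forward_dimension_mismatch():
    with pytest.raises(ValueError):
        forward(_zero_net(n_in=2), np.zeros(5))


def test_predict_class_argmax_and_ties():
    net = _zero_net()
    net.output_biases = np.array([0.9, 0.1, 0.0])
    assert predict_class(net, np.zeros(2)) == "asthma"
    net.output_biases = np.array([0.4, 0.4, 0.1])
    assert predict_class(net, np.zeros(2)) == "asthma"  # tie-break by class order
    net.output_biases = np.zeros(3)
    assert predict_class(net, np.zeros(2)) == "asthma"


def test_split_sizes_stratified():
    labels = ["asthma"] * 500 + ["copd"] * 400 + ["healthy"] * 100
    est, val = split_estimation_validation(labels, 0.8, seed=4)
    assert len(est) == 800 and len(val) == 200
    arr = np.array(labels)
    assert np.sum(arr[est] == "asthma") == 400
    assert np.sum(arr[est] == "healthy") == 80
    assert len(set(est) & set(val)) == 0
    assert len(set(est) | set(val)) == 1000


def test_split_deterministic_given_seed():
    labels = ["asthma"] * 6 + ["copd"] * 6 + ["healthy"] * 4
    a = split_estimation_validation(labels, 0.5, seed=9)
    b = split_estimation_validation(labels, 0.5, seed=9)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
    c = split_estimation_validation(labels, 0.5, seed=10)
    assert not (np.array_equal(a[0], c[0]) and np.array_equal(a[1], c[1]))


def test_split_half_on_ten():
    labels = ["asthma"] * 5 + ["copd"] * 5
    est, val = split_estimation_validation(labels, 0.5, seed=0)
    assert len(est) == 5 and len(val) == 5


def test_split_rejects_singleton_class():
    with pytest.raises(ValueError, match="healthy"):
        split_estimation_validation(["asthma", "asthma", "healthy"], 0.5, seed=0)


def test_lm_matches_linear_least_squares():
    """On a purely linear residual the damped Gauss-Newton solution equals
    the closed-form least-squares fit."""
    rng = np.random.default_rng(2)
    A = rng.normal(size=(40, 5))
    b = rng.normal(size=40)
    theta, rec = levenberg_marquardt(
        residual_fn=lambda t: A @ t - b,
        jacobian_fn=lambda t: A,
        theta0=np.zeros(5),
    )
    expected, *_ = np.linalg.lstsq(A, b, rcond=None)
    assert np.allclose(theta, expected, atol=1e-6)
    assert rec.sse_per_iteration[-1] <= rec.sse_per_iteration[0]


def test_lm_sse_monotone_non_increasing():
    X, labels = _toy_separable()
    _, rec = train_lm(X, labels, hidden_size=4, seed=1)
    sse = rec.sse_per_iteration
    assert all(b <= a + 1e-12 for a, b in zip(sse, sse[1:]))
    assert all(d > 0 for d in rec.damping_per_iteration)


def _toy_separable(n_per=10, seed=0):
    rng = np.random.default_rng(seed)
    centers = {"asthma": (2, 0), "copd": (-2, 0), "healthy": (0, 2)}
    X, labels = [], []
    for lab, (cx, cy) in centers.items():
        X.append(rng.normal(loc=(cx, cy), scale=0.3, size=(n_per, 2)))
        labels += [lab] * n_per
    return np.vstack(X), labels


def test_lm_learns_separable_toy_problem():
    X, labels = _toy_separable()
    net, rec = train_lm(X, labels, hidden_size=4, seed=3, config=LMConfig(max_iter=50))
    assert accuracy(net, X, labels) == 1.0
    # cross-check against an independent optimizer on the same objective
    from scipy.optimize import least_squares

    T = one_hot(labels)

    def resid(theta):
        h, n_in, k = 4, 2, 3
        i = 0
        W1 = theta[:h * n_in].reshape(h, n_in); i = h * n_in
        b1 = theta[i:i + h]; i += h
        W2 = theta[i:i + k * h].reshape(k, h); i += k * h
        b2 = theta[i:]
        return ((np.tanh(X @ W1.T + b1) @ W2.T + b2) - T).ravel()

    rng = np.random.default_rng(3)
    theta0 = rng.uniform(-0.5, 0.5, size=4 * 2 + 4 + 3 * 4 + 3)
    ref = least_squares(resid, theta0, method="lm", max_nfev=20000)
    assert rec.sse_per_iteration[-1] <= 2 * ref.cost + 1e-3  # cost = SSE/2


def test_lm_single_class_constant_fit():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(12, 3))
    net, rec = train_lm(X, ["copd"] * 12, hidden_size=2, seed=5)
    assert rec.sse_per_iteration[-1] < 1e-6
    assert all(b <= a + 1e-12 for a, b in zip(rec.sse_per_iteration, rec.sse_per_iteration[1:]))


def test_lm_deterministic_given_seed():
    X, labels = _toy_separable()
    n1, r1 = train_lm(X, labels, hidden_size=3, seed=7)
    n2, r2 = train_lm(X, labels, hidden_size=3, seed=7)
    assert np.array_equal(n1.hidden_weights, n2.hidden_weights)
    assert np.array_equal(n1.output_biases, n2.output_biases)
    assert r1.sse_per_iteration == r2.sse_per_iteration


def test_lm_jacobian_matches_finite_differences():
    from airwaydx.network import _net_jacobian

    rng = np.random.default_rng(8)
    X = rng.normal(size=(5, 3))
    h, k = 2, 3
    p = h * 3 + h + k * h + k
    theta = rng.normal(size=p) * 0.5

    def resid(t):
        from airwaydx.network import _unpack

        W1, b1, W2, b2 = _unpack(t, h, 3, k)
        return ((np.tanh(X @ W1.T + b1) @ W2.T + b2)).ravel()

    J = _net_jacobian(theta, X, h, k)
    eps = 1e-6
    J_fd = np.empty_like(J)
    for j in range(p):
        e = np.zeros(p)
        e[j] = eps
        J_fd[:, j] = (resid(theta + e) - resid(theta - e)) / (2 * eps)
    assert np.allclose(J, J_fd, atol=1e-5)


def test_model_serialization_round_trip(tmp_path):
    X, labels = _toy_separable()
    net, _ = train_lm(X, labels, hidden_size=3, seed=2)
    path = tmp_path / "model.json"
    net.save(path)
    loaded = NeuralNet.load(path)
    probe = np.linspace(-1, 1, 2)
    assert np.array_equal(forward(net, probe), forward(loaded, probe))
    assert loaded.class_order == CLASS_ORDER


def test_noise_free_cohort_reaches_high_validation_accuracy():
    """Labels are a deterministic function of the features at zero noise,
    so a trained net recovers them nearly perfectly."""
    params = GeneratorParams(n_asthma=60, n_copd=60, n_healthy=30, seed=13, noise_scale=0.0)
    cohort = generate_cohort(params)
    X, labels = featurize_cohort(cohort)
    est, val = split_estimation_validation(labels, 0.8, seed=13)
    net, _ = train_lm(X[est], [labels[i] for i in est], hidden_size=10, seed=13)
    assert accuracy(net, X[val], [labels[i] for i in val]) >= 0.99
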