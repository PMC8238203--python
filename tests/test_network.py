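"""SCG pattern network: loss/gradient, training behaviour, CV output."""

import numpy as np
import pytest

import netsnp as ns
from netsnp.network import _flatten, _init_params, loss_and_gradient


def _random_net(rng, sizes):
    return _flatten(_init_params(sizes, rng))


def _fd_gradient(w, sizes, x, t, reg, step=1e-6):
    num = np.zeros_like(w)
    for i in range(w.size):
        e = np.zeros_like(w)
        e[i] = step
        fp, _ = loss_and_gradient(w + e, sizes, x, t, reg)
        fm, _ = loss_and_gradient(w - e, sizes, x, t, reg)
        num[i] = (fp - fm) / (2 * step)
    return num


def test_zero_weights_give_ln2_cross_entropy():
    sizes = (3, 4, 2)
    w = np.zeros(3 * 4 + 4 + 4 * 2 + 2)
    x = np.random.default_rng(0).normal(size=(10, 3))
    t = np.eye(2)[np.array([0, 1] * 5)]
    perf, _ = loss_and_gradient(w, sizes, x, t, reg=0.1)
    # penalty term vanishes; CE is ln 2 per sample; ratio scales it by 0.9
    assert perf == pytest.approx(0.9 * np.log(2), rel=1e-12)
    perf0, _ = loss_and_gradient(w, sizes, x, t, reg=0.0)
    assert perf0 == pytest.approx(np.log(2), rel=1e-12)


@pytest.mark.parametrize("sizes", [(4, 5, 2), (3, 6, 4, 2), (5, 4, 3)])
def test_gradient_matches_finite_differences(sizes):
    rng = np.random.default_rng(17)
    w = _random_net(rng, sizes)
    x = rng.normal(size=(15, sizes[0]))
    t = np.eye(sizes[-1])[rng.integers(0, sizes[-1], 15)]
    _, g = loss_and_gradient(w, sizes, x, t, reg=0.1)
    num = _fd_gradient(w, sizes, x, t, 0.1)
    rel = np.max(np.abs(g - num)) / max(np.max(np.abs(num)), 1e-8)
    assert rel < 1e-5


def _blobs(rng, n=200, sep=3.0):
    x = np.vstack([rng.normal(size=(n, 2)) - sep, rng.normal(size=(n, 2)) + sep])
    y = np.r_[np.zeros(n, int), np.ones(n, int)]
    p = rng.permutation(2 * n)
    return x[p], y[p]


def test_separable_blobs_reach_perfect_accuracy():
    rng = np.random.default_rng(2)
    x, y = _blobs(rng)
    cfg = ns.NetConfig(hidden_layers=(10, 5), max_epochs=300, seed=3)
    net = ns.train_patternnet(x[:300], y[:300], x[300:], y[300:], cfg)
    cv = net.predict_cv(x[300:])
    assert np.mean((cv > 0).astype(int) == y[300:]) == 1.0


def test_permuted_labels_give_chance_accuracy():
    rng = np.random.default_rng(4)
    x, y = _blobs(rng, n=250)
    y = rng.permutation(y)
    cfg = ns.NetConfig(hidden_layers=(10, 5), max_epochs=150, seed=5)
    net = ns.train_patternnet(x[:400], y[:400], x[400:450], y[400:450], cfg)
    cv = net.predict_cv(x[450:])
    acc = np.mean((cv > 0).astype(int) == y[450:])
    sd = np.sqrt(0.25 / 50)
    assert abs(acc - 0.5) < 3 * sd


def test_training_loss_mostly_non_increasing():
    rng = np.random.default_rng(6)
    x, y = _blobs(rng, n=150, sep=1.5)
    cfg = ns.NetConfig(hidden_layers=(8,), max_epochs=120, seed=7)
    net = ns.train_patternnet(x[:200], y[:200], x[200:250], y[200:250], cfg)
    losses = [h[1] for h in net.history]
    drops = sum(1 for a, b in zip(losses, losses[1:]) if b <= a + 1e-12)
    assert drops / (len(losses) - 1) >= 0.95


def test_disabled_early_stopping_runs_exactly_max_epochs():
    rng = np.random.default_rng(8)
    x, y = _blobs(rng, n=60, sep=1.0)
    cfg = ns.NetConfig(hidden_layers=(6,), max_epochs=40, min_grad=0.0,
                       max_fails=0, seed=9)
    net = ns.train_patternnet(x, y, None, None, cfg)
    assert len(net.history) - 1 == 40
    assert net.stop_reason == "max_epochs"


def test_training_is_deterministic_given_seed():
    rng = np.random.default_rng(10)
    x, y = _blobs(rng, n=80)
    cfg = ns.NetConfig(hidden_layers=(6,), max_epochs=60, seed=11)
    n1 = ns.train_patternnet(x[:120], y[:120], x[120:], y[120:], cfg)
    n2 = ns.train_patternnet(x[:120], y[:120], x[120:], y[120:], cfg)
    assert np.array_equal(n1.flat_weights, n2.flat_weights)


def test_validation_required_when_max_fails_active():
    rng = np.random.default_rng(12)
    x, y = _blobs(rng, n=40)
    cfg = ns.NetConfig(hidden_layers=(4,), max_epochs=10, seed=0)
    with pytest.raises(ValueError, match="validation"):
        ns.train_patternnet(x, y, None, None, cfg)


def test_single_class_labels_rejected():
    cfg = ns.NetConfig(hidden_layers=(4,), max_epochs=10, max_fails=0, seed=0)
    x = np.zeros((10, 2))
    with pytest.raises(ValueError, match="2 classes"):
        ns.train_patternnet(x, np.zeros(10, int), None, None, cfg)


def test_cv_definition_and_immutability():
    rng = np.random.default_rng(13)
    x, y = _blobs(rng, n=60)
    cfg = ns.NetConfig(hidden_layers=(5,), max_epochs=50, seed=14)
    net = ns.train_patternnet(x[:90], y[:90], x[90:], y[90:], cfg)
    cv = net.predict_cv(x)
    assert np.all((cv >= -0.5) & (cv <= 0.5))
    assert np.allclose(net.predict_proba_case(x) - cv, 0.5)   # differ by exactly 0.5
    assert np.array_equal(cv, net.predict_cv(x))              # bit-identical reapply
    with pytest.raises(ValueError, match="mismatch"):
        net.predict_cv(x[:, :1])
    with pytest.raises(ValueError):
        net.flat_weights[0] = 99.0                            # weights frozen


def test_feature_scaling_min_max_map_and_clip():
    x = np.array([[0.0, 0.0, 5.0], [1.0, 0.0, 6.0], [2.0, 0.0, 7.0]])
    sc = ns.FeatureScaling.fit(x)
    out = sc.apply(x)
    assert np.allclose(out[:, 0], [-1, 0, 1])
    assert np.allclose(out[:, 1], 0.0)            # constant feature -> 0
    clipped = sc.apply(np.array([[9.0, 0.0, 4.0]]))
    assert clipped[0, 0] == 1.0 and clipped[0, 2] == -1.0


def test_build_feature_matrix_scales_codes(small_cohort):
    store, _, _ = small_cohort
    x, scaling = ns.build_feature_matrix(store, list(range(50)), [0, 1, 2])
    assert x.min() >= -1 and x.max() <= 1
    with pytest.raises(ValueError):
        ns.build_feature_matrix(store, [], [0])


def test_kclass_softmax_head():
    rng = np.random.default_rng(15)
    centers = np.array([[-4, 0], [4, 0], [0, 4]])
    x = np.vstack([rng.normal(size=(60, 2)) + c for c in centers])
    y = np.repeat([0, 1, 2], 60)
    p = rng.permutation(180)
    x, y = x[p], y[p]
    cfg = ns.NetConfig(hidden_layers=(8,), max_epochs=200, seed=16)
    net = ns.train_patternnet(x[:140], y[:140], x[140:], y[140:], cfg)
    proba = net.probabilities(x[140:])
    assert proba.shape == (40, 3)
    assert np.allclose(proba.sum(axis=1), 1.0)
    assert np.mean(proba.argmax(axis=1) == y[140:]) > 0.9
    with pytest.raises(ValueError):
        net.predict_cv(x[140:])   # CV undefined for a 3-class head


def test_trained_net_json_round_trip(tmp_path):
    rng = np.random.default_rng(18)
    x, y = _blobs(rng, n=40)
    cfg = ns.NetConfig(hidden_layers=(4,), max_epochs=30, seed=19)
    net = ns.train_patternnet(x[:60], y[:60], x[60:], y[60:], cfg)
    path = tmp_path / "net.json"
    net.to_json(path)
    loaded = ns.TrainedNet.from_json(path)
    assert np.array_equal(loaded.flat_weights, net.flat_weights)
    assert np.array_equal(loaded.predict_cv(x), net.predict_cv(x))
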