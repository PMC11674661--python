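"""The five architectures: declared structure, simplex outputs, parameter
counts, and the shared fit/predict contract."""

import numpy as np
import pytest

from mieeg import models


@pytest.fixture(scope="module")
def rng_mod():
    return np.random.default_rng(1)


def _forward_simplex(spec, rng, n=3):
    net = spec.build(seed=0)
    x = rng.standard_normal((n, *spec.input_shape)).astype(np.float32)
    p = net.predict_proba(x)
    assert p.shape == (n, spec.n_classes)
    assert (p >= 0).all()
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
    return net, x, p


# ---------------------------------------------------------------------------
# conv2d net

def test_conv2d_net_structure():
    spec = models.build_conv2d_net(T=64)
    convs = spec.conv_layers()
    assert len(convs) == 3
    assert [c["kernels"] for c in convs] == [32, 64, 128]
    assert convs[0]["kernel_shape"] == (3, 3, 64)
    assert convs[0]["collapses_time"]          # time axis summed in layer 1
    dense = [d for k, d in spec.layer_summary if k == "dense"]
    assert [d["units"] for d in dense] == [1024, 64]


def test_conv2d_net_forward_simplex(rng_mod):
    spec = models.build_conv2d_net(T=40)
    _forward_simplex(spec, rng_mod)


def test_conv2d_net_rejects_wrong_shape(rng_mod):
    spec = models.build_conv2d_net(T=40)
    m = models.fit(spec, rng_mod.standard_normal((8, 9, 7, 40)),
                   np.array(["a", "b"] * 4), epochs=1)
    with pytest.raises(ValueError):
        m.predict_proba(rng_mod.standard_normal((2, 8, 7, 40)))


# ---------------------------------------------------------------------------
# conv3d net

def test_conv3d_net_structure_and_param_count(rng_mod):
    spec = models.build_conv3d_net(T=120)
    convs = spec.conv_layers()
    assert [c["kernel_shape"] for c in convs] == [(1, 1, 30), (2, 2, 40), (2, 2, 40)]
    assert all(c["kernels"] == 32 for c in convs)

    net = spec.build(seed=0)
    # closed-form parameter count from the declared shapes
    t_out = 120 - 29 - 39 - 39
    expected = (
        (1 * 1 * 30 * 1 * 32 + 32) + 2 * 32 +      # conv1 + batchnorm
        (2 * 2 * 40 * 32 * 32 + 32) + 2 * 32 +
        (2 * 2 * 40 * 32 * 32 + 32) + 2 * 32 +
        (9 * 7 * t_out * 32 * 32 + 32) +
        (32 * 32 + 32) +
        (32 * 4 + 4)
    )
    assert net.n_parameters() == expected


def test_conv3d_net_forward_simplex(rng_mod):
    spec = models.build_conv3d_net(T=112)
    _forward_simplex(spec, rng_mod, n=2)


def test_conv3d_net_rejects_short_time_axis():
    with pytest.raises(ValueError):
        models.build_conv3d_net(T=100)


# ---------------------------------------------------------------------------
# multi-branch conv3d

def test_mb_conv3d_structure():
    spec = models.build_mb_conv3d(T=120)
    branches = [d for k, d in spec.layer_summary if k == "branch"]
    assert len(branches) == 3
    for b in branches:
        assert len(b["conv_layers"]) == 2
        assert len(b["dense_layers"]) == 3
        assert b["dense_layers"][-1] == spec.n_classes


def test_mb_conv3d_forward_simplex(rng_mod):
    spec = models.build_mb_conv3d(T=112)
    _forward_simplex(spec, rng_mod, n=2)


def test_mb_conv3d_zeroed_branches_reduce_to_single_branch(rng_mod):
    """Additive fusion: silencing two branches leaves softmax(branch_k)."""
    from mieeg import nn

    spec = models.build_mb_conv3d(T=112)
    net = spec.build(seed=0)
    parallel = net.root.layers[-1]
    assert isinstance(parallel, nn.ParallelSum)
    for br in parallel.branches[1:]:
        for p in br.params:
            p[...] = 0.0
    x = rng_mod.standard_normal((2, 9, 7, 112)).astype(np.float32)
    full = net.predict_proba(x)
    pre = net.root.layers[0].forward(x.astype(nn.F))
    pre = net.root.layers[1].forward(pre)
    single = nn.softmax(parallel.branches[0].forward(pre).astype(np.float64))
    assert np.allclose(full, single, atol=1e-6)


# ---------------------------------------------------------------------------
# eegnet

def test_eegnet_first_kernel_is_half_sampling_rate():
    spec = models.build_eegnet(fs=160.0, n_channels=64, T=320)
    first = spec.layer_summary[0][1]
    assert first["kernel_shape"] == (1, round(160 / 2))


def test_eegnet_depthwise_contract():
    spec = models.build_eegnet(fs=160.0, n_channels=64, T=320)
    dw = dict(spec.layer_summary)["depthwise_conv2d"]
    assert dw["kernel_shape"] == (64, 1)
    assert dw["depth_multiplier"] == 2
    assert dw["groups_per_temporal_filter"] == 1


def test_eegnet_forward_simplex(rng_mod):
    spec = models.build_eegnet(fs=160.0, n_channels=16, T=128)
    _forward_simplex(spec, rng_mod)


# ---------------------------------------------------------------------------
# shallow convnet

def test_shallow_layer_sequence():
    spec = models.build_shallow_convnet(n_channels=64, T=320)
    kinds = [k for k, _ in spec.layer_summary]
    assert kinds == ["conv2d", "conv2d", "square", "mean_pool", "log",
                     "dense_softmax"]
    assert dict(spec.layer_summary)["mean_pool"] == {"length": 75, "stride": 15}


def test_shallow_forward_simplex(rng_mod):
    spec = models.build_shallow_convnet(n_channels=16, T=160)
    _forward_simplex(spec, rng_mod)


def test_shallow_zero_input_gives_bias_logits(rng_mod):
    """On all-zero input the pre-softmax activations equal the dense bias
    (the log nonlinearity maps the zero band-power to a constant that the
    dense layer turns into bias + constant-column sums)."""
    spec = models.build_shallow_convnet(n_channels=8, T=120,
                                        pool_time_length=30, pool_time_stride=15)
    net = spec.build(seed=0)
    x = np.zeros((2, 8, 120), dtype=np.float32)
    p = net.predict_proba(x)
    assert np.allclose(p[0], p[1], atol=1e-7)   # no input-driven variation


# ---------------------------------------------------------------------------
# fit / predict contract

def _separable_toy(rng, n=80, shape=(6, 32), n_classes=4):
    """Linearly separable by construction: class k lights up channel k."""
    x = 0.05 * rng.standard_normal((n, *shape))
    y = np.array([f"class_{i % n_classes}" for i in range(n)])
    for i in range(n):
        x[i, i % n_classes, :] += 1.0
    return x.astype(np.float32), y


def _separable_dense_toy(rng, n=48, T=40, n_classes=4):
    """Dense-3D analogue: class k lights up one grid cell."""
    x = 0.05 * rng.standard_normal((n, 9, 7, T))
    y = np.array([f"class_{i % n_classes}" for i in range(n)])
    cells = [(2, 2), (2, 4), (6, 2), (6, 4)]
    for i in range(n):
        r, c = cells[i % n_classes]
        x[i, r, c, :] += 1.0
    return x.astype(np.float32), y


@pytest.mark.parametrize("name,hp,dense_input", [
    ("conv2d_net", dict(kernels=(8, 8, 8), dense=(32, 16)), True),
    ("conv3d_net", dict(kernels=8, kernel_shapes=((1, 1, 8), (2, 2, 10), (2, 2, 10)),
                        dense=(16, 16)), True),
    ("mb_conv3d", dict(branches=(
        {"kernels": 4, "kernel_shapes": ((1, 1, 4), (2, 2, 6)), "dense": (16, 8)},
        {"kernels": 4, "kernel_shapes": ((1, 1, 8), (2, 2, 10)), "dense": (16, 8)},
        {"kernels": 4, "kernel_shapes": ((1, 1, 12), (2, 2, 14)), "dense": (16, 8)},
    )), True),
    ("eegnet", dict(F1=4, D=1, F2=4, dropout=0.0, sep_kernel=4), False),
    ("shallow_convnet", dict(n_filters_time=4, n_filters_spat=4,
                             filter_time_length=5, pool_time_length=14,
                             pool_time_stride=7, dropout=0.0), False),
])
def test_every_architecture_learns_separable_toy(name, hp, dense_input, rng_mod):
    """All five networks fit a linearly separable 4-class fixture to >=95%
    training accuracy within 50 epochs."""
    if dense_input:
        x, y = _separable_dense_toy(rng_mod)
        spec = models.build_model(name, T=40, **hp)
    else:
        x, y = _separable_toy(rng_mod, n=48, shape=(6, 40))
        spec = models.build_model(name, T=40, fs=32, n_channels=6, **hp)
    m = models.fit(spec, x, y, epochs=50, batch_size=16, seed=0)
    assert m.accuracy(x, y) >= 0.95


def test_fit_reaches_high_accuracy_on_separable_toy(rng_mod):
    x, y = _separable_toy(rng_mod)
    spec = models.build_shallow_convnet(
        n_channels=6, T=32, n_filters_time=4, n_filters_spat=4,
        filter_time_length=5, pool_time_length=14, pool_time_stride=7,
        dropout=0.0)
    m = models.fit(spec, x, y, epochs=50, batch_size=16, seed=0)
    assert m.accuracy(x, y) >= 0.95


def test_fit_records_history_and_patience(rng_mod):
    x, y = _separable_toy(rng_mod, n=60)
    spec = models.build_eegnet(fs=32, n_channels=6, T=32, F1=2, D=1, F2=2,
                               dropout=0.0, sep_kernel=4)
    xv, yv = _separable_toy(np.random.default_rng(99), n=20)
    m = models.fit(spec, x, y, val=(xv, yv), epochs=60, patience=10, seed=1)
    assert len(m.history["loss"]) <= 60
    assert len(m.history["val_loss"]) == len(m.history["loss"])


def test_fixed_seed_reproduces_first_epoch_loss(rng_mod):
    x, y = _separable_toy(rng_mod, n=40)
    spec = models.build_shallow_convnet(
        n_channels=6, T=32, n_filters_time=4, n_filters_spat=4,
        filter_time_length=5, pool_time_length=14, pool_time_stride=7)
    a = models.fit(spec, x, y, epochs=1, seed=7)
    b = models.fit(spec, x, y, epochs=1, seed=7)
    assert a.history["loss"][0] == b.history["loss"][0]


def test_predict_proba_permutation_equivariance(rng_mod):
    x, y = _separable_toy(rng_mod, n=24)
    spec = models.build_shallow_convnet(
        n_channels=6, T=32, n_filters_time=4, n_filters_spat=4,
        filter_time_length=5, pool_time_length=14, pool_time_stride=7)
    m = models.fit(spec, x, y, epochs=2, seed=0)
    p = m.predict_proba(x)
    perm = rng_mod.permutation(len(x))
    assert np.allclose(m.predict_proba(x[perm]), p[perm], atol=1e-7)


def test_label_outside_class_set_rejected(rng_mod):
    x, y = _separable_toy(rng_mod, n=16)
    spec = models.build_shallow_convnet(
        n_channels=6, T=32, n_filters_time=4, n_filters_spat=4,
        filter_time_length=5, pool_time_length=14, pool_time_stride=7)
    with pytest.raises(ValueError):
        models.fit(spec, x, y, classes=("a", "b"), epochs=1)


def test_save_load_round_trip(rng_mod, tmp_path):
    x, y = _separable_toy(rng_mod, n=24)
    spec = models.build_eegnet(fs=32, n_channels=6, T=32, F1=2, D=1, F2=2,
                               dropout=0.0, sep_kernel=4)
    m = models.fit(spec, x, y, epochs=3, seed=0)
    models.save_model(m, tmp_path / "ckpt")
    loaded = models.load_model(tmp_path / "ckpt")
    assert loaded.classes == m.classes
    assert np.allclose(loaded.predict_proba(x), m.predict_proba(x), atol=1e-6)


def test_registry_covers_all_networks():
    assert set(models.MODEL_NAMES) == {"conv2d_net", "conv3d_net", "mb_conv3d",
                                       "eegnet", "shallow_convnet"}
    with pytest.raises(KeyError):
        models.build_model("resnet", T=64)
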