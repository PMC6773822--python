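"""Architecture contract, initialization statistics, padding, checkpoints,
and end-to-end gradient correctness of the translation network."""

import numpy as np
import pytest

from mrct.nn import BatchNorm2d, Conv2d, ConvTranspose2d, Sequential
from mrct.objective import batch_loss_and_grad
from mrct.unet import (
    DESK_PROFILE,
    NetworkConfig,
    build_network,
    initialize,
    load_checkpoint,
    pad_to_grid,
    save_checkpoint,
    summarize,
)
from mrct.hu_windows import NormalizationSpec


@pytest.mark.parametrize(
    "depth,base,h,w",
    [(3, 8, 64, 64), (2, 4, 32, 48), (1, 2, 10, 6), (3, 4, 24, 40)],
)
def test_output_shape_matches_input(depth, base, h, w):
    """1xHxW in -> 3xHxW out for any grid-compatible size."""
    net = initialize(build_network(NetworkConfig(depth=depth, base_filters=base)), seed=0)
    x = np.random.default_rng(0).normal(size=(2, 1, h, w)).astype(np.float32)
    y = net.forward(x, training=False)
    assert y.shape == (2, 3, h, w)
    assert np.isfinite(y).all()


def test_incompatible_size_rejected_with_padding_hint():
    net = build_network(NetworkConfig(depth=3, base_filters=4))
    with pytest.raises(ValueError, match="pad to 64x64"):
        net.forward(np.zeros((1, 1, 60, 60), dtype=np.float32))


def test_encoder_filter_doubling():
    net = build_network(DESK_PROFILE)
    s = summarize(net, (64, 64))
    assert s.encoder_filters == (8, 16, 32, 64)
    assert [c for c, _, _ in s.level_shapes] == [8, 16, 32, 64]
    assert [h for _, h, _ in s.level_shapes] == [64, 32, 16, 8]
    assert s.n_parameters == net.n_parameters() > 0


def test_initialization_is_seed_deterministic():
    a = initialize(build_network(DESK_PROFILE), seed=42)
    b = initialize(build_network(DESK_PROFILE), seed=42)
    for pa, pb in zip(a.params(), b.params()):
        assert np.array_equal(pa.value, pb.value)
    c = initialize(build_network(DESK_PROFILE), seed=43)
    assert any(
        not np.array_equal(pa.value, pc.value) for pa, pc in zip(a.params(), c.params())
    )


def test_initialization_statistics():
    """Conv weights ~ N(0, 0.01^2): sample std within 10% on a large layer,
    mean within the 3-sigma CLT bound; biases 0; BN scale 1 / shift 0."""
    net = initialize(build_network(DESK_PROFILE), seed=7)
    checked_large_layer = False
    for _, block in net.blocks():
        layers = block.layers if isinstance(block, Sequential) else [block]
        for layer in layers:
            if isinstance(layer, (Conv2d, ConvTranspose2d)):
                w = layer.w.value
                if w.size >= 10_000:
                    assert abs(w.std() - 0.01) < 0.001
                    checked_large_layer = True
                assert abs(w.mean()) < 3 * 0.01 / np.sqrt(w.size)
                assert (layer.b.value == 0).all()
            elif isinstance(layer, BatchNorm2d):
                assert (layer.gamma.value == 1).all()
                assert (layer.beta.value == 0).all()
    assert checked_large_layer


@pytest.mark.parametrize(
    "shape,depth,expected",
    [((250, 250), 5, (256, 256)), ((64, 64), 3, (64, 64)), ((10, 29), 2, (12, 32))],
)
def test_pad_to_grid(shape, depth, expected):
    arr = np.random.default_rng(0).normal(size=shape)
    padded, rec = pad_to_grid(arr, depth)
    assert padded.shape == expected
    assert np.array_equal(rec.crop(padded), arr)
    if shape == expected:
        assert rec == type(rec)(0, 0, 0, 0)


def test_gradients_exist_and_match_finite_differences():
    """Backprop through the full network agrees with central differences on
    the smooth (MSE) part of the objective; the MAE kink is excluded by
    keeping residuals away from zero."""
    net = initialize(build_network(NetworkConfig(depth=2, base_filters=2)), seed=3)
    for p in net.params():
        p.value = p.value.astype(np.float64)
        p.grad = np.zeros_like(p.value)
    rng = np.random.default_rng(0)
    x = rng.normal(size=(2, 1, 8, 8))
    t = rng.normal(size=(2, 3, 8, 8)) * 0.1

    def mse_loss():
        d = net.forward(x, training=True) - t
        return float((d * d).sum() / d.size)

    d = net.forward(x, training=True) - t
    for p in net.params():
        p.grad[...] = 0
    net.backward(2 * d / d.size)
    eps = 1e-6
    check_rng = np.random.default_rng(1)
    for p in net.params():
        flat = p.value.ravel()
        for i in check_rng.choice(flat.size, size=min(3, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp = mse_loss()
            flat[i] = orig - eps
            lm = mse_loss()
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            assert np.isclose(p.grad.ravel()[i], num, rtol=1e-3, atol=1e-9)


def test_full_loss_gradients_finite():
    net = initialize(build_network(NetworkConfig(depth=2, base_filters=4)), seed=0)
    rng = np.random.default_rng(5)
    x = rng.normal(size=(4, 1, 16, 16)).astype(np.float32)
    t = rng.normal(size=(4, 3, 16, 16)).astype(np.float32)
    pred = net.forward(x, training=True)
    _, grad = batch_loss_and_grad(pred, t)
    net.backward(grad)
    assert all(np.isfinite(p.grad).all() for p in net.params())


def test_checkpoint_roundtrip(tmp_path):
    net = initialize(build_network(NetworkConfig(depth=2, base_filters=4)), seed=9)
    spec = NormalizationSpec(mr_scale=1 / 50)
    x = np.random.default_rng(2).normal(size=(1, 1, 16, 16)).astype(np.float32)
    before = net.forward(x, training=False)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, net, spec)
    net2, spec2 = load_checkpoint(path)
    assert spec2 == spec
    assert net2.config == net.config
    assert np.array_equal(net2.forward(x, training=False), before)


def test_output_channels_fixed_at_three():
    with pytest.raises(ValueError, match="3 tissue channels"):
        NetworkConfig(output_channels=4)
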