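"""Architecture contracts: dense connectivity arithmetic, attention math,
shape propagation and parameter grouping."""

import numpy as np
import pytest

from ecgdelin.nn import (CBAM, ChannelAttention, DelineationNet, DenseBlock,
                         NetConfig, SpatialAttention, Tensor, Transition,
                         shape_trace)


def test_dense_block_channel_arithmetic():
    rng = np.random.default_rng(0)
    block = DenseBlock(64, 8, 32, rng=rng)
    x = Tensor(rng.normal(size=(1, 64, 16)))
    assert block.eval()(x).shape == (1, 320, 16)

    block2 = DenseBlock(160, 4, 32, rng=rng)
    assert block2.eval()(Tensor(rng.normal(size=(1, 160, 16)))).shape \
        == (1, 288, 16)


def test_transition_halves_channels_and_length_with_floor():
    rng = np.random.default_rng(1)
    t = Transition(320, rng=rng).eval()
    assert t(Tensor(rng.normal(size=(1, 320, 162)))).shape == (1, 160, 81)
    t2 = Transition(288, rng=rng).eval()
    assert t2(Tensor(rng.normal(size=(1, 288, 81)))).shape == (1, 144, 40)
    t3 = Transition(2, rng=rng).eval()
    assert t3(Tensor(rng.normal(size=(1, 2, 2)))).shape == (1, 1, 1)
    with pytest.raises(ValueError):
        t3(Tensor(np.zeros((1, 2, 1))))


def test_channel_attention_hand_computation():
    """C=1, r=1, unit MLP weights, x=[1,3]: avg=2, max=3 -> sigmoid(5)."""
    ca = ChannelAttention(1, 1)
    ca.w0.data = np.array([[1.0]])
    ca.w1.data = np.array([[1.0]])
    out = ca(Tensor(np.array([[[1.0, 3.0]]])))
    assert out.data[0, 0] == pytest.approx(1 / (1 + np.exp(-5.0)))


def test_attention_zero_weights_give_half():
    ca = ChannelAttention(4, 2)
    ca.w0.data[:] = 0
    ca.w1.data[:] = 0
    x = Tensor(np.random.default_rng(0).normal(size=(2, 4, 9)))
    np.testing.assert_allclose(ca(x).data, 0.5)

    sa = SpatialAttention(3)
    sa.conv.weight.data[:] = 0
    sa.conv.bias.data[:] = 0
    np.testing.assert_allclose(sa(x).data, 0.5)


def test_attention_weights_in_open_interval():
    rng = np.random.default_rng(2)
    ca = ChannelAttention(8, 4, rng=rng)
    sa = SpatialAttention(3, rng=rng)
    x = Tensor(rng.normal(size=(3, 8, 20)))
    for w in (ca(x).data, sa(x).data):
        assert np.all(w > 0) and np.all(w < 1)


def test_spatial_attention_length_contract():
    sa = SpatialAttention(3, rng=np.random.default_rng(3))
    for length in (5, 20, 324):
        x = Tensor(np.random.default_rng(4).normal(size=(1, 6, length)))
        assert sa(x).shape == (1, 1, length)


def test_spatial_attention_constant_input_avg_equals_max():
    x = Tensor(np.full((1, 5, 11), 2.0))
    avg = x.mean(axis=1, keepdims=True)
    mx = x.amax(axis=1, keepdims=True)
    np.testing.assert_array_equal(avg.data, mx.data)


def test_cbam_preserves_shape_and_contracts_magnitude():
    rng = np.random.default_rng(5)
    cb = CBAM(16, reduction=4, rng=rng).eval()
    x = Tensor(rng.normal(size=(2, 16, 40)))
    out = cb(x)
    assert out.shape == x.shape
    assert np.all(np.abs(out.data) <= np.abs(x.data) + 1e-12)


def test_cbam_reduction_must_divide_channels():
    with pytest.raises(ValueError):
        ChannelAttention(6, 4)


def test_full_config_forward_traces_reference_shapes():
    cfg = NetConfig()
    net = DelineationNet(cfg, rng=np.random.default_rng(0)).eval()
    x = np.random.default_rng(1).normal(size=(1, 324))
    out, inter = net(x, return_intermediates=True)
    assert inter["stem"] == (1, 64, 324)
    assert inter["stem_pool"] == (1, 64, 162)
    assert inter["dense0"] == (1, 320, 162)
    assert inter["transition0"] == (1, 160, 81)
    assert inter["dense1"] == (1, 288, 81)
    assert inter["transition1"] == (1, 144, 40)
    assert inter["dense2"] == (1, 208, 40)
    assert inter["transition2"] == (1, 104, 20)
    assert inter["pad_pool"] == (1, 104, 21)
    assert inter["final_conv"] == (1, 128, 20)
    assert out.shape == (1, 8)


def test_pyramid_branch_dimensions_full_config():
    net = DelineationNet(NetConfig(), rng=np.random.default_rng(0))
    assert net.head.fc_full.weight.shape == (2560, 256)
    assert net.head.fc_half.weight.shape == (1280, 256)
    assert net.head.fc_quarter.weight.shape == (640, 256)
    assert net.head.fc_hidden.weight.shape == (768, 256)
    assert net.head.fc_out.weight.shape == (256, 8)


def test_pretext_head_has_four_logits(tiny_config):
    net = DelineationNet(tiny_config.with_head("pretext"),
                         rng=np.random.default_rng(0)).eval()
    out = net(np.zeros((2, tiny_config.input_len)))
    assert out.shape == (2, 4)


def test_parameter_count_differs_only_in_final_layer(tiny_config):
    reg = DelineationNet(tiny_config, rng=np.random.default_rng(0))
    pre = DelineationNet(tiny_config.with_head("pretext"),
                         rng=np.random.default_rng(0))
    n_reg = {n: p.data.size for n, p in reg.parameters()}
    n_pre = {n: p.data.size for n, p in pre.parameters()}
    assert set(n_reg) == set(n_pre)
    diff = {n for n in n_reg if n_reg[n] != n_pre[n]}
    assert diff == {"head.fc_out.weight", "head.fc_out.bias"}


def test_batch_of_identical_beats_gives_identical_outputs(tiny_config):
    net = DelineationNet(tiny_config, rng=np.random.default_rng(0)).eval()
    beat = np.random.default_rng(1).normal(size=tiny_config.input_len)
    out = net(np.stack([beat, beat])).data
    np.testing.assert_array_equal(out[0], out[1])


def test_wrong_input_length_raises(tiny_config):
    net = DelineationNet(tiny_config, rng=np.random.default_rng(0))
    with pytest.raises(ValueError):
        net(np.zeros((1, 100)))


def test_shape_trace_row_consistency(tiny_config):
    """The analytic trace agrees with an actual forward pass."""
    rows = shape_trace(tiny_config)
    net = DelineationNet(tiny_config, rng=np.random.default_rng(0)).eval()
    _, inter = net(np.zeros((1, tiny_config.input_len)),
                   return_intermediates=True)
    dense_rows = [r for r in rows if r[0] == "Dense Block"]
    for i, (_, _, (length, ch)) in enumerate(dense_rows):
        assert inter[f"dense{i}"] == (1, ch, length)


def test_ablation_flags_remove_modules(tiny_config):
    import dataclasses

    no_cbam = dataclasses.replace(tiny_config, use_cbam=False)
    net = DelineationNet(no_cbam, rng=np.random.default_rng(0))
    assert not any(n.startswith("cbams") for n, _ in net.parameters())

    no_fpp = dataclasses.replace(tiny_config, use_fpp=False)
    net2 = DelineationNet(no_fpp, rng=np.random.default_rng(0))
    assert not any("fc_half" in n for n, _ in net2.parameters())
    assert net2.eval()(np.zeros((1, 64))).shape == (1, 8)
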