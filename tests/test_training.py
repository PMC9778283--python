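"""Fold bookkeeping, loss mechanics, freezing and transfer contracts."""

import hashlib

import numpy as np
import pytest

from ecgdelin.nn import (DelineationNet, NetConfig, Tensor, l1_loss,
                         softmax_cross_entropy)
from ecgdelin.training import (Adam, SGD, TrainConfig, make_folds,
                               train_downstream, train_pretext,
                               transfer_and_freeze, trainable_parameters)


def test_make_folds_partition_properties():
    folds = make_folds(10, 5, seed=0)
    sizes = np.bincount(folds)
    assert sizes.tolist() == [2, 2, 2, 2, 2]
    folds = make_folds(103, 5, seed=1)
    assert sorted(np.bincount(folds), reverse=True) == [21, 21, 21, 20, 20]
    assert set(range(103)) == set(np.arange(103)[folds >= 0])
    with pytest.raises(ValueError):
        make_folds(3, 5)
    np.testing.assert_array_equal(make_folds(50, 5, seed=9),
                                  make_folds(50, 5, seed=9))


def test_uniform_logits_cross_entropy_is_ln4(tiny_config):
    net = DelineationNet(tiny_config.with_head("pretext"),
                         rng=np.random.default_rng(0)).eval()
    net.head.fc_out.weight.data[:] = 0
    net.head.fc_out.bias.data[:] = 0
    x = np.random.default_rng(1).normal(size=(8, 64))
    loss = softmax_cross_entropy(net(x), np.zeros(8, dtype=int))
    assert float(loss.data) == pytest.approx(np.log(4.0))


def test_l1_of_constant_predictor_matches_hand_arithmetic():
    pred = Tensor(np.full((2, 8), 10.0))
    target = np.vstack([np.full(8, 12.0), np.full(8, 7.0)])
    # |10-12| = 2 and |10-7| = 3 -> mean 2.5
    assert float(l1_loss(pred, target).data) == pytest.approx(2.5)


def test_perfect_prediction_has_zero_l1():
    target = np.arange(16.0).reshape(2, 8)
    assert float(l1_loss(Tensor(target.copy()), target).data) == 0.0


def _param_hash(pairs):
    h = hashlib.sha256()
    for name, p in sorted(pairs, key=lambda kv: kv[0]):
        h.update(name.encode())
        h.update(p.data.tobytes())
    return h.hexdigest()


def _tiny_pretext_checkpoint(tiny_config, n=24, epochs=2):
    rng = np.random.default_rng(0)
    X = rng.normal(size=(n, tiny_config.input_len))
    y = rng.integers(0, 4, n)
    return train_pretext(X, y, tiny_config.with_head("pretext"),
                         TrainConfig(epochs=epochs, folds=2, batch_size=8,
                                     seed=0, patience=5))


def test_pretext_reports_per_fold_accuracy(tiny_config):
    ck = _tiny_pretext_checkpoint(tiny_config)
    assert len(ck.fold_accuracies) == 2
    assert ck.mean_accuracy == pytest.approx(np.mean(ck.fold_accuracies))
    assert ck.backbone_state  # non-empty backbone


def test_training_is_deterministic_given_seed(tiny_config):
    a = _tiny_pretext_checkpoint(tiny_config)
    b = _tiny_pretext_checkpoint(tiny_config)
    for ha, hb in zip(a.histories, b.histories):
        assert ha == hb
    for k in a.backbone_state:
        np.testing.assert_array_equal(a.backbone_state[k],
                                      b.backbone_state[k])


def test_transfer_loads_backbone_and_reinitializes_head(tiny_config):
    ck = _tiny_pretext_checkpoint(tiny_config)
    net = transfer_and_freeze(ck, tiny_config.with_head("regression"), seed=1)
    own = dict(net.parameters())
    for name, value in ck.backbone_state.items():
        if name in own:
            np.testing.assert_array_equal(own[name].data, value)
    assert net.backbone_frozen
    # only head parameters are trainable
    trainable = trainable_parameters(net)
    assert all(n.startswith("head.") for n, _ in trainable)
    head_count = sum(p.data.size for _, p in trainable)
    assert head_count == sum(p.data.size for n, p in net.parameters()
                             if n.startswith("head."))


def test_transfer_shape_mismatch_names_layer(tiny_config):
    ck = _tiny_pretext_checkpoint(tiny_config)
    bad = dict(ck.backbone_state)
    key = "stem.weight"
    bad[key] = np.zeros((2, 2, 2))
    with pytest.raises(ValueError, match="stem.weight"):
        transfer_and_freeze(bad, tiny_config.with_head("regression"))


def test_frozen_backbone_is_bit_identical_through_finetuning(tiny_config):
    ck = _tiny_pretext_checkpoint(tiny_config)
    net = transfer_and_freeze(ck, tiny_config.with_head("regression"), seed=2)
    rng = np.random.default_rng(3)
    X = rng.normal(size=(30, tiny_config.input_len))
    Y = np.sort(rng.uniform(0, tiny_config.input_len, (30, 8)), axis=1)
    before = _param_hash(net.backbone_parameters())
    head_before = _param_hash(net.head_parameters())
    train_downstream(net, X, Y, TrainConfig(epochs=3, folds=2, batch_size=8,
                                            lr=0.001, seed=4, patience=5))
    assert _param_hash(net.backbone_parameters()) == before
    assert _param_hash(net.head_parameters()) != head_before


def test_downstream_split_is_8_to_2(tiny_config):
    net = DelineationNet(tiny_config, rng=np.random.default_rng(0))
    rng = np.random.default_rng(1)
    X = rng.normal(size=(40, tiny_config.input_len))
    Y = np.sort(rng.uniform(0, 64, (40, 8)), axis=1)
    res = train_downstream(net, X, Y,
                           TrainConfig(epochs=2, folds=2, batch_size=8,
                                       seed=0, patience=3))
    assert len(res.test_idx) == 8
    assert len(res.train_idx) == 32
    assert set(res.test_idx).isdisjoint(res.train_idx)
    assert res.test_predictions.shape == (8, 8)


def test_non_finite_loss_aborts(tiny_config):
    net = DelineationNet(tiny_config, rng=np.random.default_rng(0))
    net.head.fc_out.weight.data[:] = np.inf
    X = np.ones((10, tiny_config.input_len))
    Y = np.tile(np.arange(8.0), (10, 1))
    with pytest.raises(FloatingPointError):
        train_downstream(net, X, Y, TrainConfig(epochs=1, folds=2,
                                                batch_size=4, seed=0))


def test_optimizers_descend_on_quadratic():
    for opt_cls, kwargs in ((SGD, {"lr": 0.05, "momentum": 0.9}),
                            (Adam, {"lr": 0.1})):
        w = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = opt_cls([("w", w)], **kwargs)
        for _ in range(300):
            opt.zero_grad()
            (w * w).sum().backward()
            opt.step()
        assert np.all(np.abs(w.data) < 0.2)
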