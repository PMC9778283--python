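"""Training loops: pretext classification, backbone transfer/freezing and
downstream fine-tuning.

Pretext: k-fold cross-validation, Adam, cross-entropy; the reported
accuracy is the mean over folds and the returned checkpoint is the best
fold's backbone. Downstream: 8:2 train/test split, cross-validation
inside the training portion, SGD (lr 0.001, momentum 0.9), L1 loss and
early stopping on the validation loss. With a frozen backbone only the
fully connected head receives updates and backbone batch-norm layers run
in inference mode, so every frozen parameter stays bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nn import DelineationNet, NetConfig, l1_loss, softmax_cross_entropy


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr=0.001, momentum=0.9):
        self.params = list(params)          # [(name, Tensor)]
        self.lr, self.momentum = lr, momentum
        self.velocity = {n: np.zeros_like(p.data) for n, p in self.params}

    def zero_grad(self):
        for _, p in self.params:
            p.grad = None

    def step(self):
        for n, p in self.params:
            if p.grad is None:
                continue
            v = self.velocity[n]
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = {n: np.zeros_like(p.data) for n, p in self.params}
        self.v = {n: np.zeros_like(p.data) for n, p in self.params}
        self.t = 0

    def zero_grad(self):
        for _, p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for n, p in self.params:
            if p.grad is None:
                continue
            self.m[n] = b1 * self.m[n] + (1 - b1) * p.grad
            self.v[n] = b2 * self.v[n] + (1 - b2) * p.grad ** 2
            mhat = self.m[n] / (1 - b1 ** self.t)
            vhat = self.v[n] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Folds and configs
# ---------------------------------------------------------------------------

def make_folds(n, k, seed=0) -> np.ndarray:
    """Deterministic fold assignment: a seeded permutation split into k
    folds whose sizes differ by at most one."""
    if n < k:
        raise ValueError(f"cannot split {n} items into {k} folds")
    perm = np.random.default_rng(seed).permutation(n)
    folds = np.empty(n, dtype=int)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for fold, size in enumerate(sizes):
        folds[perm[start: start + size]] = fold
        start += size
    return folds


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters shared by both stages."""

    epochs: int = 100
    batch_size: int = 64
    lr: float = 1e-3
    momentum: float = 0.9
    folds: int = 5
    patience: int = 10
    test_fraction: float = 0.2
    seed: int = 0


@dataclass
class PretextCheckpoint:
    """Best-fold backbone weights plus the cross-validation accuracies."""

    backbone_state: dict
    fold_accuracies: list
    mean_accuracy: float
    histories: list
    config: NetConfig


def _check_finite(loss):
    if not np.isfinite(loss):
        raise FloatingPointError(f"non-finite training loss ({loss}); "
                                 "check inputs and learning rate")


def _minibatches(n, batch_size, rng):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start: start + batch_size]


def _run_epochs(net, opt, loss_fn, X, y, train_idx, val_idx, epochs,
                batch_size, patience, rng, forward=None):
    """Generic loop with early stopping; returns (best_val, history).

    ``forward`` maps an index array to network outputs; the default runs
    the full network, while frozen-backbone fine-tuning passes a closure
    over cached backbone features.
    """
    if forward is None:
        forward = lambda idx: net(X[idx])
    best_val, best_state, wait = np.inf, None, 0
    history = []
    for _ in range(epochs):
        net.train()
        ep_loss, nb = 0.0, 0
        for batch in _minibatches(len(train_idx), batch_size, rng):
            idx = train_idx[batch]
            opt.zero_grad()
            loss = loss_fn(forward(idx), y[idx])
            _check_finite(loss.data)
            loss.backward()
            opt.step()
            ep_loss += float(loss.data)
            nb += 1
        net.eval()
        val = float(loss_fn(forward(val_idx), y[val_idx]).data)
        _check_finite(val)
        history.append({"train_loss": ep_loss / max(nb, 1), "val_loss": val})
        if val < best_val - 1e-9:
            best_val, best_state, wait = val, net.state_dict(), 0
        else:
            wait += 1
            if wait >= patience:
                break
    if best_state is not None:
        net.load_state_dict(best_state)
    return best_val, history


def classification_accuracy(net, X, y) -> float:
    net.eval()
    pred = net(X).data.argmax(axis=1)
    return float(np.mean(pred == y))


# ---------------------------------------------------------------------------
# Pretext stage
# ---------------------------------------------------------------------------

def train_pretext(X, y, net_config: NetConfig | None = None,
                  cfg: TrainConfig | None = None) -> PretextCheckpoint:
    """Cross-validated pretext training on a 4-class dataset.

    ``X`` is (n, length); ``y`` integer pseudo-labels. Each fold trains a
    freshly initialized network; the checkpoint keeps the backbone of the
    fold with the best validation accuracy.
    """
    cfg = cfg or TrainConfig()
    net_config = (net_config or NetConfig(input_len=X.shape[1])
                  ).with_head("pretext")
    if net_config.input_len != X.shape[1]:
        raise ValueError("net_config.input_len must match the beat length")
    folds = make_folds(len(X), cfg.folds, cfg.seed)
    accuracies, histories = [], []
    best_acc, best_state = -1.0, None
    for fold in range(cfg.folds):
        rng = np.random.default_rng(cfg.seed + 1000 * fold + 1)
        net = DelineationNet(net_config, rng=rng)
        opt = Adam(net.parameters(), lr=cfg.lr)
        train_idx = np.flatnonzero(folds != fold)
        val_idx = np.flatnonzero(folds == fold)
        _, hist = _run_epochs(net, opt, softmax_cross_entropy, X, y,
                              train_idx, val_idx, cfg.epochs, cfg.batch_size,
                              cfg.patience, rng)
        acc = classification_accuracy(net, X[val_idx], y[val_idx])
        accuracies.append(acc)
        histories.append(hist)
        if acc > best_acc:
            best_acc, best_state = acc, net.backbone_state()
    return PretextCheckpoint(best_state, accuracies,
                             float(np.mean(accuracies)), histories,
                             net_config)


# ---------------------------------------------------------------------------
# Transfer and downstream stage
# ---------------------------------------------------------------------------

def transfer_and_freeze(checkpoint, net_config: NetConfig | None = None,
                        seed=0, freeze=True) -> DelineationNet:
    """Build a regression network from a pretext checkpoint.

    Convolutional/batch-norm backbone weights are loaded from the
    checkpoint (layer-name matched, shape checked); the fully connected
    head is freshly He-initialized. With ``freeze=True`` the backbone is
    marked frozen: only head parameters may be optimized and backbone
    batch-norm runs in inference mode during training.
    """
    state = checkpoint.backbone_state if isinstance(
        checkpoint, PretextCheckpoint) else checkpoint
    if net_config is None:
        base = checkpoint.config if isinstance(checkpoint, PretextCheckpoint) \
            else NetConfig()
        net_config = base.with_head("regression")
    rng = np.random.default_rng(seed)
    net = DelineationNet(net_config, rng=rng)
    own = dict(net.backbone_parameters())
    bufs = dict(net.named_buffers())
    for name, value in state.items():
        if name in own:
            if own[name].data.shape != value.shape:
                raise ValueError(f"shape mismatch loading {name!r}: "
                                 f"{own[name].data.shape} vs {value.shape}")
            own[name].data = value.copy()
        elif name in bufs:
            bufs[name][...] = value
        else:
            raise KeyError(f"checkpoint parameter {name!r} not in backbone")
    if freeze:
        net.set_backbone_frozen(True)
    return net


@dataclass
class DownstreamResult:
    net: DelineationNet
    best_val_l1: float
    history: list
    train_idx: np.ndarray
    test_idx: np.ndarray
    test_predictions: np.ndarray
    test_l1: float


def trainable_parameters(net: DelineationNet):
    return net.head_parameters() if net.backbone_frozen else \
        list(net.parameters())


def train_downstream(net: DelineationNet, X, Y,
                     cfg: TrainConfig | None = None) -> DownstreamResult:
    """Fine-tune on (beat, fiducial-vector) pairs.

    Beats are split 8:2 into train/test; inside the training portion a
    cross-validation fold provides the early-stopping validation set.
    The model with the best validation L1 across folds is kept and
    evaluated once on the held-out test beats.
    """
    cfg = cfg or TrainConfig(lr=0.001)
    rng = np.random.default_rng(cfg.seed)
    n = len(X)
    perm = rng.permutation(n)
    n_test = max(1, int(round(cfg.test_fraction * n)))
    test_idx, train_pool = perm[:n_test], perm[n_test:]
    folds = make_folds(len(train_pool), cfg.folds, cfg.seed + 1)
    params = trainable_parameters(net)
    # start the output layer at the mean training-set positions: with an
    # L1 loss and a small fixed learning rate the head then learns the
    # per-beat residuals instead of spending the whole budget moving the
    # bias across the coordinate range
    net.head.fc_out.bias.data = Y[train_pool].mean(axis=0)
    init_state = net.state_dict()
    forward = None
    if net.backbone_frozen:
        # frozen backbone + inference-mode BN => features are constant,
        # so compute them once and train the head on the cache
        net.eval()
        feats = net.features(X).data
        forward = lambda idx: net.head_from_features(feats[idx])
    best = (np.inf, None, None)
    all_hist = []
    for fold in range(cfg.folds):
        net.load_state_dict(init_state)
        opt = SGD(params, lr=cfg.lr, momentum=cfg.momentum)
        tr = train_pool[folds != fold]
        va = train_pool[folds == fold]
        val, hist = _run_epochs(net, opt, l1_loss, X, Y, tr, va, cfg.epochs,
                                cfg.batch_size, cfg.patience,
                                np.random.default_rng(cfg.seed + 7 * fold),
                                forward=forward)
        all_hist.append(hist)
        if val < best[0]:
            best = (val, net.state_dict(), fold)
    net.load_state_dict(best[1])
    net.eval()
    pred = net(X[test_idx]).data
    test_l1 = float(np.mean(np.abs(pred - Y[test_idx])))
    return DownstreamResult(net, float(best[0]), all_hist, train_pool,
                            test_idx, pred, test_l1)
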