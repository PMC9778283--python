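"""Neural-network building blocks for 1D ECG feature maps.

Feature maps follow the (batch, channels, length) convention. Modules hold
named :class:`~ecgdelin.nn.autodiff.Tensor` parameters; ``parameters()``
walks the tree and yields ``(name, tensor)`` pairs so optimizers and
checkpoints can address parameter groups (convolutional backbone vs.
fully connected head) by name.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, avg_pool1d, concat, conv1d, max_pool1d


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """He (Kaiming) normal initialization for ReLU networks."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Module:
    """Base class: named submodules/parameters, train/eval mode."""

    def __init__(self):
        self._modules: dict[str, Module] = {}
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, key, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[key] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[key] = value
        object.__setattr__(self, key, value)

    def register_buffer(self, name, value):
        """Non-parameter state (e.g. batch-norm running statistics) that
        travels with ``state_dict`` but receives no gradients."""
        arr = np.asarray(value, dtype=np.float64)
        self.__dict__.setdefault("_buffers", {})[name] = arr
        object.__setattr__(self, name, arr)

    def parameters(self, prefix=""):
        for name, p in self._params.items():
            yield (prefix + name, p)
        for name, mod in self._modules.items():
            yield from mod.parameters(prefix + name + ".")

    def named_buffers(self, prefix=""):
        for name, b in self._buffers.items():
            yield (prefix + name, b)
        for name, mod in self._modules.items():
            yield from mod.named_buffers(prefix + name + ".")

    def train(self, mode=True):
        self.training = mode
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state, strict=True):
        own = dict(self.parameters())
        bufs = dict(self.named_buffers())
        for name, value in state.items():
            if name in own:
                if own[name].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {name!r}: "
                        f"{own[name].data.shape} vs {value.shape}")
                own[name].data = value.copy()
            elif name in bufs:
                bufs[name][...] = value  # in place: modules hold the array
            elif strict:
                raise KeyError(f"unexpected parameter {name!r}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv1d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=0, bias=True,
                 rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.pad = stride, pad
        self.weight = Tensor(
            he_normal(rng, (out_ch, in_ch, kernel), in_ch * kernel),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x):
        return conv1d(x, self.weight, self.bias, stride=self.stride,
                      pad=self.pad)


class Linear(Module):
    def __init__(self, in_dim, out_dim, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Tensor(he_normal(rng, (in_dim, out_dim), in_dim),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def forward(self, x):
        return x @ self.weight + self.bias

    def reinitialize(self, rng):
        """He re-initialization, used when transferring to a new head."""
        self.weight.data = he_normal(rng, self.weight.shape,
                                     self.weight.shape[0])
        self.bias.data = np.zeros_like(self.bias.data)


class BatchNorm1d(Module):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=0, keepdims=True).mean(axis=2, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True).mean(axis=2, keepdims=True)
            n = x.shape[0] * x.shape[2]
            self.running_mean += self.momentum * (
                mu.data.ravel() - self.running_mean)
            unbiased = var.data.ravel() * n / max(n - 1, 1)
            self.running_var += self.momentum * (unbiased - self.running_var)
            std = (var + self.eps).sqrt()
            xhat = xc * _reciprocal(std)
        else:
            mu = self.running_mean[None, :, None]
            std = np.sqrt(self.running_var + self.eps)[None, :, None]
            xhat = (x - mu) * (1.0 / std)
        g = self.gamma.reshape(1, -1, 1)
        b = self.beta.reshape(1, -1, 1)
        return xhat * g + b


def _reciprocal(t: Tensor) -> Tensor:
    inv = 1.0 / t.data

    def bwd(g):
        t._accum(-g * inv * inv)

    return Tensor(inv, parents=(t,), backward=bwd)


class Dropout(Module):
    def __init__(self, rate, rng=None):
        super().__init__()
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x):
        if not self.training or self.rate <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(mask)


class ChannelAttention(Module):
    """Channel attention: sigmoid(MLP(avgpool) + MLP(maxpool)).

    The shared two-layer perceptron (weights ``w0``: C -> C/r, ``w1``:
    C/r -> C, no biases) is applied to the per-channel average- and
    max-pooled descriptors; the sigmoid of the summed outputs gives one
    multiplicative weight per channel.
    """

    def __init__(self, channels, reduction, rng=None):
        super().__init__()
        if channels % reduction:
            raise ValueError(
                f"channels ({channels}) must be divisible by the reduction "
                f"ratio ({reduction})")
        rng = rng or np.random.default_rng()
        hidden = channels // reduction
        self.w0 = Tensor(he_normal(rng, (channels, hidden), channels),
                         requires_grad=True)
        self.w1 = Tensor(he_normal(rng, (hidden, channels), hidden),
                         requires_grad=True)

    def forward(self, x):
        avg = x.mean(axis=2)          # (N, C)
        mx = x.amax(axis=2)           # (N, C)
        out = ((avg @ self.w0).relu() @ self.w1 +
               (mx @ self.w0).relu() @ self.w1)
        return out.sigmoid()          # (N, C)


class SpatialAttention(Module):
    """Spatial attention: sigmoid(conv_k([avgpool_c; maxpool_c]))."""

    def __init__(self, kernel=3, rng=None):
        super().__init__()
        self.conv = Conv1d(2, 1, kernel, pad=kernel // 2, rng=rng)

    def forward(self, x):
        avg = x.mean(axis=1, keepdims=True)   # (N, 1, L)
        mx = x.amax(axis=1, keepdims=True)    # (N, 1, L)
        return self.conv(concat([avg, mx], axis=1)).sigmoid()  # (N, 1, L)


class CBAM(Module):
    """Convolutional block attention: channel then spatial reweighting."""

    def __init__(self, channels, reduction=8, spatial_kernel=3, rng=None):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng=rng)
        self.spatial = SpatialAttention(spatial_kernel, rng=rng)

    def forward(self, x):
        mc = self.channel(x)                       # (N, C)
        x = x * mc.reshape(mc.shape[0], -1, 1)     # broadcast over length
        ms = self.spatial(x)                       # (N, 1, L)
        return x * ms                              # broadcast over channels


class DenseLayer(Module):
    """BN-ReLU-Conv1x1 bottleneck followed by BN-ReLU-Conv3 producing
    ``growth`` channels that are concatenated onto the input."""

    def __init__(self, in_ch, growth, bottleneck_mult=4, rng=None):
        super().__init__()
        mid = bottleneck_mult * growth
        self.bn1 = BatchNorm1d(in_ch)
        self.conv1 = Conv1d(in_ch, mid, 1, bias=False, rng=rng)
        self.bn2 = BatchNorm1d(mid)
        self.conv2 = Conv1d(mid, growth, 3, pad=1, bias=False, rng=rng)

    def forward(self, x):
        y = self.conv1(self.bn1(x).relu())
        y = self.conv2(self.bn2(y).relu())
        return concat([x, y], axis=1)


class DenseBlock(Module):
    def __init__(self, in_ch, n_layers, growth, bottleneck_mult=4, rng=None):
        super().__init__()
        self.out_channels = in_ch + n_layers * growth
        for i in range(n_layers):
            setattr(self, f"layer{i}",
                    DenseLayer(in_ch + i * growth, growth,
                               bottleneck_mult, rng=rng))
        self.n_layers = n_layers

    def forward(self, x):
        for i in range(self.n_layers):
            x = getattr(self, f"layer{i}")(x)
        return x


class Transition(Module):
    """1x1 convolution halving channels then stride-2 average pooling."""

    def __init__(self, in_ch, rng=None):
        super().__init__()
        self.out_channels = in_ch // 2
        self.bn = BatchNorm1d(in_ch)
        self.conv = Conv1d(in_ch, self.out_channels, 1, bias=False, rng=rng)

    def forward(self, x):
        if x.shape[2] < 2:
            raise ValueError("transition layer requires length >= 2")
        x = self.conv(self.bn(x).relu())
        return avg_pool1d(x, 2, 2)


class FPPHead(Module):
    """Feature pyramid pooling head over a (C, L) feature map.

    Three branches — full scale, average-pooled 2x, average-pooled 4x —
    are each flattened and projected to ``branch_dim``; the concatenated
    branch features pass through one hidden fully connected layer to the
    output (8 fiducial coordinates or 4 transformation-class logits).
    """

    def __init__(self, length, channels, out_dim, branch_dim=256,
                 hidden_dim=256, rng=None):
        super().__init__()
        if length // 4 < 1:
            raise ValueError("feature length too short to pool twice")
        self.length, self.channels = length, channels
        self.fc_full = Linear(length * channels, branch_dim, rng=rng)
        self.fc_half = Linear((length // 2) * channels, branch_dim, rng=rng)
        self.fc_quarter = Linear((length // 4) * channels, branch_dim, rng=rng)
        self.fc_hidden = Linear(3 * branch_dim, hidden_dim, rng=rng)
        self.fc_out = Linear(hidden_dim, out_dim, rng=rng)

    def _flat(self, x):
        return x.reshape(x.shape[0], x.shape[1] * x.shape[2])

    def forward(self, x):
        half = avg_pool1d(x, 2, 2)
        quarter = avg_pool1d(half, 2, 2)
        feats = concat([
            self.fc_full(self._flat(x)).relu(),
            self.fc_half(self._flat(half)).relu(),
            self.fc_quarter(self._flat(quarter)).relu(),
        ], axis=1)
        return self.fc_out(self.fc_hidden(feats).relu())
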