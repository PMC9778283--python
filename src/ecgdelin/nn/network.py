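"""The delineation network: 1D DenseNet backbone with CBAM and a
feature-pyramid-pooling head.

Architecture (default configuration, input length 324):

    Conv(64) -> MaxPool/2 -> [DenseBlock -> CBAM -> Transition] x 3
    -> padded Pool -> Conv(128) -> Dropout -> FPP head

With growth rate 32 and (8, 4, 2) layers per block the channel sequence is
64 -> 320 -> 160 -> 288 -> 144 -> 208 -> 104 and the length sequence
324 -> 162 -> 81 -> 40 -> 20, ending in a (20, 128) map whose pyramid
branches flatten to 2560/1280/640, each projected to 256 and concatenated
to 768 before the output layer (8 fiducial coordinates, or 4 logits for
the transformation-recognition pretext head).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor, avg_pool1d, max_pool1d
from .layers import (BatchNorm1d, CBAM, Conv1d, DenseBlock, Dropout, FPPHead,
                     Module, Transition)

#: head type -> output dimension
HEAD_DIMS = {"regression": 8, "pretext": 4}


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    Defaults reproduce the full-scale detection network; tests and
    desk-scale training runs use :meth:`reduced`.
    """

    input_len: int = 324
    stem_channels: int = 64
    stem_kernel: int = 7
    growth: int = 32
    block_layers: tuple = (8, 4, 2)
    bottleneck_mult: int = 4
    cbam_reduction: int = 8
    spatial_kernel: int = 3
    final_channels: int = 128
    branch_dim: int = 256
    hidden_dim: int = 256
    dropout: float = 0.2
    head: str = "regression"
    use_cbam: bool = True
    use_fpp: bool = True

    def with_head(self, head: str) -> "NetConfig":
        if head not in HEAD_DIMS:
            raise ValueError(f"unknown head {head!r}")
        return replace(self, head=head)

    @staticmethod
    def reduced(input_len=324, head="regression") -> "NetConfig":
        """Small configuration for CPU-scale experiments."""
        return NetConfig(input_len=input_len, stem_channels=16, growth=8,
                         block_layers=(2, 2, 1), bottleneck_mult=4,
                         cbam_reduction=4, final_channels=32, branch_dim=64,
                         hidden_dim=64, head=head)


def shape_trace(cfg: NetConfig) -> list[tuple[str, tuple, tuple]]:
    """Analytic (length, channels) trace of every stage, mirroring the
    reference layer table. Returned as (stage, in_shape, out_shape)."""
    rows = []
    length, ch = cfg.input_len, 1
    rows.append(("Input", (length, ch), (length, ch)))
    rows.append(("Conv", (length, 1), (length, cfg.stem_channels)))
    ch = cfg.stem_channels
    out_len = (length + 2 - 3) // 2 + 1          # maxpool k3 s2 p1
    rows.append(("Pooling", (length, ch), (out_len, ch)))
    length = out_len
    for n in cfg.block_layers:
        out_ch = ch + n * cfg.growth
        rows.append(("Dense Block", (length, ch), (length, out_ch)))
        ch = out_ch
        rows.append(("TransitionLayer", (length, ch), (length // 2, ch // 2)))
        length, ch = length // 2, ch // 2
    rows.append(("Pooling", (length, ch), (length + 1, ch)))   # k2 s1 p1
    rows.append(("Conv", (length + 1, ch), (length, cfg.final_channels)))
    ch = cfg.final_channels
    rows.append(("Dropout", (length, ch), (length, ch)))
    rows.append(("Flatten", (length, ch), (length * ch,)))
    rows.append(("Fully-connected", (length * ch,), (cfg.branch_dim,)))
    rows.append(("Pooling (downsampling 2x)", (length, ch), (length // 2, ch)))
    rows.append(("Flatten", (length // 2, ch), (length // 2 * ch,)))
    rows.append(("Fully-connected", (length // 2 * ch,), (cfg.branch_dim,)))
    rows.append(("Pooling (downsampling 4x)", (length // 2, ch),
                 (length // 4, ch)))
    rows.append(("Flatten", (length // 4, ch), (length // 4 * ch,)))
    rows.append(("Fully-connected", (length // 4 * ch,), (cfg.branch_dim,)))
    rows.append(("Concatenation", (cfg.branch_dim, 3), (3 * cfg.branch_dim,)))
    rows.append(("Fully-connected", (3 * cfg.branch_dim,), (cfg.hidden_dim,)))
    rows.append(("Fully-connected", (cfg.hidden_dim,),
                 (HEAD_DIMS[cfg.head],)))
    return rows


class SimpleHead(Module):
    """Single-scale head used when feature-pyramid pooling is ablated."""

    def __init__(self, length, channels, out_dim, hidden_dim, rng=None):
        super().__init__()
        from .layers import Linear
        self.fc_hidden = Linear(length * channels, hidden_dim, rng=rng)
        self.fc_out = Linear(hidden_dim, out_dim, rng=rng)

    def forward(self, x):
        flat = x.reshape(x.shape[0], x.shape[1] * x.shape[2])
        return self.fc_out(self.fc_hidden(flat).relu())


class DelineationNet(Module):
    """Backbone + head; see module docstring for the layer plan.

    Parameters whose names start with a convolutional-stage prefix form
    the transferable/freezable backbone; the fully connected head is
    everything under ``head.``.
    """

    BACKBONE_PREFIXES = ("stem", "blocks", "cbams", "transitions",
                        "final_conv", "final_bn")

    def __init__(self, cfg: NetConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        self.backbone_frozen = False
        self.stem = Conv1d(1, cfg.stem_channels, cfg.stem_kernel,
                           pad=cfg.stem_kernel // 2, bias=False, rng=rng)
        self.stem_bn = BatchNorm1d(cfg.stem_channels)

        length = (cfg.input_len + 2 - 3) // 2 + 1
        ch = cfg.stem_channels
        self._blocks = []
        for i, n in enumerate(cfg.block_layers):
            block = DenseBlock(ch, n, cfg.growth, cfg.bottleneck_mult, rng=rng)
            ch = block.out_channels
            cbam = (CBAM(ch, cfg.cbam_reduction, cfg.spatial_kernel, rng=rng)
                    if cfg.use_cbam else None)
            trans = Transition(ch, rng=rng)
            setattr(self, f"blocks{i}", block)
            if cbam is not None:
                setattr(self, f"cbams{i}", cbam)
            setattr(self, f"transitions{i}", trans)
            self._blocks.append((block, cbam, trans))
            ch = trans.out_channels
            length //= 2

        # padded pool (L -> L+1) then valid k2 conv back to L, as in the
        # reference table's (20,104)->(21,104)->(20,128) tail
        self.final_conv = Conv1d(ch, cfg.final_channels, 2, bias=False,
                                 rng=rng)
        self.final_bn = BatchNorm1d(cfg.final_channels)
        self.feature_len, self.feature_ch = length, cfg.final_channels
        self.dropout = Dropout(cfg.dropout, rng=rng)
        out_dim = HEAD_DIMS[cfg.head]
        if cfg.use_fpp:
            self.head = FPPHead(length, cfg.final_channels, out_dim,
                                cfg.branch_dim, cfg.hidden_dim, rng=rng)
        else:
            self.head = SimpleHead(length, cfg.final_channels, out_dim,
                                   cfg.hidden_dim, rng=rng)

    # -- parameter groups ------------------------------------------------
    def backbone_parameters(self):
        return [(n, p) for n, p in self.parameters()
                if not n.startswith("head.")]

    def head_parameters(self):
        return [(n, p) for n, p in self.parameters() if n.startswith("head.")]

    def backbone_state(self):
        """Backbone parameters plus batch-norm running statistics."""
        state = {n: p.data.copy() for n, p in self.backbone_parameters()}
        state.update({n: b.copy() for n, b in self.named_buffers()
                      if not n.startswith("head.")})
        return state

    def set_backbone_frozen(self, frozen=True):
        """Freeze the convolutional backbone: its parameters are excluded
        from optimization (and from gradient computation), and its
        batch-norm layers stay in inference mode while the head trains."""
        self.backbone_frozen = frozen
        for _, p in self.backbone_parameters():
            p.requires_grad = not frozen
        self.train(self.training)
        return self

    def _backbone_modules(self):
        for name, mod in self._modules.items():
            if name != "head" and name != "dropout":
                yield mod

    def train(self, mode=True):
        super().train(mode)
        if self.backbone_frozen and mode:
            for mod in self._backbone_modules():
                mod.train(False)
        return self

    # -- forward ---------------------------------------------------------
    def features(self, x, intermediates=None):
        """Convolutional-backbone forward up to the (length, final_channels)
        feature map. With a frozen backbone this output is deterministic,
        so head training may cache it."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        if x.ndim == 2:
            x = x.reshape(x.shape[0], 1, x.shape[1])
        if x.shape[2] != self.cfg.input_len:
            raise ValueError(
                f"input length {x.shape[2]} != configured "
                f"{self.cfg.input_len}")
        inter = intermediates if intermediates is not None else {}
        x = self.stem_bn(self.stem(x)).relu()
        inter["stem"] = x.shape
        x = max_pool1d(x, 3, 2, pad=1)
        inter["stem_pool"] = x.shape
        for i, (block, cbam, trans) in enumerate(self._blocks):
            x = block(x)
            inter[f"dense{i}"] = x.shape
            if cbam is not None:
                x = cbam(x)
            x = trans(x)
            inter[f"transition{i}"] = x.shape
        x = avg_pool1d(x, 2, 1, pad=1)
        inter["pad_pool"] = x.shape
        x = self.final_bn(self.final_conv(x)).relu()
        inter["final_conv"] = x.shape
        return x

    def head_from_features(self, feats):
        """Dropout plus the fully connected head on a backbone feature map."""
        if not isinstance(feats, Tensor):
            feats = Tensor(np.asarray(feats, dtype=np.float64))
        return self.head(self.dropout(feats))

    def forward(self, x, return_intermediates=False):
        """``x``: (batch, input_len) or (batch, 1, input_len) array/Tensor."""
        inter = {}
        out = self.head_from_features(self.features(x, intermediates=inter))
        inter["output"] = out.shape
        if return_intermediates:
            return out, inter
        return out
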