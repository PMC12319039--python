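"""Embedding backbones for the twin network.

``resnet50`` / ``se_resnet50`` follow the standard 50-layer bottleneck
layout (stem 7x7/64 stride 2, max pool, stages of 3/4/6/3 bottlenecks,
widths 64/128/256/512, expansion 4); the SE variant inserts a
squeeze-and-excitation gate in every residual unit, applied to the branch
output before the skip addition.  ``se_resnet_tiny`` / ``resnet_tiny`` are
reduced-depth analogs (three bottlenecks) sized so that pair training is
practical on a single CPU; they keep the same structural ingredients.

Every backbone ends with global average pooling and two fully connected
layers producing a fixed-length embedding.
"""

from __future__ import annotations

import numpy as np

from .nn import (BatchNorm2d, Bottleneck, Conv2d, GlobalAvgPool, Layer,
                 Linear, MaxPool2d, ReLU, SEBlock, Sequential)

BACKBONES = ("resnet50", "se_resnet50", "resnet_tiny", "se_resnet_tiny")


class EmbeddingNet(Layer):
    """Feature trunk + global pooling + two-layer embedding head."""

    def __init__(self, trunk: Sequential, feat_dim: int, embedding_dim: int,
                 rng, dtype=np.float32):
        self.trunk = trunk
        self.pool = GlobalAvgPool()
        self.fc1 = Linear(feat_dim, max(embedding_dim, feat_dim // 4), rng=rng, dtype=dtype)
        self.relu = ReLU()
        self.fc2 = Linear(max(embedding_dim, feat_dim // 4), embedding_dim,
                          rng=rng, dtype=dtype)
        self.embedding_dim = embedding_dim

    def forward(self, x, train: bool = False):
        x = self.trunk.forward(x, train=train)
        x = self.pool.forward(x, train=train)
        x = self.fc1.forward(x, train=train)
        x = self.relu.forward(x, train=train)
        return self.fc2.forward(x, train=train)

    def backward(self, dout):
        dout = self.fc2.backward(dout)
        dout = self.relu.backward(dout)
        dout = self.fc1.backward(dout)
        dout = self.pool.backward(dout)
        return self.trunk.backward(dout)


def _stage(in_ch, width, out_ch, blocks, stride, se, rng, dtype):
    layers = [Bottleneck(in_ch, width, out_ch, stride=stride, se_reduction=se,
                         rng=rng, dtype=dtype)]
    for _ in range(blocks - 1):
        layers.append(Bottleneck(out_ch, width, out_ch, stride=1, se_reduction=se,
                                 rng=rng, dtype=dtype))
    return layers


def build_backbone(name: str, embedding_dim: int = 256, se_reduction: int = 16,
                   seed: int = 0, dtype=np.float32) -> EmbeddingNet:
    """Construct an embedding backbone by name (deterministic from ``seed``)."""
    rng = np.random.default_rng(seed)
    if name not in BACKBONES:
        raise ValueError(f"unknown backbone {name!r}; choose from {BACKBONES}")
    se = se_reduction if name.startswith("se_") else None
    if name in ("resnet50", "se_resnet50"):
        layers: list = [
            Conv2d(3, 64, 7, stride=2, pad=3, bias=False, rng=rng, dtype=dtype),
            BatchNorm2d(64, dtype=dtype), ReLU(), MaxPool2d(3, stride=2, pad=1)]
        spec = [(64, 64, 256, 3, 1), (256, 128, 512, 4, 2),
                (512, 256, 1024, 6, 2), (1024, 512, 2048, 3, 2)]
        for in_ch, width, out_ch, blocks, stride in spec:
            layers.extend(_stage(in_ch, width, out_ch, blocks, stride, se, rng, dtype))
        feat_dim = 2048
    else:  # tiny variants
        layers = [
            Conv2d(3, 16, 3, stride=2, pad=1, bias=False, rng=rng, dtype=dtype),
            BatchNorm2d(16, dtype=dtype), ReLU(), MaxPool2d(2, stride=2)]
        spec = [(16, 16, 64, 1, 1), (64, 32, 128, 1, 2), (128, 32, 128, 1, 2)]
        for in_ch, width, out_ch, blocks, stride in spec:
            layers.extend(_stage(in_ch, width, out_ch, blocks, stride, se, rng, dtype))
        feat_dim = 128
    return EmbeddingNet(Sequential(*layers), feat_dim, embedding_dim, rng, dtype=dtype)


def pin_se_gates(net: Layer, pinned: bool = True) -> None:
    """Force every squeeze-and-excitation gate to 1 (identity gating)."""
    for mod in net.modules():
        if isinstance(mod, SEBlock):
            mod.pinned = pinned


def copy_non_se_weights(src: Layer, dst: Layer) -> None:
    """Copy all parameters that are not inside SE blocks between two
    structurally matching backbones (e.g. se_resnet50 -> resnet50)."""
    src_params = {n: p for n, p in src.named_params() if ".se." not in n}
    dst_params = {n: p for n, p in dst.named_params() if ".se." not in n}
    if set(src_params) != set(dst_params):
        missing = set(src_params) ^ set(dst_params)
        raise ValueError(f"backbones do not match structurally: {sorted(missing)[:5]}")
    for n, p in dst_params.items():
        p.data = src_params[n].data.copy()
    # batchnorm running statistics travel too
    src_bns = [m for m in src.modules() if isinstance(m, BatchNorm2d)]
    dst_bns = [m for m in dst.modules() if isinstance(m, BatchNorm2d)]
    for s_bn, d_bn in zip(src_bns, dst_bns):
        d_bn.running_mean = s_bn.running_mean.copy()
        d_bn.running_var = s_bn.running_var.copy()
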