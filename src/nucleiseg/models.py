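"""Builders for the U-Net+ dense-encoder network and its two controls.

Three architectures share the input/output contract (a 256x256 grayscale
patch in, a sigmoid probability map out) and the filter schedule
``2**(n-1) * B`` at level n = 1..N:

``unet_plus``
    The dense-encoder network.  Each encoder level carries a chain of
    convolution blocks; every block after the first concatenates the
    preceding block at the same level with a stride-2 down-sampled feature
    from the level above, so shallow, high-resolution detail is repeatedly
    re-injected while descending.  One down-sampling chain additionally
    short-circuits two levels (a down block applied to an already
    down-sampled tensor); its arrival is fused both into the level-3
    encoder chain and into the corresponding decoder skip.  The decoder is
    U-Net-like: 2x up-sampling (transposed conv that halves the channel
    count, or parameter-free repetition that preserves it) followed by two
    convolution blocks after concatenation with the encoder skip(s).
    Convolution and down-sampling blocks are conv(3x3) + batch-norm + ReLU.

``unet``
    The classic benchmark U-Net: two plain 3x3 ReLU convolutions per level,
    2x2 max-pooling, decoder of 2x repetition up-sampling + 2x2 convolution,
    skip concatenation and two 3x3 convolutions, with a 3x3 conv to two
    channels before the 1x1 sigmoid head.  No batch normalization — this
    reproduces the widely used reference implementation's weight count.

``unet_pp``
    The nested-skip network (U-Net++): the same backbone as ``unet`` plus
    the dense grid of intermediate nodes X(i,j), each a 2x2 transposed-conv
    up-sample of X(i+1,j-1) concatenated with all X(i,0..j-1), followed by
    two 3x3 convolutions.  Deep supervision and pruning are not built.

``count_weights`` totals every stored array: kernels, biases, batch-norm
scale/shift and the batch-norm moving statistics (the framework-total
convention under which the published per-model counts are stated).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import ConvLayer, GraphModel, MaxPool, Node, TConvLayer, Upsample

__all__ = ["ModelConfig", "build_model", "count_weights", "summarize_architecture"]

ARCHS = ("unet_plus", "unet", "unet_pp")
UPSAMPLE_MODES = ("transposed_conv", "upsample")


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    base_filters is B, the channel count of the first level; depth is N, the
    number of levels; level n uses 2**(n-1) * B filters.  l2_lambda is the
    L2 penalty applied to convolution kernels during training.
    use_batchnorm defaults per architecture (True for unet_plus, False for
    the two reference controls, whose published weight counts are BN-free).
    """

    arch: str = "unet_plus"
    base_filters: int = 8
    depth: int = 5
    upsample_mode: str = "transposed_conv"
    l2_lambda: float = 0.0
    n_classes: int = 1
    use_batchnorm: bool | None = None
    seed: int = 0

    def __post_init__(self):
        if self.arch not in ARCHS:
            raise ValueError(f"unknown arch {self.arch!r}; expected one of {ARCHS}")
        if self.upsample_mode not in UPSAMPLE_MODES:
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")
        if self.base_filters < 2 or self.base_filters % 2:
            raise ValueError("base_filters B must be a positive multiple of 2")
        if self.depth < 2:
            raise ValueError("depth N must be at least 2")

    @property
    def batchnorm(self) -> bool:
        if self.use_batchnorm is None:
            return self.arch == "unet_plus"
        return self.use_batchnorm


def _chain_lengths(n_levels: int) -> list[int]:
    """Encoder conv-chain lengths for the dense encoder at depth N.

    N = 5 gives (4, 4, 3, 1): two full-length chains, a tapering middle and
    a single block above the bottleneck, matching the published topology.
    """
    if n_levels < 3:
        raise ValueError("unet_plus needs depth N >= 3")
    if n_levels == 3:
        return [2, 1]
    middle = [n_levels - n for n in range(2, n_levels - 2)]
    return [n_levels - 1, n_levels - 1] + middle + [1]


def _build_unet_plus(cfg: ModelConfig) -> GraphModel:
    rng = np.random.default_rng(cfg.seed)
    n = cfg.depth
    f = [cfg.base_filters * 2 ** i for i in range(n)]
    bn = cfg.batchnorm
    lens = _chain_lengths(n)
    nodes = []

    def conv_block(name, cin, cout, inputs, stride=1, kind="conv_block"):
        nodes.append(Node(name, kind,
                          ConvLayer(cin, cout, k=3, stride=stride, bn=bn,
                                    act="relu", rng=rng), inputs))
        return name

    # encoder level 1 chain (single-input blocks)
    prev = conv_block("C_1_1", 1, f[0], ["input"])
    for j in range(1, lens[0]):
        prev = conv_block(f"C_1_{j + 1}", f[0], f[0], [prev])
    enc_last = {0: prev}
    arrival = {}
    for lv in range(1, n - 1):          # levels 2..N-1 (0-based 1..n-2)
        k_here = lens[lv]
        # one down block per conv block of this level, from successive
        # blocks of the level above
        downs = []
        for j in range(k_here):
            src = f"C_{lv}_{j + 1}"
            downs.append(conv_block(f"D_{lv}_{j + 1}", f[lv - 1], f[lv], [src],
                                    stride=2, kind="down_block"))
        if lv == 1:
            # chain-end down: the deepest arrival goes straight down again
            arrival[2] = conv_block(f"D_{lv}_chain", f[lv], f[lv + 1],
                                    [downs[-1]], stride=2, kind="down_block")
        first_in = [downs[0]] + ([arrival[lv]] if lv in arrival else [])
        cin = f[lv] * len(first_in)
        prev = conv_block(f"C_{lv + 1}_1", cin, f[lv], first_in)
        for j in range(1, k_here):
            prev = conv_block(f"C_{lv + 1}_{j + 1}", 2 * f[lv], f[lv],
                              [prev, downs[j]])
        enc_last[lv] = prev
    # bottleneck: a single down block into level N
    bneck = conv_block(f"D_{n - 1}_1", f[n - 2], f[n - 1],
                       [enc_last[n - 2]], stride=2, kind="down_block")

    prev = bneck
    for lv in range(n - 2, -1, -1):
        skips = [enc_last[lv]] + ([arrival[lv]] if lv in arrival else [])
        if cfg.upsample_mode == "transposed_conv":
            up_c = f[lv]
            nodes.append(Node(f"U_{lv + 1}", "up_block",
                              TConvLayer(f[lv + 1], f[lv], k=3, stride=2,
                                         rng=rng), [prev]))
        else:
            up_c = f[lv + 1]
            nodes.append(Node(f"U_{lv + 1}", "up_block", Upsample(), [prev]))
        cin = up_c + f[lv] * len(skips)
        prev = conv_block(f"UC_{lv + 1}_1", cin, f[lv],
                          [f"U_{lv + 1}"] + skips)
        prev = conv_block(f"UC_{lv + 1}_2", f[lv], f[lv], [prev])
    nodes.append(Node("head", "head",
                      ConvLayer(f[0], cfg.n_classes, k=1, bn=False,
                                act="sigmoid", rng=rng), [prev]))
    return GraphModel(nodes, "head", meta={"arch": cfg.arch, "depth": n, "divisor": 2 ** (n - 1),
                                           "l2_lambda": cfg.l2_lambda})


def _build_unet(cfg: ModelConfig) -> GraphModel:
    rng = np.random.default_rng(cfg.seed)
    n = cfg.depth
    f = [cfg.base_filters * 2 ** i for i in range(n)]
    bn = cfg.batchnorm
    nodes = []

    def conv(name, cin, cout, inputs, k=3, kind="conv_block"):
        nodes.append(Node(name, kind, ConvLayer(cin, cout, k=k, bn=bn,
                                                act="relu", rng=rng), inputs))
        return name

    prev, cin = "input", 1
    skips = []
    for lv in range(n):
        prev = conv(f"C_{lv + 1}_1", cin, f[lv], [prev])
        prev = conv(f"C_{lv + 1}_2", f[lv], f[lv], [prev])
        skips.append(prev)
        if lv < n - 1:
            nodes.append(Node(f"P_{lv + 1}", "down_block", MaxPool(), [prev]))
            prev, cin = f"P_{lv + 1}", f[lv]
    for lv in range(n - 2, -1, -1):
        nodes.append(Node(f"US_{lv + 1}", "up_block", Upsample(), [prev]))
        prev = conv(f"U_{lv + 1}", f[lv + 1], f[lv], [f"US_{lv + 1}"], k=2,
                    kind="up_block")
        prev = conv(f"UC_{lv + 1}_1", 2 * f[lv], f[lv], [prev, skips[lv]])
        prev = conv(f"UC_{lv + 1}_2", f[lv], f[lv], [prev])
    prev = conv("pre_head", f[0], 2, [prev])
    nodes.append(Node("head", "head",
                      ConvLayer(2, cfg.n_classes, k=1, bn=False,
                                act="sigmoid", rng=rng), [prev]))
    return GraphModel(nodes, "head", meta={"arch": cfg.arch, "depth": n, "divisor": 2 ** (n - 1),
                                           "l2_lambda": cfg.l2_lambda})


def _build_unet_pp(cfg: ModelConfig) -> GraphModel:
    rng = np.random.default_rng(cfg.seed)
    n = cfg.depth
    f = [cfg.base_filters * 2 ** i for i in range(n)]
    bn = cfg.batchnorm
    nodes = []

    def conv(name, cin, cout, inputs, k=3, kind="conv_block"):
        nodes.append(Node(name, kind, ConvLayer(cin, cout, k=k, bn=bn,
                                                act="relu", rng=rng), inputs))
        return name

    out = {}
    prev, cin = "input", 1
    for i in range(n):
        a = conv(f"X_{i}_0_a", cin, f[i], [prev])
        out[(i, 0)] = conv(f"X_{i}_0_b", f[i], f[i], [a])
        if i < n - 1:
            nodes.append(Node(f"P_{i}", "down_block", MaxPool(), [out[(i, 0)]]))
            prev, cin = f"P_{i}", f[i]
    for j in range(1, n):
        for i in range(n - j):
            below = out[(i + 1, j - 1)]
            if cfg.upsample_mode == "transposed_conv":
                nodes.append(Node(f"T_{i}_{j}", "up_block",
                                  TConvLayer(f[i + 1], f[i], k=2, stride=2,
                                             rng=rng), [below]))
                up, up_c = f"T_{i}_{j}", f[i]
            else:
                nodes.append(Node(f"T_{i}_{j}", "up_block", Upsample(), [below]))
                up, up_c = f"T_{i}_{j}", f[i + 1]
            inputs = [out[(i, jj)] for jj in range(j)] + [up]
            cin = f[i] * j + up_c
            a = conv(f"X_{i}_{j}_a", cin, f[i], inputs)
            out[(i, j)] = conv(f"X_{i}_{j}_b", f[i], f[i], [a])
    nodes.append(Node("head", "head",
                      ConvLayer(f[0], cfg.n_classes, k=1, bn=False,
                                act="sigmoid", rng=rng), [out[(0, n - 1)]]))
    return GraphModel(nodes, "head", meta={"arch": cfg.arch, "depth": n, "divisor": 2 ** (n - 1),
                                           "l2_lambda": cfg.l2_lambda})


def build_model(config: ModelConfig) -> GraphModel:
    """Build the network described by ``config``."""
    builder = {"unet_plus": _build_unet_plus,
               "unet": _build_unet,
               "unet_pp": _build_unet_pp}[config.arch]
    return builder(config)


def count_weights(model: GraphModel) -> int:
    """Total stored parameters, including batch-norm moving statistics."""
    return model.count_weights()


def summarize_architecture(config: ModelConfig, input_size: int | None = None):
    """Per-block listing (name, kind, output shape, inputs, params).

    Returns (text_table, rows); the params column sums to count_weights.
    """
    model = build_model(config)
    size = input_size or 16 * 2 ** (config.depth - 1)
    model.forward(np.zeros((1, size, size, 1), dtype=np.float32))
    rows = []
    for node in model.nodes:
        shape = model.last_shapes[node.name]
        rows.append({
            "name": node.name,
            "kind": node.kind,
            "output_shape": f"{shape[1]}x{shape[2]}x{shape[3]}",
            "inputs": ",".join(node.inputs),
            "params": node.layer.num_params(),
        })
    total = sum(r["params"] for r in rows)
    assert total == model.count_weights()
    widths = {k: max(len(k), max(len(str(r[k])) for r in rows))
              for k in rows[0]}
    lines = ["\t".join(k.ljust(widths[k]) for k in rows[0])]
    for r in rows:
        lines.append("\t".join(str(r[k]).ljust(widths[k]) for k in rows[0]))
    lines.append(f"total\t{total}\t({total / 1e6:.3f} M)")
    return "\n".join(lines), rows
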