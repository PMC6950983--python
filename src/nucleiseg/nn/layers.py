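"""Layer objects and the named-node graph model used by the builders."""
from __future__ import annotations

import numpy as np

from . import core
from .core import Parameter, Tensor

__all__ = ["ConvLayer", "TConvLayer", "MaxPool", "Upsample", "Node", "GraphModel"]


def _he_normal(rng, k, cin, cout, dtype):
    std = np.sqrt(2.0 / (k * k * cin))
    return (rng.standard_normal((k, k, cin, cout)) * std).astype(dtype)


class ConvLayer:
    """Convolution (+ optional batch-norm) (+ optional nonlinearity)."""

    def __init__(self, cin, cout, k=3, stride=1, bn=False, act="relu",
                 bias=True, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.act, self.bn = k, stride, act, bn
        self.w = Parameter(_he_normal(rng, k, cin, cout, dtype))
        self.b = Parameter(np.zeros(cout, dtype=dtype)) if bias else None
        if bn:
            self.gamma = Parameter(np.ones(cout, dtype=dtype))
            self.beta = Parameter(np.zeros(cout, dtype=dtype))
            self.running_mean = np.zeros(cout, dtype=dtype)
            self.running_var = np.ones(cout, dtype=dtype)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        y = core.conv2d(x, self.w, self.b, stride=self.stride)
        if self.bn:
            y = core.batch_norm(y, self.gamma, self.beta,
                                self.running_mean, self.running_var, train)
        if self.act == "relu":
            y = core.relu(y)
        elif self.act == "sigmoid":
            y = core.sigmoid(y)
        return y

    def parameters(self):
        ps = [self.w] + ([self.b] if self.b is not None else [])
        if self.bn:
            ps += [self.gamma, self.beta]
        return ps

    def kernel_parameters(self):
        return [self.w]

    def num_params(self):
        n = self.w.data.size + (self.b.data.size if self.b is not None else 0)
        if self.bn:
            # scale, shift and the two running statistics all count
            n += self.gamma.data.size + self.beta.data.size
            n += self.running_mean.size + self.running_var.size
        return n

    def extra_state(self):
        return [self.running_mean, self.running_var] if self.bn else []


class TConvLayer:
    """Transposed convolution (2x spatial upsampling), linear activation."""

    def __init__(self, cin, cout, k=3, stride=2, bias=True, act=None,
                 rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.act, self.bn = k, stride, act, False
        self.w = Parameter(_he_normal(rng, k, cin, cout, dtype))
        self.b = Parameter(np.zeros(cout, dtype=dtype)) if bias else None

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        y = core.conv_transpose2d(x, self.w, self.b, stride=self.stride)
        if self.act == "relu":
            y = core.relu(y)
        return y

    def parameters(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def kernel_parameters(self):
        return [self.w]

    def num_params(self):
        return self.w.data.size + (self.b.data.size if self.b is not None else 0)

    def extra_state(self):
        return []


class _Paramless:
    def parameters(self):
        return []

    def kernel_parameters(self):
        return []

    def num_params(self):
        return 0

    def extra_state(self):
        return []


class MaxPool(_Paramless):
    def __call__(self, x, train):
        return core.max_pool2(x)


class Upsample(_Paramless):
    def __call__(self, x, train):
        return core.upsample2(x)


class Node:
    """Named computation node: concatenate ``inputs`` then apply ``layer``."""

    def __init__(self, name, kind, layer, inputs):
        self.name, self.kind, self.layer, self.inputs = name, kind, layer, inputs


class GraphModel:
    """Feed-forward DAG of named nodes; input node is ``"input"``."""

    def __init__(self, nodes, output: str, meta=None):
        self.nodes = nodes
        self.output = output
        self.meta = dict(meta or {})
        self.last_shapes = {}

    def forward(self, x: np.ndarray, train: bool = False) -> Tensor:
        """x: (N, H, W, C) float array -> output Tensor (sigmoid probs)."""
        values = {"input": Tensor(np.asarray(x))}
        self.last_shapes = {"input": values["input"].shape}
        for node in self.nodes:
            inp = core.concat([values[i] for i in node.inputs])
            values[node.name] = node.layer(inp, train)
            self.last_shapes[node.name] = values[node.name].shape
        return values[self.output]

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False).data

    def parameters(self):
        ps = []
        for node in self.nodes:
            ps.extend(node.layer.parameters())
        return ps

    def kernel_parameters(self):
        ps = []
        for node in self.nodes:
            ps.extend(node.layer.kernel_parameters())
        return ps

    def count_weights(self) -> int:
        return sum(node.layer.num_params() for node in self.nodes)

    # -- checkpointing ------------------------------------------------
    def get_state(self):
        arrays = [p.data.copy() for p in self.parameters()]
        extras = []
        for node in self.nodes:
            extras.extend(a.copy() for a in node.layer.extra_state())
        return arrays, extras

    def set_state(self, state):
        arrays, extras = state
        for p, a in zip(self.parameters(), arrays):
            p.data = a.copy()
        i = 0
        for node in self.nodes:
            for arr in node.layer.extra_state():
                arr[...] = extras[i]
                i += 1

    def save(self, path):
        arrays, extras = self.get_state()
        np.savez(path, meta=np.array(repr(self.meta)),
                 **{f"p{i}": a for i, a in enumerate(arrays)},
                 **{f"e{i}": a for i, a in enumerate(extras)})

    def load(self, path):
        with np.load(path, allow_pickle=False) as z:
            arrays = [z[f"p{i}"] for i in range(len(self.parameters()))]
            n_extra = sum(len(n.layer.extra_state()) for n in self.nodes)
            extras = [z[f"e{i}"] for i in range(n_extra)]
        self.set_state((arrays, extras))
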