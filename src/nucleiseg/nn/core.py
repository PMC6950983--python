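"""Minimal reverse-mode autodiff over NumPy arrays, NHWC layout.

Provides exactly the primitives the segmentation networks need: 2-D
convolution and transposed convolution (im2col / col2im + BLAS matmul),
batch normalization, 2x2 max-pooling, nearest-neighbour 2x upsampling,
channel concatenation and the ReLU / sigmoid nonlinearities.  Tensors form
a DAG through their parents; ``Tensor.backward`` walks it in reverse
topological order and accumulates gradients on ``Parameter`` leaves.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "conv2d",
    "conv_transpose2d",
    "batch_norm",
    "max_pool2",
    "upsample2",
    "concat",
    "relu",
    "sigmoid",
]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad):
        """Back-propagate ``grad`` (same shape as ``self.data``) to leaves."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t.grad is None or t._backward is None:
                continue
            for parent, g in t._backward(t.grad):
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g


class Parameter(Tensor):
    """Trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data))


def _same_pad(size, k, s):
    """Keras-style 'same' padding (extra pixel goes to the bottom/right)."""
    total = max(k - s, 0) if size % s == 0 else max(k - (size % s), 0)
    return total // 2, total - total // 2


def _im2col(xp, k, s, ho, wo):
    """Gather k x k patches from padded input xp -> (N, ho, wo, k, k, C)."""
    n, _, _, c = xp.shape
    cols = np.empty((n, ho, wo, k, k, c), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, :, i, j, :] = xp[:, i:i + ho * s:s, j:j + wo * s:s, :]
    return cols

def _col2im(cols, k, s, hp, wp):
    """Scatter-add k x k contributions back onto a padded canvas."""
    n, ho, wo, _, _, c = cols.shape
    xp = np.zeros((n, hp, wp, c), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, i:i + ho * s:s, j:j + wo * s:s, :] += cols[:, :, :, i, j, :]
    return xp


def conv2d(x: Tensor, w: Parameter, b: Parameter | None, stride: int = 1) -> Tensor:
    """'same' cross-correlation; w has shape (k, k, Cin, Cout)."""
    n, h, wd, cin = x.data.shape
    k = w.data.shape[0]
    pt, pb = _same_pad(h, k, stride)
    pl, pr = _same_pad(wd, k, stride)
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    ho = (h + pt + pb - k) // stride + 1
    wo = (wd + pl + pr - k) // stride + 1
    cols = _im2col(xp, k, stride, ho, wo)
    flat = cols.reshape(n * ho * wo, k * k * cin)
    wm = w.data.reshape(k * k * cin, -1)
    out = flat @ wm
    if b is not None:
        out += b.data
    out = out.reshape(n, ho, wo, -1)

    def backward(dy):
        dyf = dy.reshape(n * ho * wo, -1)
        dw = (flat.T @ dyf).reshape(w.data.shape)
        dcols = (dyf @ wm.T).reshape(cols.shape)
        dxp = _col2im(dcols, k, stride, xp.shape[1], xp.shape[2])
        dx = dxp[:, pt:pt + h, pl:pl + wd, :]
        grads = [(x, dx), (w, dw)]
        if b is not None:
            grads.append((b, dyf.sum(axis=0)))
        return grads

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents, backward)


def conv_transpose2d(x: Tensor, w: Parameter, b: Parameter | None,
                     stride: int = 2) -> Tensor:
    """Transposed convolution, output spatial dims = input * stride.

    w has shape (k, k, Cin, Cout); the output is cropped Keras-'same' style
    (the k - stride surplus rows/cols are dropped from the bottom/right).
    """
    n, h, wd, cin = x.data.shape
    k = w.data.shape[0]
    ho, wo = h * stride, wd * stride
    hf, wf = (h - 1) * stride + k, (wd - 1) * stride + k
    cols = np.tensordot(x.data, w.data, axes=([3], [2]))  # (N,H,W,k,k,Cout)
    full = _col2im(cols, k, stride, hf, wf)
    out = full[:, :ho, :wo, :]
    if b is not None:
        out = out + b.data

    def backward(dy):
        dyfull = np.zeros((n, hf, wf, dy.shape[-1]), dtype=dy.dtype)
        dyfull[:, :ho, :wo, :] = dy
        dcols = _im2col(dyfull, k, stride, h, wd)
        dx = np.tensordot(dcols, w.data, axes=([3, 4, 5], [0, 1, 3]))
        dw = np.tensordot(x.data, dcols,
                          axes=([0, 1, 2], [0, 1, 2])).transpose(1, 2, 0, 3)
        grads = [(x, dx), (w, dw)]
        if b is not None:
            grads.append((b, dy.sum(axis=(0, 1, 2))))
        return grads

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents, backward)


def batch_norm(x: Tensor, gamma: Parameter, beta: Parameter,
               running_mean: np.ndarray, running_var: np.ndarray,
               train: bool, momentum: float = 0.9, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    In training mode batch statistics are used and the running statistics
    (plain arrays, updated in place) track them with the given momentum.
    """
    if train:
        mu = x.data.mean(axis=(0, 1, 2))
        var = x.data.var(axis=(0, 1, 2))
        running_mean *= momentum
        running_mean += (1.0 - momentum) * mu
        running_var *= momentum
        running_var += (1.0 - momentum) * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = gamma.data * xhat + beta.data

    def backward(dy):
        dgamma = (dy * xhat).sum(axis=(0, 1, 2))
        dbeta = dy.sum(axis=(0, 1, 2))
        if train:
            m = dy.shape[0] * dy.shape[1] * dy.shape[2]
            dxhat = dy * gamma.data
            dx = (inv / m) * (m * dxhat - dxhat.sum(axis=(0, 1, 2))
                              - xhat * (dxhat * xhat).sum(axis=(0, 1, 2)))
        else:
            dx = dy * gamma.data * inv
        return [(x, dx.astype(x.data.dtype)), (gamma, dgamma), (beta, dbeta)]

    return Tensor(out.astype(x.data.dtype), (x, gamma, beta), backward)


def max_pool2(x: Tensor) -> Tensor:
    n, h, w, c = x.data.shape
    win = x.data.reshape(n, h // 2, 2, w // 2, 2, c)
    flat = win.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(dy):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
        dx = dflat.reshape(n, h // 2, w // 2, c, 2, 2).transpose(
            0, 1, 4, 2, 5, 3).reshape(n, h, w, c)
        return [(x, dx)]

    return Tensor(out, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling (row/column repetition)."""
    out = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def backward(dy):
        n, h, w, c = x.data.shape
        dx = dy.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4))
        return [(x, dx)]

    return Tensor(out, (x,), backward)


def concat(tensors) -> Tensor:
    tensors = list(tensors)
    if len(tensors) == 1:
        return tensors[0]
    out = np.concatenate([t.data for t in tensors], axis=-1)
    sizes = [t.data.shape[-1] for t in tensors]

    def backward(dy):
        grads, ofs = [], 0
        for t, s in zip(tensors, sizes):
            grads.append((t, dy[..., ofs:ofs + s]))
            ofs += s
        return grads

    return Tensor(out, tuple(tensors), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, (x,), lambda dy: [(x, dy * mask)])


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    return Tensor(out, (x,), lambda dy: [(x, dy * out * (1.0 - out))])
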