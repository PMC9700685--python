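"""Spatial ops (NHWC) for the autodiff engine.

Stride-1 convolutions use 'same' zero padding.  Transposed convolutions
are the exact adjoints of the corresponding stride-2 'same' convolutions,
so they double the spatial dimensions; they carry their own weights and
are the learned upsampling used by the decoder and the attention pyramid.

Bias addition and the activation are fused into each op: a layer call
materialises a single output tensor, and backward passes recompute cheap
quantities (zero-padding, im2col patches, logistic factors) instead of
caching them, keeping the peak memory of a training step low.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, _sigmoid

__all__ = [
    "conv2d_same",
    "depthwise_conv3x3_same",
    "conv_transpose2d",
    "dense",
    "maxpool2x2",
    "concat_channels",
    "bce_with_logits",
]


# --------------------------------------------------------------------------
# fused activations: forward returns (out, cache); backward maps the
# incoming gradient to the pre-activation gradient.
# --------------------------------------------------------------------------

def _act_forward(act, z):
    if act in (None, "linear"):
        return z, None
    if act == "swish":
        s = _sigmoid(z)
        return z * s, s                    # cache the logistic factor
    if act == "relu":
        return np.maximum(z, 0), None
    if act == "sigmoid":
        return _sigmoid(z), None
    raise ValueError(f"unknown activation {act!r}")


def _act_backward(act, g, out, cache):
    if act in (None, "linear"):
        return g
    if act == "swish":
        # d/dz[z*s] = s + z*s*(1-s) = s + out*(1-s), with s cached
        return g * (cache + out * (1.0 - cache))
    if act == "relu":
        return g * (out > 0)
    if act == "sigmoid":
        return g * out * (1.0 - out)
    raise ValueError(f"unknown activation {act!r}")


def _parents(x, w, b):
    return (x, w) if b is None else (x, w, b)


# --------------------------------------------------------------------------
# convolutions
# --------------------------------------------------------------------------

def _im2col(x, k):
    """(N,H,W,C) -> (N*H*W, k*k*C) patches under 'same' zero padding."""
    n, h, w, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    cols = np.empty((n, h, w, k * k, c), dtype=x.dtype)
    for u in range(k):
        for v in range(k):
            cols[:, :, :, u * k + v, :] = xp[:, u:u + h, v:v + w, :]
    return cols.reshape(n * h * w, k * k * c)


def _col2im(gcols, k, shape):
    """Adjoint of :func:`_im2col`."""
    n, h, w, c = shape
    p = k // 2
    gxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=gcols.dtype)
    g5 = gcols.reshape(n, h, w, k * k, c)
    for u in range(k):
        for v in range(k):
            gxp[:, u:u + h, v:v + w, :] += g5[:, :, :, u * k + v, :]
    return gxp[:, p:p + h, p:p + w, :]


def conv2d_same(x: Tensor, w: Tensor, b: Tensor | None = None,
                act: str | None = None) -> Tensor:
    """Stride-1 k×k convolution, 'same' padding; w has shape (k,k,Ci,Co)."""
    k, _, ci, co = w.data.shape
    n, h, ww, _ = x.data.shape
    wf = w.data.reshape(k * k * ci, co)
    if k == 1:
        z = x.data.reshape(-1, ci) @ wf
    else:
        z = _im2col(x.data, k) @ wf
    if b is not None:
        z += b.data
    z = z.reshape(n, h, ww, co)
    out_data, cache = _act_forward(act, z)
    out = Tensor(out_data, _parents(x, w, b))

    def bwd(g):
        gz = _act_backward(act, g, out_data, cache).reshape(-1, co)
        if b is not None and b.requires_grad:
            b._accumulate(gz.sum(axis=0))
        if x.requires_grad:
            gx = gz @ wf.T
            if k == 1:
                x._accumulate(gx.reshape(x.data.shape))
            else:
                x._accumulate(_col2im(gx, k, x.data.shape))
        if w.requires_grad:
            if k == 1:
                gw = x.data.reshape(-1, ci).T @ gz
            else:
                gw = _im2col(x.data, k).T @ gz
            w._accumulate(gw.reshape(w.data.shape))

    out._backward = bwd
    return out


def depthwise_conv3x3_same(x: Tensor, w: Tensor, b: Tensor | None = None,
                           act: str | None = None) -> Tensor:
    """Per-channel 3×3 convolution (channel multiplier 1); w is (3,3,C)."""
    n, h, ww, c = x.data.shape
    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (0, 0)))
    z = np.zeros_like(x.data)
    tmp = np.empty_like(x.data)
    for u in range(3):
        for v in range(3):
            np.multiply(xp[:, u:u + h, v:v + ww, :], w.data[u, v], out=tmp)
            z += tmp
    del xp, tmp
    if b is not None:
        z += b.data
    out_data, cache = _act_forward(act, z)
    out = Tensor(out_data, _parents(x, w, b))

    def bwd(g):
        gz = _act_backward(act, g, out_data, cache)
        if b is not None and b.requires_grad:
            b._accumulate(gz.sum(axis=(0, 1, 2)))
        xp2 = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (0, 0)))
        tmp2 = np.empty_like(gz)
        if x.requires_grad:
            gxp = np.zeros_like(xp2)
            for u in range(3):
                for v in range(3):
                    np.multiply(gz, w.data[u, v], out=tmp2)
                    gxp[:, u:u + h, v:v + ww, :] += tmp2
            x._accumulate(gxp[:, 1:1 + h, 1:1 + ww, :])
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for u in range(3):
                for v in range(3):
                    np.multiply(gz, xp2[:, u:u + h, v:v + ww, :], out=tmp2)
                    gw[u, v] = tmp2.sum(axis=(0, 1, 2))
            w._accumulate(gw)

    out._backward = bwd
    return out


def _tap_slices(k, size_out):
    """Input/output slices of each transposed-conv tap along one axis."""
    off = 1 if k == 3 else 0
    out = {}
    for u in range(k):
        o = u - off
        if o < 0:
            # input pixel i lands at 2i-1: rows 1..H-1 -> 1,3,..,2H-3
            out[u] = (slice(1, None), slice(1, size_out - 2, 2))
        else:
            out[u] = (slice(None), slice(o, size_out, 2))
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     act: str | None = None) -> Tensor:
    """Stride-2 transposed convolution, kernel 2 or 3; (N,H,W,Ci)->(N,2H,2W,Co).

    Defined as the adjoint of the stride-2 'same' convolution with the same
    kernel: each input pixel scatters a k×k stamp centred on its doubled
    location (kernel 3) or paints its 2×2 block (kernel 2).
    """
    k, _, ci, co = w.data.shape
    if k not in (2, 3):
        raise ValueError("conv_transpose2d supports kernels 2 and 3")
    n, h, ww, _ = x.data.shape
    ho, wo = 2 * h, 2 * ww
    z = np.zeros((n, ho, wo, co), dtype=x.data.dtype)
    x2 = x.data.reshape(-1, ci)
    row_slices = _tap_slices(k, ho)
    col_slices = _tap_slices(k, wo)
    for u in range(k):
        xs_r, ys_r = row_slices[u]
        for v in range(k):
            xs_c, ys_c = col_slices[v]
            contrib = (x2 @ w.data[u, v]).reshape(n, h, ww, co)
            z[:, ys_r, ys_c, :] += contrib[:, xs_r, xs_c, :]
    if b is not None:
        z += b.data
    out_data, cache = _act_forward(act, z)
    out = Tensor(out_data, _parents(x, w, b))

    def bwd(g):
        gz = _act_backward(act, g, out_data, cache)
        if b is not None and b.requires_grad:
            b._accumulate(gz.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for u in range(k):
                xs_r, ys_r = row_slices[u]
                for v in range(k):
                    xs_c, ys_c = col_slices[v]
                    gs = gz[:, ys_r, ys_c, :]
                    gx[:, xs_r, xs_c, :] += (
                        gs.reshape(-1, co) @ w.data[u, v].T
                    ).reshape(gs.shape[:3] + (ci,))
            x._accumulate(gx)
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for u in range(k):
                xs_r, ys_r = row_slices[u]
                for v in range(k):
                    xs_c, ys_c = col_slices[v]
                    xs = x.data[:, xs_r, xs_c, :].reshape(-1, ci)
                    gs = gz[:, ys_r, ys_c, :].reshape(-1, co)
                    gw[u, v] = xs.T @ gs
            w._accumulate(gw)

    out._backward = bwd
    return out


def dense(x: Tensor, w: Tensor, b: Tensor | None = None,
          act: str | None = None) -> Tensor:
    """(.., Ci) @ (Ci, Co) + b with fused activation."""
    ci, co = w.data.shape
    x2 = x.data.reshape(-1, ci)
    z = x2 @ w.data
    if b is not None:
        z += b.data
    z = z.reshape(x.data.shape[:-1] + (co,))
    out_data, cache = _act_forward(act, z)
    out = Tensor(out_data, _parents(x, w, b))

    def bwd(g):
        gz = _act_backward(act, g, out_data, cache).reshape(-1, co)
        if b is not None and b.requires_grad:
            b._accumulate(gz.sum(axis=0))
        if x.requires_grad:
            x._accumulate((gz @ w.data.T).reshape(x.data.shape))
        if w.requires_grad:
            w._accumulate(x2.T @ gz)

    out._backward = bwd
    return out


# --------------------------------------------------------------------------
# pooling, concatenation, loss
# --------------------------------------------------------------------------

def maxpool2x2(x: Tensor) -> Tensor:
    """2×2 max pooling with stride 2; ties route the gradient to one pixel."""
    n, h, w, c = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    xr = x.data.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    xr = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, c, 4)
    idx = xr.argmax(axis=-1)
    out = Tensor(np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0], (x,))

    def bwd(g):
        if x.requires_grad:
            gr = np.zeros((n, h // 2, w // 2, c, 4), dtype=g.dtype)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gr = gr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
            x._accumulate(np.ascontiguousarray(gr).reshape(n, h, w, c))

    out._backward = bwd
    return out


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[-1]
    out = Tensor(np.concatenate([a.data, b.data], axis=-1), (a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g[..., :ca])
        if b.requires_grad:
            b._accumulate(g[..., ca:])

    out._backward = bwd
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Pixelwise-mean binary cross-entropy, numerically stable in the logits."""
    z = logits.data
    t = np.asarray(targets, dtype=z.dtype)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(np.asarray(loss.mean(), dtype=z.dtype), (logits,))

    def bwd(g):
        if logits.requires_grad:
            logits._accumulate(g * (_sigmoid(z) - t) / z.size)

    out._backward = bwd
    return out
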