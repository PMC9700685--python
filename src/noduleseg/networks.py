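"""Network assembly: the pyramid-attention segmenter and a U-Net baseline.

The main network is a compact encoder/decoder for 64×64 single-channel
nodule patches: two encoder stages of two inverted residual blocks each
(32 then 64 filters) with 2×2 max-pooling, a feature-pyramid-attention
bridge at 16×16×64, and a mirrored decoder whose upsampling layers are
3×3 stride-2 transposed convolutions (the second one halves the channel
count, per the architecture's feature-map table).  A final 1×1
convolution with a logistic activation yields a per-pixel nodule
probability.  The default configuration holds 891,713 trainable
parameters; see ``scripts/calibrate_params.py`` for how the
under-determined hyperparameters were fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attention import FeaturePyramidAttention, PyramidConfig
from .blocks import InvertedResidual, IRBlockConfig
from .nn import Conv2D, ConvTranspose2D, Module, Tensor
from .nn.layers import DTYPE
from .nn.ops import concat_channels, maxpool2x2

__all__ = [
    "NetworkSpec", "ShapeTrace", "PyramidAttentionNet", "UNet",
    "build_segmenter", "build_unet_baseline", "count_trainable_parameters",
    "trace_shapes", "forward", "binarize", "save_weights", "load_weights",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Hyperparameters of the pyramid-attention segmenter."""

    input_shape: tuple = (64, 64, 1)
    encoder_filters: tuple = (32, 64)
    decoder_filters: tuple = (64, 32)
    ir_kernel: int = 3
    ir_stride: int = 1
    se_ratio: float = 0.25
    expansion: int = 7
    bridge: PyramidConfig = field(default_factory=PyramidConfig)
    final_activation: str = "sigmoid"

    def __post_init__(self):
        if tuple(self.decoder_filters) != tuple(reversed(self.encoder_filters)):
            raise ValueError("decoder filters must mirror the encoder")
        if self.bridge.channels != self.encoder_filters[-1]:
            raise ValueError("bridge channels must equal the deepest encoder "
                             "filter count")
        h, w, c = self.input_shape
        div = 1 << (len(self.encoder_filters) + self.bridge.levels)
        if h % div or w % div:
            raise ValueError(f"input spatial dims must be divisible by {div}")


@dataclass
class ShapeTrace:
    """Ordered (level, operator, H×W×C) rows of a probe forward pass."""

    rows: list

    @property
    def shapes(self):
        return [shape for _, _, shape in self.rows]

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.rows, columns=["level", "operator", "shape"])

    def to_csv(self, path):
        df = self.to_dataframe()
        df["shape"] = df["shape"].map(lambda s: "x".join(map(str, s)))
        df.to_csv(path, index=False)


class PyramidAttentionNet(Module):
    def __init__(self, spec: NetworkSpec, rng, dtype=DTYPE):
        self.spec = spec

        def stage(in_c, f):
            mk = lambda ci: InvertedResidual(
                IRBlockConfig(ci, f, spec.ir_kernel, spec.ir_stride,
                              spec.se_ratio, spec.expansion), rng, dtype)
            return [mk(in_c), mk(f)]

        f1, f2 = spec.encoder_filters
        in_c = spec.input_shape[-1]
        self.encoder1 = stage(in_c, f1)
        self.encoder2 = stage(f1, f2)
        self.bridge = FeaturePyramidAttention(spec.bridge, rng, dtype)
        d1, d2 = spec.decoder_filters
        self.up1 = ConvTranspose2D(3, spec.bridge.channels, d1, rng, dtype=dtype)
        self.decoder1 = stage(d1 + f2, d1)
        self.up2 = ConvTranspose2D(3, d1, d2, rng, dtype=dtype)
        self.decoder2 = stage(d2 + f1, d2)
        self.head = Conv2D(1, d2, 1, rng, activation=None, dtype=dtype)

    def logits(self, x: Tensor, trace: list | None = None) -> Tensor:
        def rec(level, name, t):
            if trace is not None:
                trace.append((level, name, t.data.shape[1:]))
            return t

        y = x
        for blk in self.encoder1:
            y = blk(y)
        skip1 = rec(1, "Encoder block 1", y)
        y = rec(1, "Maxpooling layer 1", maxpool2x2(y))
        for blk in self.encoder2:
            y = blk(y)
        skip2 = rec(2, "Encoder block 2", y)
        y = rec(2, "Maxpooling layer 2", maxpool2x2(y))
        y = rec(3, "Pyramidal attention block", self.bridge(y))
        y = rec(4, "Upsampling layer 1", self.up1(y))
        y = rec(4, "Concatenation", concat_channels(y, skip2))
        for blk in self.decoder1:
            y = blk(y)
        y = rec(4, "Decoder block 1", y)
        y = rec(5, "Upsampling layer 2", self.up2(y))
        y = rec(5, "Concatenation", concat_channels(y, skip1))
        for blk in self.decoder2:
            y = blk(y)
        y = rec(5, "Decoder block 2", y)
        return rec(6, "Convolutional layer (1 x 1)", self.head(y))

    def __call__(self, x: Tensor) -> Tensor:
        return self.logits(x).sigmoid()


class UNet(Module):
    """Classic contracting/expanding U-Net baseline with double 3×3 convs."""

    def __init__(self, depth: int, base_filters: int, rng, in_channels=1,
                 dtype=DTYPE):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        if 64 % (1 << depth):
            raise ValueError("input size 64 must be divisible by 2**depth")
        self.depth = depth
        conv = lambda ci, co: Conv2D(3, ci, co, rng, activation="relu",
                                     dtype=dtype)
        self.enc = []
        c = in_channels
        for lvl in range(depth):
            f = base_filters << lvl
            self.enc.append([conv(c, f), conv(f, f)])
            c = f
        fb = base_filters << depth
        self.bottom = [conv(c, fb), conv(fb, fb)]
        self.ups, self.dec = [], []
        c = fb
        for lvl in reversed(range(depth)):
            f = base_filters << lvl
            self.ups.append(ConvTranspose2D(2, c, f, rng, dtype=dtype))
            self.dec.append([conv(2 * f, f), conv(f, f)])
            c = f
        self.head = Conv2D(1, c, 1, rng, activation=None, dtype=dtype)

    def layers(self):  # flatten the nested stage lists for Module.parameters
        for group in (*self.enc, self.bottom, self.ups, *self.dec, [self.head]):
            yield from group

    def logits(self, x: Tensor) -> Tensor:
        skips = []
        y = x
        for c1, c2 in self.enc:
            y = c2(c1(y))
            skips.append(y)
            y = maxpool2x2(y)
        c1, c2 = self.bottom
        y = c2(c1(y))
        for up, (d1, d2) in zip(self.ups, self.dec):
            y = concat_channels(up(y), skips.pop())
            y = d2(d1(y))
        return self.head(y)

    def __call__(self, x: Tensor) -> Tensor:
        return self.logits(x).sigmoid()


# --------------------------------------------------------------------------
# functional surface
# --------------------------------------------------------------------------

def build_segmenter(spec: NetworkSpec | None = None, seed: int = 0,
                    dtype=DTYPE) -> PyramidAttentionNet:
    """Build the pyramid-attention segmenter, He-normal initialised."""
    return PyramidAttentionNet(spec or NetworkSpec(),
                               np.random.default_rng(seed), dtype)


def build_unet_baseline(depth: int = 4, base_filters: int = 64,
                        seed: int = 0, dtype=DTYPE) -> UNet:
    return UNet(depth, base_filters, np.random.default_rng(seed), dtype=dtype)


def count_trainable_parameters(net: Module) -> int:
    return net.n_params


def trace_shapes(net: PyramidAttentionNet,
                 input_shape: tuple | None = None) -> ShapeTrace:
    """Probe forward pass recording each named operator's output H×W×C."""
    shape = tuple(input_shape or net.spec.input_shape)
    trace: list = []
    net.logits(Tensor(np.zeros((1,) + shape, dtype=DTYPE)), trace=trace)
    return ShapeTrace(trace)


def forward(net: Module, patch: np.ndarray) -> np.ndarray:
    """Inference: nodule-probability map for one patch or a batch.

    Accepts (H, W), (H, W, 1) or (N, H, W, 1); the output matches the
    input's leading shape with values strictly inside (0, 1).
    """
    arr = np.asarray(patch, dtype=DTYPE)
    squeeze2d = arr.ndim == 2
    if squeeze2d:
        arr = arr[..., None]
    squeeze_batch = arr.ndim == 3
    if squeeze_batch:
        arr = arr[None]
    expected = tuple(getattr(net, "spec", NetworkSpec()).input_shape)
    if arr.ndim != 4 or arr.shape[1:] != expected:
        raise ValueError(f"expected input of shape {expected}, "
                         f"got {np.asarray(patch).shape}")
    prob = net(Tensor(arr)).data
    if squeeze_batch:
        prob = prob[0]
    if squeeze2d:
        prob = prob[..., 0]
    return prob


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map to a {0,1} mask (pixel=1 iff p >= t)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    prob = np.asarray(prob_map)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    return (prob >= threshold).astype(np.uint8)


def save_weights(net: Module, path):
    np.savez_compressed(path, **{f"p{i}": p.data
                                 for i, p in enumerate(net.parameters())})


def load_weights(net: Module, path):
    with np.load(path) as data:
        params = net.parameters()
        if len(data.files) != len(params):
            raise ValueError("checkpoint does not match the network")
        for i, p in enumerate(params):
            arr = data[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint does not match the network")
            p.data = arr.astype(p.data.dtype)
    return net
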