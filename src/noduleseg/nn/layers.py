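"""Parameterised layers: convolutions, dense layers, He-normal init.

Weight layout is (k, k, Ci, Co) for convolutions, (3, 3, C) for the
depthwise convolution and (Ci, Co) for dense layers.  Every layer carries
a bias, and the activation is fused into the layer's op.  Initialisation
is He-normal (zero-mean normal with variance 2/fan_in), drawn from the
``numpy.random.Generator`` handed to the constructor so that a network
build is fully reproducible from one seed.
"""

from __future__ import annotations

import numpy as np

from . import ops
from .tensor import Parameter, Tensor

DTYPE = np.float32

_ACTIVATIONS = (None, "linear", "swish", "sigmoid", "relu")


def he_normal(rng: np.random.Generator, shape, fan_in: int, dtype=DTYPE):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class Layer:
    """Base class: parameter registry plus a fused activation."""

    def __init__(self, activation=None):
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.params: list[Parameter] = []

    def _register(self, *params):
        self.params.extend(params)
        return params

    @property
    def n_params(self) -> int:
        return sum(p.data.size for p in self.params)

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2D(Layer):
    """k×k stride-1 'same' convolution with bias."""

    def __init__(self, kernel: int, in_channels: int, out_channels: int,
                 rng: np.random.Generator, activation=None, dtype=DTYPE):
        super().__init__(activation)
        fan_in = kernel * kernel * in_channels
        self.w, self.b = self._register(
            Parameter(he_normal(rng, (kernel, kernel, in_channels, out_channels),
                                fan_in, dtype)),
            Parameter(np.zeros(out_channels, dtype=dtype)),
        )

    def forward(self, x):
        return ops.conv2d_same(x, self.w, self.b, act=self.activation)


class DepthwiseConv2D(Layer):
    """3×3 per-channel convolution, channel multiplier 1, with bias."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 activation=None, dtype=DTYPE):
        super().__init__(activation)
        self.w, self.b = self._register(
            Parameter(he_normal(rng, (3, 3, channels), 9, dtype)),
            Parameter(np.zeros(channels, dtype=dtype)),
        )

    def forward(self, x):
        return ops.depthwise_conv3x3_same(x, self.w, self.b,
                                          act=self.activation)


class ConvTranspose2D(Layer):
    """Stride-2 learned upsampling (kernel 2 or 3), doubling H and W."""

    def __init__(self, kernel: int, in_channels: int, out_channels: int,
                 rng: np.random.Generator, activation=None, dtype=DTYPE):
        super().__init__(activation)
        fan_in = kernel * kernel * in_channels
        self.w, self.b = self._register(
            Parameter(he_normal(rng, (kernel, kernel, in_channels, out_channels),
                                fan_in, dtype)),
            Parameter(np.zeros(out_channels, dtype=dtype)),
        )

    def forward(self, x):
        return ops.conv_transpose2d(x, self.w, self.b, act=self.activation)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, activation=None, dtype=DTYPE):
        super().__init__(activation)
        self.w, self.b = self._register(
            Parameter(he_normal(rng, (in_features, out_features), in_features,
                                dtype)),
            Parameter(np.zeros(out_features, dtype=dtype)),
        )

    def forward(self, x):
        return ops.dense(x, self.w, self.b, act=self.activation)


class Module:
    """A container whose trainable parameters are gathered recursively."""

    def layers(self):
        for v in vars(self).values():
            if isinstance(v, (Layer, Module)):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, (Layer, Module)):
                        yield item

    def parameters(self) -> list[Parameter]:
        out = []
        for child in self.layers():
            out.extend(child.params if isinstance(child, Layer)
                       else child.parameters())
        return out

    @property
    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())
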