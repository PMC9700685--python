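"""Building blocks of the segmentation network and the convolution cost model.

The encoder/decoder stages are built from *inverted residual blocks*
(narrow–wide–narrow bottlenecks): a 1×1 expansion convolution widens the
representation, a 3×3 depthwise convolution mixes spatially at low cost, a
squeeze-excitation gate reweights channels, and a linear 1×1 projection
narrows back to the block's filter count.  A skip connection joins the
narrow ends whenever stride is 1 and the channel counts agree.

The cost model quantifies why the depthwise factorisation is cheap: a
standard convolution over an Hi×Wi×Di map with Dj output channels and an
f×f filter costs Hi·Wi·Di·Dj·f², while the depthwise-separable variant
costs Hi·Wi·Di·(f² + Dj) — a reduction by f²·Dj/(f² + Dj), which for
f = 3 approaches 9× as Dj grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn import Conv2D, Dense, DepthwiseConv2D, Module, Tensor
from .nn.layers import DTYPE

__all__ = [
    "swish",
    "ConvCostSpec",
    "conv_cost_standard",
    "conv_cost_depthwise",
    "cost_reduction_factor",
    "IRBlockConfig",
    "SqueezeExcite",
    "InvertedResidual",
]


def swish(x):
    """Elementwise x·σ(x); accepts scalars, arrays or engine tensors."""
    if isinstance(x, Tensor):
        return x.swish()
    x = np.asarray(x, dtype=float)
    return x / (1.0 + np.exp(-x))


# --------------------------------------------------------------------------
# cost model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvCostSpec:
    """Dimensions entering the convolution cost formulas.

    Hi, Wi: spatial size of the input feature map (pixels);
    Di, Dj: input and output channel counts; f: square filter side.
    """

    Hi: int
    Wi: int
    Di: int
    Dj: int
    f: int

    def __post_init__(self):
        for name in ("Hi", "Wi", "Di", "Dj", "f"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")


def conv_cost_standard(spec: ConvCostSpec) -> int:
    """Multiply count of a standard convolution: Hi·Wi·Di·Dj·f²."""
    return spec.Hi * spec.Wi * spec.Di * spec.Dj * spec.f * spec.f


def conv_cost_depthwise(spec: ConvCostSpec) -> int:
    """Multiply count of a depthwise-separable convolution: Hi·Wi·Di·(f²+Dj)."""
    return spec.Hi * spec.Wi * spec.Di * (spec.f ** 2 + spec.Dj)


def cost_reduction_factor(spec: ConvCostSpec) -> float:
    """Standard/depthwise cost ratio f²·Dj/(f²+Dj); bounded above by f²."""
    return spec.f ** 2 * spec.Dj / (spec.f ** 2 + spec.Dj)


# --------------------------------------------------------------------------
# inverted residual block
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IRBlockConfig:
    """Hyperparameters of one inverted residual block.

    ``expansion`` multiplies ``filters`` (the narrow output width) to set
    the wide middle width; the squeeze-excitation bottleneck holds
    ``ceil(se_ratio · filters)`` units.  The default expansion of 7 is the
    calibrated value under which the full default network's trainable
    parameter count matches the published architecture exactly (see
    ``scripts/calibrate_params.py``).
    """

    in_channels: int
    filters: int
    kernel: int = 3
    stride: int = 1
    se_ratio: float = 0.25
    expansion: int = 7

    def __post_init__(self):
        if self.in_channels < 1 or self.filters < 1:
            raise ValueError("channel counts must be positive")
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ValueError("kernel must be odd and positive")
        if self.kernel != 3:
            raise ValueError("only 3x3 depthwise kernels are implemented")
        if self.stride != 1:
            raise ValueError("only stride 1 is implemented; downsampling is "
                             "done by max pooling")
        if not 0 < self.se_ratio <= 1:
            raise ValueError("se_ratio must lie in (0, 1]")
        if self.expansion < 1:
            raise ValueError("expansion must be a positive integer")
        if self.se_units < 1:
            raise ValueError("se_ratio too small for the filter count")

    @property
    def expanded(self) -> int:
        return self.expansion * self.filters

    @property
    def se_units(self) -> int:
        return max(1, math.ceil(self.se_ratio * self.filters))


class SqueezeExcite(Module):
    """Channel attention: GAP → bottleneck dense (swish) → dense gate (σ).

    Each channel of the input is rescaled by a scalar in (0, 1) computed
    from the channel's global average, so spatial dims and channel count
    are unchanged.
    """

    def __init__(self, channels: int, units: int, rng, dtype=DTYPE):
        if units < 1:
            raise ValueError("SE bottleneck needs at least one unit")
        self.reduce = Dense(channels, units, rng, activation="swish", dtype=dtype)
        self.gate = Dense(units, channels, rng, activation="sigmoid", dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        g = self.gate(self.reduce(x.global_avg_pool()))
        return x * g


class InvertedResidual(Module):
    """Expand (1×1, swish) → depthwise 3×3 (swish) → SE → project (1×1, linear).

    The identity skip is added iff stride is 1 and the input channel count
    equals ``filters``; spatial dimensions are always preserved.
    """

    def __init__(self, cfg: IRBlockConfig, rng, dtype=DTYPE):
        self.cfg = cfg
        e = cfg.expanded
        self.expand = Conv2D(1, cfg.in_channels, e, rng, activation="swish",
                             dtype=dtype)
        self.depthwise = DepthwiseConv2D(e, rng, activation="swish", dtype=dtype)
        self.se = SqueezeExcite(e, cfg.se_units, rng, dtype=dtype)
        self.project = Conv2D(1, e, cfg.filters, rng, activation=None,
                              dtype=dtype)
        self.use_skip = cfg.stride == 1 and cfg.in_channels == cfg.filters

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.shape[-1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, "
                f"got {x.data.shape[-1]}")
        y = self.project(self.se(self.depthwise(self.expand(x))))
        return y + x if self.use_skip else y
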