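"""Feature-pyramid-attention bridge between encoder and decoder.

The block computes a pixel-wise attention map from a three-level
convolution pyramid (7×7, 5×5, 3×3 filters at progressively halved
resolution, so the filters see large, medium and small context) and
multiplies it onto a 1×1-convolved main branch.  Shapes are preserved:
a 16×16×64 bridge input yields a 16×16×64 output.

Down the pyramid each level is max-pooled 2× and convolved; the deepest
level receives one extra 3×3 convolution.  Up the pyramid each level is
upsampled with a learned 2×2 stride-2 transposed convolution and fused
with the finer level by addition.  This fusion order (deepest first,
addition, learned upsampling) together with the extra bottom convolution
is part of the calibrated default configuration (see
``scripts/calibrate_params.py``).
"""

from __future__ import annotations

from dataclasses import dataclass

from .nn import Conv2D, ConvTranspose2D, Module, Tensor
from .nn.layers import DTYPE
from .nn.ops import maxpool2x2

__all__ = ["PyramidConfig", "FeaturePyramidAttention", "feature_pyramid_attention"]


@dataclass(frozen=True)
class PyramidConfig:
    """Configuration of the attention pyramid.

    kernel_sizes: filter sides of the pyramid levels, strictly decreasing
    and odd; channels: channel count of the bridge (64 in the default
    network); extra_bottom_conv: one additional 3×3 convolution at the
    deepest level; upsample: 'tconv' (learned 2×2 stride-2 transposed
    convolution, the calibrated default) or 'nearest'; gap_branch:
    optional global-average-pooling shortcut added to the attention map;
    main_conv_on: where the 1×1 convolution sits — 'main' (default) or
    'attention'.
    """

    kernel_sizes: tuple = (7, 5, 3)
    channels: int = 64
    extra_bottom_conv: bool = True
    upsample: str = "tconv"
    gap_branch: bool = False
    main_conv_on: str = "main"

    def __post_init__(self):
        ks = tuple(self.kernel_sizes)
        if any(k % 2 == 0 for k in ks) or list(ks) != sorted(ks, reverse=True) \
                or len(set(ks)) != len(ks):
            raise ValueError("kernel sizes must be odd and strictly decreasing")
        if self.channels < 1:
            raise ValueError("channels must be positive")
        if self.upsample not in ("tconv", "nearest"):
            raise ValueError("upsample must be 'tconv' or 'nearest'")
        if self.main_conv_on not in ("main", "attention"):
            raise ValueError("main_conv_on must be 'main' or 'attention'")

    @property
    def levels(self) -> int:
        return len(self.kernel_sizes)


class FeaturePyramidAttention(Module):
    def __init__(self, cfg: PyramidConfig, rng, dtype=DTYPE):
        self.cfg = cfg
        c = cfg.channels
        self.main = Conv2D(1, c, c, rng, activation=None, dtype=dtype)
        self.down = [Conv2D(k, c, c, rng, activation="swish", dtype=dtype)
                     for k in cfg.kernel_sizes]
        self.bottom = (Conv2D(3, c, c, rng, activation="swish", dtype=dtype)
                       if cfg.extra_bottom_conv else None)
        if cfg.upsample == "tconv":
            self.up = [ConvTranspose2D(2, c, c, rng, activation=None,
                                       dtype=dtype)
                       for _ in cfg.kernel_sizes]
        else:
            self.up = []
        self.gap = (Conv2D(1, c, c, rng, activation=None, dtype=dtype)
                    if cfg.gap_branch else None)

    def __call__(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        n, h, w, c = x.data.shape
        if c != cfg.channels:
            raise ValueError(f"expected {cfg.channels} channels, got {c}")
        if h % (1 << cfg.levels) or w % (1 << cfg.levels):
            raise ValueError(
                f"spatial dims must be divisible by {1 << cfg.levels}")

        feats = []
        y = x
        for conv in self.down:
            y = conv(maxpool2x2(y))
            feats.append(y)
        if self.bottom is not None:
            feats[-1] = self.bottom(feats[-1])

        att = feats[-1]
        for lvl in range(cfg.levels - 1, -1, -1):
            att = self._upsample(att, lvl)
            if lvl > 0:
                att = att + feats[lvl - 1]
        if self.gap is not None:
            att = att + self.gap(x.global_avg_pool())

        if cfg.main_conv_on == "main":
            return self.main(x) * att
        return x * self.main(att)

    def _upsample(self, t: Tensor, lvl: int) -> Tensor:
        if self.cfg.upsample == "tconv":
            return self.up[lvl](t)
        import numpy as np
        data = np.repeat(np.repeat(t.data, 2, axis=1), 2, axis=2)
        out = Tensor(data, (t,))

        def bwd(g):
            if t.requires_grad:
                n, h, w, c = t.data.shape
                t._accumulate(g.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4)))

        out._backward = bwd
        return out


def feature_pyramid_attention(fm, cfg: PyramidConfig | None = None, *,
                              rng=None, block: FeaturePyramidAttention | None = None):
    """Functional wrapper: apply a (new or given) FPA block to a feature map.

    ``fm`` may be an engine tensor or a numpy H×W×C / N×H×W×C array; the
    result has the same form and shape as the input.
    """
    import numpy as np

    if block is None:
        cfg = cfg or PyramidConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        block = FeaturePyramidAttention(cfg, rng)
    if isinstance(fm, Tensor):
        return block(fm)
    arr = np.asarray(fm, dtype=np.float32)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    out = block(Tensor(arr)).data
    return out[0] if squeeze else out
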