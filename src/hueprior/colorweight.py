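"""ColorWeight: color-prior feature module over the masked hue plane.

The module turns the masked, normalized hue channel into (a) a compact
64-dimensional projection suitable for residual injection into the hyperedge
generator and (b) a global statistics vector fusing max/mean responses of
the refined features with max/mean of the raw hue input.

Pipeline for a 640×640 input:

1. three convolution stages, ``(1,640,640) → (32,320,320) → (64,80,80) →
   (64,40,40)`` (strides 2, 4, 2), each followed by batch norm and SiLU;
2. global average pooling of the final block to a 64-vector, then a
   ``Linear(64, 64)`` projection (``proj``);
3. statistics: per-channel spatial max and mean of the final block, plus max
   and mean of the raw input broadcast-embedded to 64 channels by a learned
   1→64 map, concatenated to a 256-vector (``stats``) and mapped by
   ``Linear(256, 64)`` (``stat_proj``).

The flow generalizes to any input side divisible by 16 (side → side/2 →
side/8 → side/16).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import BatchNorm2d, Conv2d, Linear, silu

STAGE_CHANNELS = (32, 64, 64)
STAGE_STRIDES = (2, 4, 2)
STAGE_KERNELS = (3, 5, 3)  # stride-4 stage gets the larger receptive field
FEAT_CHANNELS = 64
STAT_DIM = 4 * FEAT_CHANNELS  # max/mean of features + max/mean of embedded input


@dataclass
class ColorWeightOutput:
    """Forward-pass products of the ColorWeight module."""

    proj: np.ndarray       # (64,) projection for residual injection
    stats: np.ndarray      # (256,) concatenated statistics, pre linear map
    stat_proj: np.ndarray  # (64,) statistics after the final linear map
    feat_map: np.ndarray   # (64, side/16, side/16) refined feature block

    @classmethod
    def zeros(cls) -> "ColorWeightOutput":
        """All-zero output: disables color injection downstream exactly."""
        return cls(
            proj=np.zeros(FEAT_CHANNELS),
            stats=np.zeros(STAT_DIM),
            stat_proj=np.zeros(FEAT_CHANNELS),
            feat_map=np.zeros((FEAT_CHANNELS, 1, 1)),
        )


def statistical_summary(feat: np.ndarray) -> np.ndarray:
    """Per-channel spatial max then spatial mean, concatenated to ``2c``."""
    feat = np.asarray(feat, dtype=np.float64)
    if feat.ndim != 3 or feat.shape[1] < 1 or feat.shape[2] < 1:
        raise ValueError(f"expected (C, H, W) with H, W >= 1, got {feat.shape}")
    return np.concatenate([feat.max(axis=(1, 2)), feat.mean(axis=(1, 2))])


class ColorWeight:
    """Seeded forward-only ColorWeight module.

    Parameters
    ----------
    seed
        Seeds the fan-in uniform weight initialization; identical seeds give
        bitwise-identical modules.
    """

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.stages = []
        in_ch = 1
        for out_ch, stride, kernel in zip(STAGE_CHANNELS, STAGE_STRIDES, STAGE_KERNELS):
            conv = Conv2d(in_ch, out_ch, kernel, stride, kernel // 2, rng)
            self.stages.append((conv, BatchNorm2d(out_ch)))
            in_ch = out_ch
        self.head_proj = Linear(FEAT_CHANNELS, FEAT_CHANNELS, rng)
        self.input_embed = Linear(1, FEAT_CHANNELS, rng)  # scalar stat -> 64
        self.stat_head = Linear(STAT_DIM, FEAT_CHANNELS, rng)

    def __call__(self, hue_input: np.ndarray) -> ColorWeightOutput:
        return self.forward(hue_input)

    def forward(self, hue_input: np.ndarray) -> ColorWeightOutput:
        """Run the module on a masked normalized hue plane.

        ``hue_input`` is ``(1, side, side)`` (or ``(side, side)``) with values
        in [0, 1]; side must be divisible by 16.
        """
        x = np.asarray(hue_input, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[0] != 1:
            raise ValueError(f"expected a single-plane input, got shape {x.shape}")
        side = x.shape[1]
        if x.shape[1] != x.shape[2] or side % 16 != 0:
            raise ValueError(
                f"input side must be square and divisible by 16, got {x.shape[1:]}"
            )

        feat = x
        for conv, bn in self.stages:
            feat = silu(bn(conv(feat)))

        pooled = feat.mean(axis=(1, 2))               # global average pool -> 64
        proj = self.head_proj(pooled)

        feat_stats = statistical_summary(feat)        # [max(64); mean(64)]
        in_max = self.input_embed(np.array([x.max()]))   # scalar -> 64
        in_mean = self.input_embed(np.array([x.mean()]))
        stats = np.concatenate([feat_stats, in_max, in_mean])
        stat_proj = self.stat_head(stats)

        return ColorWeightOutput(proj=proj, stats=stats, stat_proj=stat_proj,
                                 feat_map=feat)
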