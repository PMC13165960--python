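"""Environment-aware hue mask and four-channel input composition.

The detector's fourth input plane is a masked, normalized hue channel: each
pixel keeps ``hue/180`` when its half-scale hue falls inside the
environment's retained interval(s) (endpoints inclusive), and is zeroed
otherwise. The mask therefore carries graded hue information on retained
pixels, not a binary indicator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .hsv_color_db import N_HUE_BINS, extract_hue_channel, normalize_intervals

logger = logging.getLogger(__name__)

#: Preset hue intervals (half-scale units). Warm caps in greenhouse and
#: semi-open sheds sit in [4, 38]; LED-lit automated houses shift fruit
#: bodies into the cool [110, 155] band. The "merged" preset widens the cool
#: band's lower edge to 78, a union list used when the environment is unknown.
INTERVAL_PRESETS: dict[str, list[list[int]]] = {
    "greenhouse": [[4, 38]],
    "semi_open": [[4, 38]],
    "automated": [[110, 155]],
    "merged": [[4, 38], [78, 155]],
}


class UnknownEnvironmentError(KeyError):
    """Environment tag has no preset and no override was given."""


@dataclass
class FourChannelImage:
    """RGB planes scaled to [0, 1] plus the masked normalized hue plane."""

    rgb: np.ndarray        # (3, H, W) in [0, 1]
    hue_mask: np.ndarray   # (H, W) in [0, 1], 0 outside the intervals

    @property
    def height(self) -> int:
        return self.rgb.shape[1]

    @property
    def width(self) -> int:
        return self.rgb.shape[2]

    def stacked(self) -> np.ndarray:
        """All four planes as one (4, H, W) array."""
        return np.concatenate([self.rgb, self.hue_mask[None]], axis=0)


def select_intervals(environment: str,
                     override: Sequence[Sequence[int]] | None = None) -> list[list[int]]:
    """Hue intervals for an environment tag, or an explicit override."""
    if override is not None:
        return normalize_intervals(override)
    try:
        return [list(iv) for iv in INTERVAL_PRESETS[environment]]
    except KeyError:
        raise UnknownEnvironmentError(
            f"no interval preset for environment {environment!r}; "
            f"known tags: {sorted(INTERVAL_PRESETS)}"
        ) from None


def interval_membership(hue: np.ndarray, intervals: Iterable[Sequence[int]]) -> np.ndarray:
    """Boolean plane: hue inside any [lo, hi] interval (inclusive ends)."""
    hue = np.asarray(hue)
    inside = np.zeros(hue.shape, dtype=bool)
    for lo, hi in intervals:
        if lo <= hi:
            inside |= (hue >= lo) & (hue <= hi)
        else:  # wrap-around interval
            inside |= (hue >= lo) | (hue <= hi)
    return inside


def make_hue_mask(hue: np.ndarray, intervals: Sequence[Sequence[int]]) -> np.ndarray:
    """Masked normalized hue plane: ``hue/180`` inside the intervals, else 0."""
    hue = np.asarray(hue)
    if hue.min(initial=0) < 0 or hue.max(initial=0) > N_HUE_BINS - 1:
        raise ValueError("hue values must lie in [0, 179]")
    if not list(intervals):
        logger.warning("empty interval list: hue mask is all zeros")
        return np.zeros(hue.shape, dtype=np.float64)
    inside = interval_membership(hue, intervals)
    return np.where(inside, hue / float(N_HUE_BINS), 0.0)


def compose_four_channel(image: np.ndarray, mask: np.ndarray) -> FourChannelImage:
    """Append the masked hue plane to a [0,255] RGB image as channel four."""
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=np.float64)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {image.shape}")
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"image spatial shape {image.shape[:2]} != mask shape {mask.shape}"
        )
    rgb = np.moveaxis(image.astype(np.float64) / 255.0, -1, 0)
    return FourChannelImage(rgb=rgb, hue_mask=mask)


def four_channel_input(image: np.ndarray, environment: str,
                       override: Sequence[Sequence[int]] | None = None) -> FourChannelImage:
    """Convenience: extract hue, mask it per environment, compose 4 channels."""
    hue = extract_hue_channel(image)
    intervals = select_intervals(environment, override)
    return compose_four_channel(image, make_hue_mask(hue, intervals))
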