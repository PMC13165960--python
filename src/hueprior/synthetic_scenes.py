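"""Synthetic mushroom-cultivation scenes with YOLO annotations.

Stands in for field imagery of *Pleurotus ostreatus* shelves: each scene is
a 640×640 RGB image whose objects are cap-like ellipse clusters with pixel
hues drawn inside the environment's hue interval (warm [4, 38] for
greenhouse / semi-open, cool [110, 155] for LED-lit automated houses,
half-scale units), over a cluttered background whose hues are sampled
outside that interval. Five maturity stages differ in morphology and in
which sub-band of the interval their hues occupy:

- ``base`` — small, low-contrast disks (primordia);
- ``mulberry`` / ``coral`` — clusters of 3–8 tiny caps;
- ``forming`` — single mid-size caps;
- ``maturation`` — large caps with flattened tops, hue shifted toward the
  interval's upper edge.

Stressors (partial occlusion by gray struts, global dimming, blur) emulate
the field conditions a detector must survive. Everything is deterministic
given the scene seed. This is a visual stand-in for the real crop, not a
biological growth model: see the methods note for what it does and does not
emulate.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb
from skimage.draw import ellipse

from .dataset_pipeline import CLASS_NAMES, DetectionLabel, write_yolo_labels
from .hsv_color_db import N_HUE_BINS
from .hue_mask import select_intervals

CANVAS_SIDE = 640

#: margin (bins) kept from interval edges when sampling object hues, so that
#: uint8 round-trips cannot push a pixel outside its generating interval
HUE_EDGE_MARGIN = 2


class SceneGenerationError(ValueError):
    """The requested scene cannot be drawn (e.g. objects larger than canvas)."""


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene."""

    environment: str = "greenhouse"
    n_objects: int = 6
    stage_mix: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    size_range: tuple[int, int] = (24, 120)   # object diameter, pixels
    occlusion_prob: float = 0.0
    dim_factor: float = 1.0
    blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        mix = np.asarray(self.stage_mix, dtype=np.float64)
        if mix.shape != (len(CLASS_NAMES),) or mix.min() < 0 or abs(mix.sum() - 1) > 1e-9:
            raise ValueError("stage_mix must be 5 nonnegative numbers summing to 1")
        lo, hi = self.size_range
        if not (0 < lo <= hi):
            raise ValueError("size_range must satisfy 0 < min <= max")
        if hi > CANVAS_SIDE:
            raise SceneGenerationError(
                f"max object diameter {hi} exceeds the {CANVAS_SIDE}px canvas"
            )
        if not (0.0 <= self.occlusion_prob <= 1.0):
            raise ValueError("occlusion_prob must be in [0, 1]")
        if not (0.0 < self.dim_factor <= 1.0):
            raise ValueError("dim_factor must be in (0, 1]")


@dataclass
class SceneDebug:
    """Per-pixel ground truth the renderer tracked while drawing."""

    object_masks: list[np.ndarray]  # boolean (H, W) per object, pre-occlusion
    occlusion: np.ndarray           # boolean (H, W), pixels covered by struts
    intervals: list[list[int]]      # hue intervals the objects were drawn from


def stage_hue_band(intervals: Sequence[Sequence[int]], class_id: int) -> tuple[float, float]:
    """Sub-band of the environment interval assigned to one maturity stage.

    The first (primary) interval, shrunk by the edge margin, is divided into
    five equal bands in stage order, making the stages hue-separable while
    every stage stays inside the environment's interval.
    """
    lo, hi = intervals[0]
    lo, hi = lo + HUE_EDGE_MARGIN, hi - HUE_EDGE_MARGIN
    span = (hi - lo) / len(CLASS_NAMES)
    return lo + class_id * span, lo + (class_id + 1) * span


def _background_hue(rng: np.random.Generator, intervals) -> float:
    """A hue at least the edge margin outside every retained interval."""
    forbidden = np.zeros(N_HUE_BINS, dtype=bool)
    for lo, hi in intervals:
        a = max(lo - HUE_EDGE_MARGIN, 0)
        b = min(hi + HUE_EDGE_MARGIN, N_HUE_BINS - 1)
        forbidden[a:b + 1] = True
    allowed = np.nonzero(~forbidden)[0]
    return float(rng.choice(allowed))


def _draw_ellipse(hsv: np.ndarray, cy: float, cx: float, ry: float, rx: float,
                  hue: float, sat: float, val: float) -> np.ndarray:
    rr, cc = ellipse(cy, cx, ry, rx, shape=hsv.shape[:2])
    hsv[rr, cc, 0] = hue / N_HUE_BINS
    hsv[rr, cc, 1] = sat
    hsv[rr, cc, 2] = val
    mask = np.zeros(hsv.shape[:2], dtype=bool)
    mask[rr, cc] = True
    return mask


def _draw_object(hsv: np.ndarray, rng: np.random.Generator, class_id: int,
                 diameter: float, cx: float, cy: float,
                 intervals) -> np.ndarray:
    """Draw one stage-shaped cap cluster; returns its pixel mask."""
    band_lo, band_hi = stage_hue_band(intervals, class_id)
    stage = CLASS_NAMES[class_id]
    mask = np.zeros(hsv.shape[:2], dtype=bool)
    r = diameter / 2

    def hue():
        return rng.uniform(band_lo, band_hi)

    if stage == "base":  # small low-contrast disks
        n = rng.integers(1, 4)
        for _ in range(n):
            oy = cy + rng.uniform(-0.3, 0.3) * r
            ox = cx + rng.uniform(-0.3, 0.3) * r
            rad = rng.uniform(0.4, 0.7) * r
            mask |= _draw_ellipse(hsv, oy, ox, rad, rad, hue(),
                                  rng.uniform(0.45, 0.6), rng.uniform(0.35, 0.5))
    elif stage in ("mulberry", "coral"):  # clusters of 3-8 tiny caps
        n = rng.integers(3, 9)
        for _ in range(n):
            oy = cy + rng.uniform(-0.6, 0.6) * r
            ox = cx + rng.uniform(-0.6, 0.6) * r
            rad = rng.uniform(0.18, 0.35) * r
            mask |= _draw_ellipse(hsv, oy, ox, rad, rad * rng.uniform(0.8, 1.2),
                                  hue(), rng.uniform(0.55, 0.9),
                                  rng.uniform(0.45, 0.85))
    elif stage == "forming":  # single mid-size cap
        mask |= _draw_ellipse(hsv, cy, cx, r * rng.uniform(0.7, 0.9), r,
                              hue(), rng.uniform(0.55, 0.9),
                              rng.uniform(0.45, 0.85))
    else:  # maturation: large flattened cap, hue toward the upper band edge
        h = rng.uniform((band_lo + band_hi) / 2, band_hi)
        mask |= _draw_ellipse(hsv, cy, cx, r * rng.uniform(0.45, 0.6), r,
                              h, rng.uniform(0.55, 0.9), rng.uniform(0.5, 0.9))
        # stipe hint below the cap
        mask |= _draw_ellipse(hsv, cy + 0.45 * r, cx, r * 0.3, r * 0.25,
                              h, rng.uniform(0.5, 0.8), rng.uniform(0.4, 0.7))
    return mask


def render_scene(spec: SceneSpec, return_debug: bool = False):
    """Render one scene.

    Returns ``(image, labels)`` — a uint8 RGB 640×640 array plus one
    DetectionLabel per object — or ``(image, labels, debug)`` when
    ``return_debug`` is set.
    """
    rng = np.random.default_rng(spec.seed)
    intervals = select_intervals(spec.environment)
    side = CANVAS_SIDE

    hsv = np.zeros((side, side, 3), dtype=np.float64)
    # background substrate: a single out-of-interval hue with value texture
    bg_hue = _background_hue(rng, intervals)
    hsv[..., 0] = bg_hue / N_HUE_BINS
    hsv[..., 1] = rng.uniform(0.15, 0.35)
    hsv[..., 2] = rng.uniform(0.25, 0.5) + rng.normal(0, 0.02, (side, side))

    # clutter: blobs of other out-of-interval hues (shelf edges, substrate bags)
    for _ in range(rng.integers(6, 14)):
        _draw_ellipse(
            hsv,
            rng.uniform(0, side), rng.uniform(0, side),
            rng.uniform(10, 90), rng.uniform(10, 90),
            _background_hue(rng, intervals),
            rng.uniform(0.2, 0.8), rng.uniform(0.15, 0.85),
        )

    # objects
    labels: list[DetectionLabel] = []
    masks: list[np.ndarray] = []
    class_ids = rng.choice(len(CLASS_NAMES), size=spec.n_objects,
                           p=np.asarray(spec.stage_mix))
    for class_id in class_ids:
        diameter = rng.uniform(*spec.size_range)
        margin = diameter / 2 + 4
        cx = rng.uniform(margin, side - margin)
        cy = rng.uniform(margin, side - margin)
        mask = _draw_object(hsv, rng, int(class_id), diameter, cx, cy, intervals)
        if not mask.any():
            continue
        ys, xs = np.nonzero(mask)
        x1, x2 = xs.min(), xs.max() + 1
        y1, y2 = ys.min(), ys.max() + 1
        labels.append(DetectionLabel(
            int(class_id),
            cx=(x1 + x2) / 2 / side, cy=(y1 + y2) / 2 / side,
            w=(x2 - x1) / side, h=(y2 - y1) / side,
        ))
        masks.append(mask)

    # occlusion: gray struts across occluded objects
    occlusion = np.zeros((side, side), dtype=bool)
    for lb, mask in zip(labels, masks):
        if rng.uniform() < spec.occlusion_prob:
            x1, y1, x2, y2 = (v * side for v in lb.corners())
            bar_h = max(3.0, (y2 - y1) * rng.uniform(0.15, 0.3))
            bar_y = rng.uniform(y1, y2 - bar_h)
            yy0, yy1 = int(bar_y), min(int(bar_y + bar_h) + 1, side)
            xx0, xx1 = max(int(x1) - 5, 0), min(int(x2) + 5, side)
            hsv[yy0:yy1, xx0:xx1, 1] = 0.0
            hsv[yy0:yy1, xx0:xx1, 2] = rng.uniform(0.3, 0.6)
            occlusion[yy0:yy1, xx0:xx1] = True

    hsv[..., 2] = np.clip(hsv[..., 2] * spec.dim_factor, 0, 1)
    hsv[..., 1] = np.clip(hsv[..., 1], 0, 1)
    rgb = hsv2rgb(hsv)
    if spec.blur_sigma > 0:
        rgb = gaussian_filter(rgb, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
    image = (np.clip(rgb, 0, 1) * 255).astype(np.uint8)

    if return_debug:
        return image, labels, SceneDebug(masks, occlusion, intervals)
    return image, labels


def derive_scene_seeds(root_seed: int, n: int) -> list[int]:
    """Per-scene child seeds from one root seed.

    Splitting rule (recorded in the manifest): ``SeedSequence(root_seed)``
    spawns one state word per scene, reduced mod 2**31.
    """
    state = np.random.SeedSequence(root_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2 ** 31)) for s in state]


def render_dataset(n: int, template: SceneSpec, seed: int,
                   out_dir: str | Path) -> list[Path]:
    """Render ``n`` scenes into ``out_dir``: PNG images, YOLO TXT labels, and
    a manifest CSV recording each scene's spec and derived seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    images_dir = out_dir / "images"
    labels_dir = out_dir / "labels"
    images_dir.mkdir(parents=True, exist_ok=True)
    labels_dir.mkdir(parents=True, exist_ok=True)

    seeds = derive_scene_seeds(seed, n)
    written = []
    with (out_dir / "manifest.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([
            "image_id", "environment", "n_objects", "stage_mix", "size_range",
            "occlusion_prob", "dim_factor", "blur_sigma", "scene_seed",
            "seed_rule",
        ])
        for i, scene_seed in enumerate(seeds):
            spec = replace(template, seed=scene_seed)
            image, labels = render_scene(spec)
            image_id = f"scene_{i:05d}"
            Image.fromarray(image).save(images_dir / f"{image_id}.png")
            write_yolo_labels(labels, labels_dir / f"{image_id}.txt")
            writer.writerow([
                image_id, spec.environment, spec.n_objects,
                "|".join(f"{p:g}" for p in spec.stage_mix),
                f"{spec.size_range[0]}|{spec.size_range[1]}",
                spec.occlusion_prob, spec.dim_factor, spec.blur_sigma,
                scene_seed, f"SeedSequence({seed}).generate_state mod 2^31",
            ])
            written.append(images_dir / f"{image_id}.png")
    return written
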