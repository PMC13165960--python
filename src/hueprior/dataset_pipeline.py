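"""Dataset preparation: YOLO TXT I/O, geometric-only augmentation, letterbox
resizing, and deterministic 8:1:1 splitting.

Augmentation is restricted to geometric deformations (translation, rotation,
scaling): photometric changes are deliberately excluded because the
downstream detector relies on color as a primary cue, and brightness or
saturation edits would corrupt the hue statistics the rest of the stack is
built on.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from skimage.transform import AffineTransform, resize, warp

logger = logging.getLogger(__name__)

CLASS_NAMES = ("base", "mulberry", "coral", "forming", "maturation")

#: fraction of a clipped box's original area below which the box is dropped
MIN_RESIDUAL_AREA = 0.20


class LabelParseError(ValueError):
    """A YOLO TXT line could not be parsed; carries the 1-based line number."""

    def __init__(self, path, line_no: int, line: str, reason: str):
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {reason}: {line!r}")


@dataclass
class DetectionLabel:
    """One annotated object: maturity class plus normalized center/size box."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not (0 <= self.class_id < len(CLASS_NAMES)):
            raise ValueError(f"class_id must be 0..{len(CLASS_NAMES) - 1}")
        for name in ("cx", "cy", "w", "h"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0) and name in ("w", "h"):
                raise ValueError(f"{name}={v} outside (0, 1]")
        if not (self.cx - self.w / 2 >= -1e-9 and self.cx + self.w / 2 <= 1 + 1e-9
                and self.cy - self.h / 2 >= -1e-9 and self.cy + self.h / 2 <= 1 + 1e-9):
            raise ValueError("box extends outside the unit square")

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[self.class_id]

    def corners(self) -> tuple[float, float, float, float]:
        """(x1, y1, x2, y2) normalized corner coordinates."""
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)


@dataclass
class DatasetSplit:
    train: list[str]
    val: list[str]
    test: list[str]
    ratios: tuple[float, float, float]

    def as_dict(self) -> dict[str, list[str]]:
        return {"train": self.train, "val": self.val, "test": self.test}


# ---------------------------------------------------------------------------
# YOLO TXT I/O

def parse_yolo_line(line: str) -> DetectionLabel:
    parts = line.split()
    if len(parts) != 5:
        raise ValueError("expected 5 whitespace-separated fields")
    class_id = int(parts[0])
    cx, cy, w, h = (float(p) for p in parts[1:])
    return DetectionLabel(class_id, cx, cy, w, h)


def read_yolo_labels(path: str | Path) -> list[DetectionLabel]:
    """Parse a YOLO TXT label file (one ``class cx cy w h`` line per object)."""
    path = Path(path)
    labels = []
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            labels.append(parse_yolo_line(line))
        except (ValueError, IndexError) as exc:
            raise LabelParseError(path, line_no, line, str(exc)) from exc
    if not labels:
        # empty synthetic scenes are legal; real annotations should not be
        logger.warning("label file %s contains no annotations", path)
    return labels


def write_yolo_labels(labels: Iterable[DetectionLabel], path: str | Path) -> None:
    """Write labels in YOLO TXT format at 6-decimal precision."""
    lines = [
        f"{lb.class_id} {lb.cx:.6f} {lb.cy:.6f} {lb.w:.6f} {lb.h:.6f}"
        for lb in labels
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# geometric augmentation

def _transform_labels(labels: Sequence[DetectionLabel], tform: AffineTransform,
                      width: int, height: int) -> list[DetectionLabel]:
    """Map boxes through an affine transform as axis-aligned corner hulls,
    clip to the canvas, and drop boxes whose residual area falls below 20%."""
    out = []
    for lb in labels:
        x1, y1, x2, y2 = lb.corners()
        corners = np.array([
            [x1 * width, y1 * height], [x2 * width, y1 * height],
            [x1 * width, y2 * height], [x2 * width, y2 * height],
        ])
        moved = tform(corners)
        nx1, ny1 = moved.min(axis=0)
        nx2, ny2 = moved.max(axis=0)
        area = (nx2 - nx1) * (ny2 - ny1)
        cx1, cy1 = max(nx1, 0.0), max(ny1, 0.0)
        cx2, cy2 = min(nx2, width), min(ny2, height)
        if cx2 <= cx1 or cy2 <= cy1:
            continue
        if (cx2 - cx1) * (cy2 - cy1) < MIN_RESIDUAL_AREA * area:
            continue
        out.append(DetectionLabel(
            lb.class_id,
            cx=(cx1 + cx2) / 2 / width, cy=(cy1 + cy2) / 2 / height,
            w=(cx2 - cx1) / width, h=(cy2 - cy1) / height,
        ))
    return out


def augment_geometric(image: np.ndarray, labels: Sequence[DetectionLabel],
                      ops: Sequence[str], seed: int,
                      max_translate: float = 0.2, max_rotate: float = 30.0,
                      scale_range: tuple[float, float] = (0.8, 1.2),
                      ) -> tuple[np.ndarray, list[DetectionLabel]]:
    """Apply a random combination of translation/rotation/scaling.

    Boxes are transformed consistently with pixels; rotated boxes become
    their axis-aligned hulls. No photometric change is ever applied.
    """
    ops = list(ops)
    if not ops:
        raise ValueError("ops must be a nonempty subset of {translate, rotate, scale}")
    unknown = set(ops) - {"translate", "rotate", "scale"}
    if unknown:
        raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
    image = np.asarray(image)
    height, width = image.shape[:2]
    rng = np.random.default_rng(seed)

    tx = ty = 0.0
    angle = 0.0
    scale = 1.0
    if "translate" in ops:
        tx = rng.uniform(-max_translate, max_translate) * width
        ty = rng.uniform(-max_translate, max_translate) * height
    if "rotate" in ops:
        angle = np.deg2rad(rng.uniform(-max_rotate, max_rotate))
    if "scale" in ops:
        scale = rng.uniform(*scale_range)

    center = np.array([width / 2, height / 2])
    # rotate/scale about the image center, then translate
    tform = (AffineTransform(translation=-center)
             + AffineTransform(rotation=angle, scale=scale)
             + AffineTransform(translation=center)
             + AffineTransform(translation=(tx, ty)))

    warped = warp(image.astype(np.float64) / 255.0, tform.inverse,
                  output_shape=image.shape, order=1, mode="constant", cval=0.0)
    warped = np.rint(np.clip(warped, 0, 1) * 255).astype(np.uint8)
    return warped, _transform_labels(labels, tform, width, height)


def resize_to_canvas(image: np.ndarray, labels: Sequence[DetectionLabel],
                     side: int = 640, mode: str = "letterbox",
                     ) -> tuple[np.ndarray, list[DetectionLabel]]:
    """Resize to a ``side×side`` canvas.

    ``letterbox`` (default) scales uniformly and pads the short axis with
    black, preserving every label; ``stretch`` resizes each axis
    independently, leaving normalized labels unchanged.
    """
    if side <= 0:
        raise ValueError("side must be positive")
    image = np.asarray(image)
    height, width = image.shape[:2]
    if mode == "stretch" or height == width:
        if (height, width) == (side, side):
            return image.copy(), list(labels)
        out = resize(image.astype(np.float64) / 255.0, (side, side),
                     order=1, anti_aliasing=True)
        return np.rint(np.clip(out, 0, 1) * 255).astype(np.uint8), list(labels)
    if mode != "letterbox":
        raise ValueError(f"unknown resize mode {mode!r}")

    scale = side / max(height, width)
    new_h, new_w = round(height * scale), round(width * scale)
    scaled = resize(image.astype(np.float64) / 255.0, (new_h, new_w),
                    order=1, anti_aliasing=True)
    canvas = np.zeros((side, side) + image.shape[2:], dtype=np.float64)
    pad_y, pad_x = (side - new_h) // 2, (side - new_w) // 2
    canvas[pad_y:pad_y + new_h, pad_x:pad_x + new_w] = scaled
    out_labels = [
        DetectionLabel(
            lb.class_id,
            cx=(lb.cx * new_w + pad_x) / side, cy=(lb.cy * new_h + pad_y) / side,
            w=lb.w * new_w / side, h=lb.h * new_h / side,
        )
        for lb in labels
    ]
    return np.rint(np.clip(canvas, 0, 1) * 255).astype(np.uint8), out_labels


# ---------------------------------------------------------------------------
# splitting

def split_dataset(ids: Sequence[str], ratios: Sequence[float] = (8, 1, 1),
                  seed: int = 0) -> DatasetSplit:
    """Shuffle ids by seed and partition by ratios with largest-remainder
    rounding (so 100 ids under 8:1:1 give exactly 80/10/10)."""
    ids = list(ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 ids to split")
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ValueError("ratios must be 3 positive numbers")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]

    total = sum(ratios)
    exact = [r / total * len(ids) for r in ratios]
    counts = [int(np.floor(e)) for e in exact]
    remainders = [e - c for e, c in zip(exact, counts)]
    for i in sorted(range(3), key=lambda i: -remainders[i])[: len(ids) - sum(counts)]:
        counts[i] += 1

    train = shuffled[:counts[0]]
    val = shuffled[counts[0]:counts[0] + counts[1]]
    test = shuffled[counts[0] + counts[1]:]
    return DatasetSplit(train, val, test, ratios)


def write_split_manifest(split: DatasetSplit, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "subset"])
        for subset, members in split.as_dict().items():
            for image_id in members:
                writer.writerow([image_id, subset])
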