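"""Hue-analysis database and environment-specific hue-interval estimation.

*Pleurotus ostreatus* fruit bodies shift their dominant hue with the
cultivation environment: warm orange-brown tones (half-scale hue roughly
[4, 38]) under greenhouse and semi-open conditions, and a cool cyan-green
regime (roughly [110, 155]) under fully enclosed LED illumination. This
module builds a per-image hue database over annotated fruit-body regions and
estimates, per environment, the minimal contiguous (circular) hue interval
that captures a target fraction of the pooled hue mass.

All hue values use the half-scale convention: hue in degrees divided by two,
stored as integers in [0, 179], so that dividing by 180 normalizes to [0, 1].
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from skimage.color import rgb2hsv

N_HUE_BINS = 180

ENVIRONMENTS = ("greenhouse", "semi_open", "automated")
STAGES = ("base", "mulberry", "coral", "forming", "maturation")


class EmptyDatabaseError(ValueError):
    """No records match the requested environment."""


class IntervalEstimationError(ValueError):
    """Coverage target cannot be met (e.g. all-zero histogram)."""


@dataclass
class HueRecord:
    """One database row: the hue histogram of one image's fruit-body pixels.

    ``histogram`` holds pixel fractions per half-scale hue bin (bin ``b``
    covers hue value ``b``); it sums to 1 when ``n_pixels > 0`` and is
    all-zero otherwise.
    """

    image_id: str
    environment: str
    stage: str
    histogram: np.ndarray
    n_pixels: int

    def __post_init__(self):
        self.histogram = np.asarray(self.histogram, dtype=np.float64)
        if self.histogram.shape != (N_HUE_BINS,):
            raise ValueError(f"histogram must have {N_HUE_BINS} bins")
        if self.environment not in ENVIRONMENTS:
            raise ValueError(f"unknown environment {self.environment!r}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.n_pixels < 0:
            raise ValueError("n_pixels must be non-negative")
        total = float(self.histogram.sum())
        if self.n_pixels == 0:
            if total != 0.0:
                raise ValueError("histogram must be all-zero when n_pixels == 0")
        elif abs(total - 1.0) > 1e-9:
            raise ValueError("histogram must sum to 1 when n_pixels > 0")


@dataclass
class EnvironmentProfile:
    """An environment tag plus the hue intervals retained for it.

    ``coverage`` is the pooled-histogram mass the intervals capture.
    """

    environment: str
    intervals: list[list[int]]
    coverage: float = 1.0

    def __post_init__(self):
        self.intervals = normalize_intervals(self.intervals)


def normalize_intervals(intervals: Iterable[Sequence[int]]) -> list[list[int]]:
    """Validate, sort, and merge overlapping [lo, hi] half-scale intervals."""
    cleaned = []
    for iv in intervals:
        lo, hi = int(iv[0]), int(iv[1])
        if not (0 <= lo <= hi <= N_HUE_BINS - 1):
            raise ValueError(f"invalid hue interval [{lo}, {hi}]")
        cleaned.append([lo, hi])
    cleaned.sort()
    merged: list[list[int]] = []
    for lo, hi in cleaned:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return merged


def extract_hue_channel(image: np.ndarray) -> np.ndarray:
    """Convert an RGB image to its half-scale hue plane.

    Parameters
    ----------
    image
        ``(H, W, 3)`` array with values in [0, 255].

    Returns
    -------
    ``(H, W)`` integer plane with hue in [0, 179]. Pixels with undefined hue
    (zero saturation) get hue 0 by convention.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {image.shape}")
    hsv = rgb2hsv(image.astype(np.float64) / 255.0)
    hue = np.rint(hsv[..., 0] * N_HUE_BINS).astype(np.int64) % N_HUE_BINS
    return hue


def extract_hsv(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hue (half-scale int), saturation and value planes (floats in [0,1])."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {image.shape}")
    hsv = rgb2hsv(image.astype(np.float64) / 255.0)
    hue = np.rint(hsv[..., 0] * N_HUE_BINS).astype(np.int64) % N_HUE_BINS
    return hue, hsv[..., 1], hsv[..., 2]


def compute_hue_histogram(hue: np.ndarray, region: np.ndarray) -> tuple[np.ndarray, int]:
    """Fraction of region pixels falling in each half-scale hue bin.

    An empty region yields the all-zero vector with count 0 (not an error):
    synthetic scenes may legitimately contain empty annotation masks.
    """
    hue = np.asarray(hue)
    region = np.asarray(region, dtype=bool)
    if hue.shape != region.shape:
        raise ValueError("hue plane and region mask shapes differ")
    values = hue[region]
    n = int(values.size)
    if n == 0:
        return np.zeros(N_HUE_BINS), 0
    counts = np.bincount(values.ravel(), minlength=N_HUE_BINS).astype(np.float64)
    return counts / n, n


def record_from_image(image_id: str, image: np.ndarray, environment: str, stage: str,
                      region: np.ndarray | None = None,
                      saturation_floor: float = 0.0) -> HueRecord:
    """Build a HueRecord from an RGB image and an optional fruit-body mask.

    ``saturation_floor`` optionally drops near-achromatic pixels whose hue is
    numerically arbitrary; the default keeps everything.
    """
    hue, sat, _ = extract_hsv(image)
    if region is None:
        region = np.ones(hue.shape, dtype=bool)
    region = np.asarray(region, dtype=bool)
    if saturation_floor > 0:
        region = region & (sat >= saturation_floor)
    hist, n = compute_hue_histogram(hue, region)
    return HueRecord(image_id, environment, stage, hist, n)


def pool_environment(records: Sequence[HueRecord], environment: str) -> np.ndarray:
    """Pixel-count-weighted mean histogram over one environment's records.

    Weighting by pixel count makes the pooled vector equal the hue
    distribution of all fruit-body pixels in the environment taken together.
    """
    members = [r for r in records if r.environment == environment and r.n_pixels > 0]
    if not members:
        raise EmptyDatabaseError(
            f"no records with pixels for environment {environment!r}"
        )
    weights = np.array([r.n_pixels for r in members], dtype=np.float64)
    stacked = np.stack([r.histogram for r in members])
    pooled = (weights[:, None] * stacked).sum(axis=0) / weights.sum()
    return pooled


def estimate_hue_interval(pooled: np.ndarray, coverage: float = 0.90) -> list[int]:
    """Minimal-width contiguous circular hue interval holding ≥ ``coverage`` mass.

    The hue axis is circular (bin 179 neighbours bin 0), so wrap-around
    windows are considered. Ties on width are broken by the smaller start
    index. Returns ``[lo, hi]``; a wrap-around winner is reported with
    ``lo > hi`` meaning bins ``lo..179`` plus ``0..hi``.
    """
    pooled = np.asarray(pooled, dtype=np.float64)
    if pooled.shape != (N_HUE_BINS,):
        raise ValueError(f"pooled histogram must have {N_HUE_BINS} bins")
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage must be in (0, 1]")
    total = float(pooled.sum())
    if total <= 0 or coverage > total + 1e-12:
        raise IntervalEstimationError("coverage target exceeds histogram mass")

    # prefix sums on the doubled axis make every circular window O(1)
    doubled = np.concatenate([pooled, pooled])
    prefix = np.concatenate([[0.0], np.cumsum(doubled)])
    target = coverage - 1e-12  # tolerate float accumulation at exact coverage

    best: tuple[int, int] | None = None  # (width, lo)
    for width in range(1, N_HUE_BINS + 1):
        starts = np.arange(N_HUE_BINS)
        mass = prefix[starts + width] - prefix[starts]
        hit = np.nonzero(mass >= target)[0]
        if hit.size:
            best = (width, int(hit[0]))
            break
    assert best is not None  # width 180 always reaches total >= coverage
    width, lo = best
    hi = (lo + width - 1) % N_HUE_BINS
    return [lo, hi]


def interval_mass(pooled: np.ndarray, intervals: Iterable[Sequence[int]]) -> float:
    """Histogram mass inside a set of [lo, hi] intervals (wrap-around aware)."""
    pooled = np.asarray(pooled, dtype=np.float64)
    inside = np.zeros(N_HUE_BINS, dtype=bool)
    for lo, hi in intervals:
        if lo <= hi:
            inside[lo:hi + 1] = True
        else:
            inside[lo:] = True
            inside[:hi + 1] = True
    return float(pooled[inside].sum())


def build_profile(records: Sequence[HueRecord], environment: str,
                  coverage: float = 0.90) -> EnvironmentProfile:
    """Pool one environment's records and estimate its hue interval."""
    pooled = pool_environment(records, environment)
    lo, hi = estimate_hue_interval(pooled, coverage)
    if lo <= hi:
        intervals = [[lo, hi]]
    else:  # report a wrapped window as two forward intervals
        intervals = [[0, hi], [lo, N_HUE_BINS - 1]]
    profile = EnvironmentProfile(environment, intervals, 1.0)
    profile.coverage = interval_mass(pooled, profile.intervals)
    return profile


# ---------------------------------------------------------------------------
# persistence

_CSV_HEADER = ["image_id", "environment", "stage", "n_pixels"] + [
    f"h{b:03d}" for b in range(N_HUE_BINS)
]


def write_database(records: Sequence[HueRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for r in records:
            writer.writerow(
                [r.image_id, r.environment, r.stage, r.n_pixels]
                + [f"{v:.9g}" for v in r.histogram]
            )


def read_database(path: str | Path) -> list[HueRecord]:
    path = Path(path)
    records = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != _CSV_HEADER:
            raise ValueError(f"unexpected database header in {path}")
        for row in reader:
            hist = np.array([float(v) for v in row[4:]])
            records.append(HueRecord(row[0], row[1], row[2], hist, int(row[3])))
    return records


def write_profiles(profiles: Sequence[EnvironmentProfile], path: str | Path) -> None:
    payload = {
        p.environment: {"intervals": [list(iv) for iv in p.intervals],
                        "coverage": float(p.coverage)}
        for p in profiles
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_profiles(path: str | Path) -> list[EnvironmentProfile]:
    payload = yaml.safe_load(Path(path).read_text())
    return [
        EnvironmentProfile(env, entry["intervals"], float(entry["coverage"]))
        for env, entry in payload.items()
    ]
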