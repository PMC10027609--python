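"""Leaf yellow-area scoring by hue/saturation/brightness thresholding.

Leaves are photographed on a dark background; the leaf is segmented as
the largest bright connected component, then pixels inside the leaf are
classified as yellow or green by hue bands (with saturation and
brightness floors).  The severity score is the yellow-area ratio:
yellow pixels / leaf pixels.  A colour-reference-card check guards
comparisons across photo sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.measure import label

__all__ = [
    "HSBThresholds",
    "LeafScore",
    "NoLeafError",
    "to_hsb",
    "hue_in_band",
    "segment_leaf",
    "yellow_ratio",
    "measure_card",
    "calibration_passes",
]


class NoLeafError(ValueError):
    """No pixel exceeds the brightness floor: nothing to segment."""


@dataclass(frozen=True)
class HSBThresholds:
    """Hue bands (degrees, half-open [lo, hi)) and S/B floors.

    Wrap-around bands (lo > hi, crossing 0°) are supported.  Defaults are
    conventional for yellow/green leaf tissue; the original macro's cutoffs
    are configurable, and every result records the thresholds used.
    """

    yellow_band: tuple[float, float] = (35.0, 65.0)
    green_band: tuple[float, float] = (65.0, 165.0)
    min_saturation: float = 0.25
    min_brightness: float = 0.15

    def __post_init__(self) -> None:
        for lo, hi in (self.yellow_band, self.green_band):
            if not (0 <= lo < 360 and 0 <= hi < 360 or hi == 360):
                raise ValueError("hue band edges must lie in [0, 360)")
        if not (0 <= self.min_saturation <= 1 and 0 <= self.min_brightness <= 1):
            raise ValueError("saturation/brightness minima must be in [0, 1]")


@dataclass(frozen=True)
class LeafScore:
    leaf_pixel_count: int
    yellow_pixel_count: int
    green_pixel_count: int
    thresholds: HSBThresholds = field(default_factory=HSBThresholds)

    def __post_init__(self) -> None:
        if self.yellow_pixel_count + self.green_pixel_count > self.leaf_pixel_count:
            raise ValueError("yellow + green cannot exceed leaf area")

    @property
    def yellow_area_ratio(self) -> float:
        return self.yellow_pixel_count / self.leaf_pixel_count


def to_hsb(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel hue [0, 360), saturation [0, 1], brightness [0, 1].

    Standard hexcone (HSV) conversion; achromatic pixels get hue 0 and
    saturation 0.  Accepts 8-bit or float RGB.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    hsv = rgb2hsv(image)
    return hsv[..., 0] * 360.0, hsv[..., 1], hsv[..., 2]


def hue_in_band(hue: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Membership in a half-open hue band [lo, hi), wrapping at 0°."""
    lo, hi = band
    if lo <= hi:
        return (hue >= lo) & (hue < hi)
    return (hue >= lo) | (hue < hi)


def segment_leaf(image: np.ndarray, thresholds: HSBThresholds = HSBThresholds()) -> np.ndarray:
    """Boolean leaf mask: bright pixels, largest connected component,
    holes filled."""
    _, _, v = to_hsb(image)
    bright = v >= thresholds.min_brightness
    if not bright.any():
        raise NoLeafError("no pixel above the brightness floor; no leaf found")
    labels = label(bright, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == counts.argmax()
    return ndimage.binary_fill_holes(mask)


def yellow_ratio(image: np.ndarray, thresholds: HSBThresholds = HSBThresholds()) -> LeafScore:
    """Classify leaf pixels into yellow/green bands and score the leaf."""
    h, s, v = to_hsb(image)
    mask = segment_leaf(image, thresholds)
    chromatic = mask & (s >= thresholds.min_saturation) & (v >= thresholds.min_brightness)
    yellow = chromatic & hue_in_band(h, thresholds.yellow_band)
    green = chromatic & hue_in_band(h, thresholds.green_band)
    return LeafScore(int(mask.sum()), int(yellow.sum()), int(green.sum()), thresholds)


def overlay(image: np.ndarray, thresholds: HSBThresholds = HSBThresholds()) -> np.ndarray:
    """Painted copy of the photo: yellow-classified pixels pure yellow,
    green-classified pure green (mirrors the macro's control output)."""
    h, s, v = to_hsb(image)
    mask = segment_leaf(image, thresholds)
    chromatic = mask & (s >= thresholds.min_saturation) & (v >= thresholds.min_brightness)
    out = np.asarray(image).copy()
    if out.dtype != np.uint8:
        out = (np.clip(out, 0, 1) * 255).astype(np.uint8)
    out[chromatic & hue_in_band(h, thresholds.yellow_band)] = (255, 255, 0)
    out[chromatic & hue_in_band(h, thresholds.green_band)] = (0, 200, 0)
    return out


# ---------------------------------------------------------------------------
# Colour-card calibration


def measure_card(
    image: np.ndarray,
    patches: Mapping[str, tuple[int, int, int, int]],
    thresholds: HSBThresholds = HSBThresholds(),
) -> dict[str, int]:
    """Yellow-classified pixel count per reference-card patch.

    ``patches`` maps patch name to a (row0, row1, col0, col1) bounding box
    supplied by the user (no automatic card detection).
    """
    if not patches:
        raise ValueError("no card patches given; card region missing")
    h, s, v = to_hsb(image)
    yellow = (
        hue_in_band(h, thresholds.yellow_band)
        & (s >= thresholds.min_saturation)
        & (v >= thresholds.min_brightness)
    )
    out = {}
    for name, (r0, r1, c0, c1) in patches.items():
        if r0 >= r1 or c0 >= c1:
            raise ValueError(f"patch {name!r}: empty bounding box")
        out[name] = int(yellow[r0:r1, c0:c1].sum())
    return out


def calibration_passes(
    measurements: Sequence[Mapping[str, int]],
    yellow_patch: str,
    rel_tolerance: float = 0.05,
) -> bool:
    """True when the yellow patch's measured area is stable across photos.

    A session passes calibration if max deviation from the mean measured
    yellow area is within ``rel_tolerance``; only photos from a passing
    session should be compared.
    """
    areas = np.array([m[yellow_patch] for m in measurements], dtype=float)
    if areas.size < 2:
        return True
    mean = areas.mean()
    if mean == 0:
        return bool(np.all(areas == 0))
    return bool(np.max(np.abs(areas - mean)) / mean <= rel_tolerance)
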