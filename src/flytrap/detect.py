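"""Trap segmentation and dark-element localization.

Stage 2 of the inference pipeline: before any classification, the yellow
panel is segmented out of the frame (so nothing outside the trap can
become a false positive), then dark connected components inside the panel
are localized by exploiting the contrast between the yellow adhesive
background and the dark bodies of trapped insects.  Each located element
is cut to a fixed 32x32x3 patch for the classifiers.

All thresholds here are declared configuration, not facts about any
particular trap: the hue band defining "yellow", the saturation floor,
the darkness rule and the component-area bounds are all adjustable on
:class:`SegmentConfig` and :class:`LocateConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .core import CROP_SIZE, BoundingBox, ElementCrop, TrapImage, TrapNotFoundError

#: Reference frame area used to scale the component-area bounds.
_REF_AREA = 1600 * 1200


@dataclass(frozen=True)
class SegmentConfig:
    """Yellow-panel segmentation parameters (HSV colour model)."""

    hue_lo: float = 0.07      # yellow hue band, hue in [0, 1)
    hue_hi: float = 0.25
    sat_min: float = 0.25     # saturation floor: grey surround is excluded
    val_min: float = 0.15     # very dark pixels are never "yellow"
    closing_radius: int = 5   # morphological closing of the panel mask
    min_trap_fraction: float = 0.05  # below this mask/frame ratio: no trap


@dataclass(frozen=True)
class LocateConfig:
    """Dark-element localization parameters.

    ``min_area``/``max_area`` are expressed at the nominal 1600x1200
    frame and scaled by the actual frame area.  The darkness threshold
    is ``dark_ratio`` times the median panel value (a relative rule that
    adapts to overall lighting and yields no detections on an empty
    panel), refined by the Otsu split of the value channel inside the
    mask when that split lands in a plausible figure/ground range —
    a raw Otsu threshold can fall between two dark sub-populations
    (very dark vs merely dark insects) and drop the paler ones.
    """

    min_area: float = 30.0
    max_area: float = 3000.0
    dark_ratio: float = 0.6


def _value_channel(pixels: np.ndarray) -> np.ndarray:
    # HSV value = max over RGB, unit scale
    return pixels.max(axis=2).astype(np.float64) / 255.0


def segment_trap(image: TrapImage, config: SegmentConfig = SegmentConfig()) -> np.ndarray:
    """Segment the yellow trap panel; return a boolean H x W mask.

    The mask is the largest connected yellow-dominated component,
    morphologically closed and hole-filled (trapped insects are dark
    holes in the yellow region but lie on the panel).  Pixels outside the
    mask are excluded from all later stages.

    Raises
    ------
    TrapNotFoundError
        If the candidate mask covers less than ``min_trap_fraction`` of
        the frame.
    """
    hsv = rgb2hsv(image.pixels)
    yellow = (
        (hsv[:, :, 0] >= config.hue_lo)
        & (hsv[:, :, 0] <= config.hue_hi)
        & (hsv[:, :, 1] >= config.sat_min)
        & (hsv[:, :, 2] >= config.val_min)
    )
    if config.closing_radius > 0:
        yellow = morphology.closing(
            yellow, morphology.disk(config.closing_radius))
    labels = cc_label(yellow, connectivity=2)
    if labels.max() == 0:
        raise TrapNotFoundError(
            f"no trap found: no yellow-dominated region in frame "
            f"(hue band [{config.hue_lo}, {config.hue_hi}])")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = ndi.binary_fill_holes(labels == largest)
    fraction = mask.mean()
    if fraction < config.min_trap_fraction:
        raise TrapNotFoundError(
            f"no trap found: largest yellow region covers {fraction:.3f} "
            f"of the frame, below minimum {config.min_trap_fraction}")
    return mask


def locate_elements(image: TrapImage, mask: np.ndarray,
                    config: LocateConfig = LocateConfig()) -> list[BoundingBox]:
    """Locate dark connected components inside the panel mask.

    Returns one bounding box per component whose pixel area lies within
    the (frame-scaled) ``[min_area, max_area]`` bounds, sorted by (y, x)
    top-left corner for determinism.  An empty list is a valid result.
    Touching elements merge into a single component and yield one box.
    """
    if mask.shape != image.pixels.shape[:2]:
        raise ValueError("mask shape does not match image")
    value = _value_channel(image.pixels)
    panel = value[mask]
    if panel.size == 0:
        return []
    ceiling = config.dark_ratio * float(np.median(panel))
    threshold = ceiling
    if panel.min() != panel.max():  # Otsu undefined on a flat panel
        otsu = float(threshold_otsu(panel))
        if otsu >= 0.5 * ceiling:
            threshold = min(otsu, ceiling)
    dark = mask & (value < threshold)
    scale = (image.height * image.width) / _REF_AREA
    lo, hi = config.min_area * scale, config.max_area * scale
    boxes: list[BoundingBox] = []
    for region in regionprops(cc_label(dark, connectivity=2)):
        if lo <= region.area <= hi:
            r0, c0, r1, c1 = region.bbox
            boxes.append(BoundingBox(x=c0, y=r0, w=c1 - c0, h=r1 - r0))
    boxes.sort(key=lambda b: (b.y, b.x))
    return boxes


def extract_crop(image: TrapImage, box: BoundingBox) -> ElementCrop:
    """Cut the fixed 32x32x3 patch centred on a box centroid.

    Windows that would cross the image border are shifted inward, so the
    output patch is always full size (no rescaling of the element).

    Raises
    ------
    ValueError
        If the box does not intersect the image, or the image is smaller
        than the patch.
    """
    h, w = image.height, image.width
    if h < CROP_SIZE or w < CROP_SIZE:
        raise ValueError(f"image {h}x{w} is smaller than the {CROP_SIZE}px patch")
    if box.x2 <= 0 or box.y2 <= 0 or box.x >= w or box.y >= h:
        raise ValueError(f"box {box} lies fully outside the {h}x{w} image")
    cx, cy = box.center
    x0 = int(round(cx)) - CROP_SIZE // 2
    y0 = int(round(cy)) - CROP_SIZE // 2
    x0 = min(max(x0, 0), w - CROP_SIZE)
    y0 = min(max(y0, 0), h - CROP_SIZE)
    patch = image.pixels[y0:y0 + CROP_SIZE, x0:x0 + CROP_SIZE].copy()
    return ElementCrop(patch=patch, source_box=box,
                       trap_id=image.trap_id, timestamp=image.timestamp)


def extract_all_crops(image: TrapImage, boxes: list[BoundingBox]) -> list[ElementCrop]:
    """Convenience: one crop per located box, in the given order."""
    return [extract_crop(image, box) for box in boxes]
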