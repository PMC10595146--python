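"""Shared domain types and errors for the sticky-trap detection pipeline.

The pipeline operates on photographs of yellow adhesive panels ("sticky
traps") used to monitor the olive fruit fly, *Bactrocera oleae*.  Every
dark connected region on a trap ("element") becomes a classification
candidate: a fixed 32x32x3 pixel patch is cut around it and scored by a
random-forest / support-vector-machine ensemble.

Labels use a three-way scheme for annotation (olive fly, other fly
species, other elements such as attractant bags, panel holes, shadows or
printed marks) that collapses to a binary olive-fly-vs-others task for
classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

import numpy as np

#: The three annotation classes, in canonical order.
LABELS3 = ("olive_fly", "other_fly", "other_element")

#: Binary grouping: the positive class and everything else.
POSITIVE_LABEL = "olive_fly"
OTHERS_LABEL = "others"

#: Side of the square patch cut around each localized element.
CROP_SIZE = 32


class FlytrapError(Exception):
    """Base class for all package-specific errors."""


class PlacementError(FlytrapError):
    """Requested synthetic elements could not be placed without overlap."""


class TrapNotFoundError(FlytrapError):
    """No sufficiently large yellow trap region was found in the frame."""


class AnnotationError(FlytrapError):
    """An annotation file is malformed or uses an unknown label."""


class SingleClassError(FlytrapError):
    """Training was attempted on labels containing a single class."""


def to_binary_label(label3: str) -> str:
    """Collapse a three-way label to the binary olive-fly/others scheme."""
    if label3 not in LABELS3:
        raise ValueError(f"unknown label {label3!r}; expected one of {LABELS3}")
    return POSITIVE_LABEL if label3 == POSITIVE_LABEL else OTHERS_LABEL


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box, 0-based, half-open: spans ``[x, x+w) x [y, y+h)``."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box must have positive extent, got w={self.w}, h={self.h}")

    @property
    def x2(self) -> int:
        return self.x + self.w

    @property
    def y2(self) -> int:
        return self.y + self.h

    @property
    def area(self) -> int:
        return self.w * self.h

    @property
    def center(self) -> tuple[float, float]:
        """(cx, cy) in pixel coordinates."""
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def intersection_area(self, other: "BoundingBox") -> int:
        iw = min(self.x2, other.x2) - max(self.x, other.x)
        ih = min(self.y2, other.y2) - max(self.y, other.y)
        if iw <= 0 or ih <= 0:
            return 0
        return iw * ih

    def iou(self, other: "BoundingBox") -> float:
        """Intersection over union with another box, in [0, 1]."""
        inter = self.intersection_area(other)
        if inter == 0:
            return 0.0
        return inter / (self.area + other.area - inter)

    def within(self, width: int, height: int) -> bool:
        return self.x >= 0 and self.y >= 0 and self.x2 <= width and self.y2 <= height

    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y, "w": self.w, "h": self.h}

    @classmethod
    def from_dict(cls, d: dict) -> "BoundingBox":
        return cls(int(d["x"]), int(d["y"]), int(d["w"]), int(d["h"]))


@dataclass
class TrapImage:
    """One trap photograph: H x W x 3 array of 8-bit intensities plus identity."""

    pixels: np.ndarray
    trap_id: str = ""
    timestamp: datetime | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an H x W x 3 image, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have positive height and width")
        if px.dtype != np.uint8:
            raise ValueError(f"expected 8-bit unsigned pixels, got dtype {px.dtype}")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ElementCrop:
    """A 32x32x3 patch cut around a localized element, with provenance."""

    patch: np.ndarray
    source_box: BoundingBox | None = None
    trap_id: str = ""
    timestamp: datetime | None = None

    def __post_init__(self) -> None:
        patch = np.asarray(self.patch)
        if patch.shape != (CROP_SIZE, CROP_SIZE, 3):
            raise ValueError(
                f"crop patch must be {CROP_SIZE}x{CROP_SIZE}x3, got shape {patch.shape}"
            )
        self.patch = patch


@dataclass
class LabelledDataset:
    """Crops with three-way labels and a partition tag.

    ``labels2`` is derived, never stored: a crop is ``olive_fly`` iff its
    three-way label is ``olive_fly``; other flies and other elements are
    grouped as ``others``.
    """

    crops: list[np.ndarray]
    labels3: list[str]
    partition: str = "train"

    def __post_init__(self) -> None:
        if len(self.crops) != len(self.labels3):
            raise ValueError(
                f"{len(self.crops)} crops but {len(self.labels3)} labels"
            )
        bad = sorted({lab for lab in self.labels3 if lab not in LABELS3})
        if bad:
            raise ValueError(f"unknown labels {bad}; expected one of {LABELS3}")

    def __len__(self) -> int:
        return len(self.crops)

    @property
    def labels2(self) -> list[str]:
        return [to_binary_label(lab) for lab in self.labels3]

    def class_counts(self) -> dict[str, int]:
        counts = {lab: 0 for lab in LABELS3}
        for lab in self.labels3:
            counts[lab] += 1
        return counts

    def subset(self, indices: Sequence[int], partition: str | None = None) -> "LabelledDataset":
        return LabelledDataset(
            crops=[self.crops[i] for i in indices],
            labels3=[self.labels3[i] for i in indices],
            partition=self.partition if partition is None else partition,
        )

    def concat(self, other: "LabelledDataset") -> "LabelledDataset":
        if other.partition != self.partition:
            raise ValueError("cannot concatenate datasets from different partitions")
        return LabelledDataset(
            crops=self.crops + other.crops,
            labels3=self.labels3 + other.labels3,
            partition=self.partition,
        )
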