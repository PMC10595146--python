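"""Label-preserving data augmentation for training crops.

Four binary transforms enlarge the small training set: vertical flip,
horizontal flip, a single 90-degree rotation, and a joint
brightness/contrast change.  All four preserve the class label ("safe"
augmentation) and the 32x32 patch geometry.  The on/off combinations of
the four techniques give exactly 2**4 = 16 variants of each crop,
including the identity.

The stochastic procedure used to build a training set draws, for each
sample, a number of new images uniformly between zero and ``max_new``
(default ten) and applies each technique independently with probability
``p_technique`` (default 50%), so the augmentation is deliberately
heterogeneous and the expected growth factor is 1 + max_new/2.

Augmentation is for the training partition only; applying it to
validation or test data is a usage error and is rejected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core import ElementCrop, FlytrapError, LabelledDataset

#: Canonical order of the four binary techniques.
TECHNIQUES = ("vflip", "hflip", "rot90", "brightness_contrast")


@dataclass(frozen=True)
class AugmentationConfig:
    """Stochastic augmentation parameters.

    ``contrast_range`` is a multiplicative factor applied around mid-grey
    and ``brightness_range`` an additive shift in 8-bit intensity units;
    the two are sampled jointly when the brightness/contrast technique
    fires.
    """

    p_technique: float = 0.5
    max_new: int = 10
    contrast_range: tuple[float, float] = (0.8, 1.2)
    brightness_range: tuple[float, float] = (-20.0, 20.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_technique <= 1.0:
            raise ValueError("p_technique must lie in [0, 1]")
        if self.max_new < 0:
            raise ValueError("max_new must be non-negative")


def apply_brightness_contrast(patch: np.ndarray, contrast: float,
                              brightness: float) -> np.ndarray:
    """``contrast * patch + brightness``, clipped back to 8-bit range."""
    out = patch.astype(np.float64) * contrast + brightness
    return np.clip(out, 0.0, 255.0).round().astype(np.uint8)


def _apply_combo(patch: np.ndarray, combo: tuple[bool, bool, bool, bool],
                 contrast: float, brightness: float) -> np.ndarray:
    vflip, hflip, rot, bc = combo
    out = patch
    if vflip:
        out = np.flipud(out)
    if hflip:
        out = np.fliplr(out)
    if rot:
        out = np.rot90(out, k=-1)  # one clockwise quarter turn
    out = np.ascontiguousarray(out)
    if bc:
        out = apply_brightness_contrast(out, contrast, brightness)
    return out


def _as_patch(crop: ElementCrop | np.ndarray) -> np.ndarray:
    return crop.patch if isinstance(crop, ElementCrop) else np.asarray(crop)


def enumerate_variants(crop: ElementCrop | np.ndarray, contrast: float = 1.1,
                       brightness: float = 10.0) -> list[np.ndarray]:
    """All 16 on/off combinations of the four techniques, identity first.

    The brightness/contrast technique is evaluated at the given fixed
    representative setting so the enumeration is deterministic.  Distinct
    combinations may coincide pixel-wise for symmetric inputs (a uniform
    patch is unchanged by any geometric transform).
    """
    patch = _as_patch(crop)
    return [
        _apply_combo(patch, combo, contrast, brightness)
        for combo in itertools.product((False, True), repeat=len(TECHNIQUES))
    ]


def augment_crop(crop: ElementCrop | np.ndarray, label: str,
                 config: AugmentationConfig,
                 rng: np.random.Generator) -> list[tuple[np.ndarray, str]]:
    """Generate k new labelled crops, k ~ uniform{0, ..., max_new}.

    Each new crop applies each of the four techniques independently with
    probability ``p_technique``; the label is copied unchanged.
    """
    patch = _as_patch(crop)
    k = int(rng.integers(0, config.max_new + 1))
    out: list[tuple[np.ndarray, str]] = []
    for _ in range(k):
        combo = tuple(rng.random() < config.p_technique
                      for _ in TECHNIQUES)
        contrast = rng.uniform(*config.contrast_range)
        brightness = rng.uniform(*config.brightness_range)
        out.append((_apply_combo(patch, combo, contrast, brightness), label))
    return out


def augment_training_set(dataset: LabelledDataset,
                         config: AugmentationConfig = AugmentationConfig()
                         ) -> LabelledDataset:
    """Originals plus stochastically generated crops, training data only.

    Each sample gets its own seeded random substream keyed by (config
    seed, sample index), so the output is reproducible and insensitive to
    how samples would be batched.  Expected output size is
    ``len(dataset) * (1 + max_new / 2)``.

    Raises
    ------
    FlytrapError
        If the dataset partition is not ``"train"`` — augmenting
        validation or test data would leak transformed copies of held-out
        samples into evaluation.
    """
    if dataset.partition != "train":
        raise FlytrapError(
            f"augmentation is restricted to the training partition, "
            f"got partition={dataset.partition!r}")
    crops: list[np.ndarray] = list(dataset.crops)
    labels: list[str] = list(dataset.labels3)
    for i, (crop, label) in enumerate(zip(dataset.crops, dataset.labels3)):
        rng = np.random.default_rng([config.seed & 0x7FFFFFFF, i])
        for patch, lab in augment_crop(crop, label, config, rng):
            crops.append(patch)
            labels.append(lab)
    return LabelledDataset(crops=crops, labels3=labels, partition="train")
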