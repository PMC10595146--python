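"""End-to-end inference: capture -> segment -> locate -> classify -> validate.

One call runs a trained classifier bundle over trap photographs: the
yellow panel is segmented, dark elements are localized and cropped, each
crop gets an RF vote and an SVM vote, and an element is marked as an
olive fly only when both models agree.  The per-image report carries
every box with its individual votes plus the final olive-fly count, and
is serialized deterministically (sorted keys) so identical inputs and
configuration produce byte-identical JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .augment import AugmentationConfig
from .classify import ClassifierBundle, RFConfig, SVMConfig
from .core import FlytrapError, TrapImage
from .detect import LocateConfig, SegmentConfig, extract_all_crops, locate_elements, segment_trap

#: Schema version of the serialized pipeline configuration.
CONFIG_SCHEMA = "flytrap-config-1"

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the inference pipeline in one serializable object."""

    segment: SegmentConfig = field(default_factory=SegmentConfig)
    locate: LocateConfig = field(default_factory=LocateConfig)
    augment: AugmentationConfig = field(default_factory=AugmentationConfig)
    rf: RFConfig = field(default_factory=RFConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    iou_threshold: float = 0.3
    seed: int = 0

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [listify(v) for v in obj]
            return obj

        d = listify(asdict(self))
        d["schema"] = CONFIG_SCHEMA
        return d

    def to_yaml(self, path: str | Path) -> None:
        """Write the full configuration as one YAML document."""
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a configuration file; unknown keys are rejected."""
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise FlytrapError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build from a nested dict, rejecting unknown keys at every level."""
        data = dict(data)
        data.pop("schema", None)
        sections = {f.name: f for f in fields(cls)}
        unknown = sorted(set(data) - set(sections))
        if unknown:
            raise FlytrapError(f"unknown config keys: {unknown}")
        kwargs = {}
        for name, f in sections.items():
            if name not in data:
                continue
            value = data[name]
            if isinstance(value, dict):
                sub_cls = f.default_factory  # type: ignore[union-attr]
                sub_fields = {sf.name for sf in fields(sub_cls)}
                bad = sorted(set(value) - sub_fields)
                if bad:
                    raise FlytrapError(f"unknown config keys in {name!r}: {bad}")
                value = {k: tuple(v) if isinstance(v, list) else v
                         for k, v in value.items()}
                kwargs[name] = sub_cls(**value)
            else:
                kwargs[name] = value
        return cls(**kwargs)


def save_crop_dataset(dataset, out_dir: str | Path) -> None:
    """Write a crop bundle: numbered PNGs plus a labels.csv manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["filename,label3,partition"]
    for i, (crop, label) in enumerate(zip(dataset.crops, dataset.labels3)):
        name = f"crop_{i:05d}.png"
        iio.imwrite(out / name, crop)
        rows.append(f"{name},{label},{dataset.partition}")
    (out / "labels.csv").write_text("\n".join(rows) + "\n")


def load_crop_dataset(in_dir: str | Path):
    """Read a crop bundle written by :func:`save_crop_dataset`."""
    from .core import LabelledDataset

    root = Path(in_dir)
    manifest = root / "labels.csv"
    if not manifest.exists():
        raise FlytrapError(f"{root}: missing labels.csv manifest")
    crops, labels = [], []
    partition = "train"
    for line in manifest.read_text().splitlines()[1:]:
        if not line.strip():
            continue
        name, label, partition = line.split(",")
        crops.append(np.asarray(iio.imread(root / name)).astype(np.uint8))
        labels.append(label)
    return LabelledDataset(crops=crops, labels3=labels, partition=partition)


def load_image(path: str | Path) -> TrapImage:
    """Read a PNG/JPEG trap photograph from disk."""
    pixels = np.asarray(iio.imread(path))
    if pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]
    return TrapImage(pixels=pixels.astype(np.uint8), trap_id=Path(path).stem)


def process_image(image: TrapImage, bundle: ClassifierBundle,
                  config: PipelineConfig = PipelineConfig()) -> dict:
    """Run segmentation, localization and AND-validated classification.

    Returns a JSON-serializable report: every located box with its RF
    vote, SVM vote and ensemble verdict, plus the validated olive-fly
    count.
    """
    mask = segment_trap(image, config.segment)
    boxes = locate_elements(image, mask, config.locate)
    detections = []
    count = 0
    if boxes:
        votes = bundle.predict(extract_all_crops(image, boxes))
        for box, row in zip(boxes, votes.itertuples(index=False)):
            is_fly = row.ensemble == bundle.positive_label
            count += int(is_fly)
            detections.append({
                "box": box.to_dict(),
                "rf_vote": str(row.rf_vote),
                "svm_vote": str(row.svm_vote),
                "olive_fly": bool(is_fly),
            })
    return {
        "trap_id": image.trap_id,
        "timestamp": image.timestamp.isoformat() if image.timestamp else None,
        "n_elements": len(boxes),
        "olive_fly_count": count,
        "detections": detections,
    }


def run_pipeline(path: str | Path, bundle: ClassifierBundle,
                 config: PipelineConfig = PipelineConfig(),
                 out_path: str | Path | None = None) -> list[dict]:
    """Process one image file or every image in a directory.

    Reports are ordered by file name.  When ``out_path`` is given the
    reports are written as deterministic JSON (sorted keys, fixed
    indentation).
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(q for q in p.iterdir()
                       if q.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise FlytrapError(f"{p}: no PNG/JPEG images found")
    else:
        files = [p]
    reports = []
    for f in files:
        try:
            image = load_image(f)
        except Exception as exc:  # plugin chains raise assorted types
            raise FlytrapError(f"unreadable image {f}: {exc}") from exc
        reports.append(process_image(image, bundle, config))
    if out_path is not None:
        Path(out_path).write_text(
            json.dumps(reports, indent=1, sort_keys=True) + "\n")
    return reports
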